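"""Fisher unit information for the interaction logistic model.

The asymptotic variance of a trial's interaction estimate is
``var(lambda_hat_i) = I_i^{-1}(4,4) / n_i``, where ``I_i`` is the 4x4
*unit* (per-participant) Fisher information of the logistic model

    logit Pr(y=1 | x, z) = alpha + beta*x + gamma*z + lambda*x*z

with design vector ``X = (1, x, z, xz)'`` and Bernoulli weight
``w = e^eta / (1 + e^eta)^2`` evaluated at the linear predictor:
``I = E_{x,z}[ w * X X' ]``.

For a binary covariate the expectation runs over the four (x, z) cells and
collapses to a closed form — a weighted sum of four constant 0/1 matrices.
For a continuous covariate no closed form exists; the expectation is taken
over a large generated (x, z) population (Monte Carlo) or, for known
families, by Gaussian quadrature per arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .trial_aggregates import (
    BinaryCovariateSummary,
    ContinuousCovariateSummary,
    ModelAssumptions,
    TrialAggregate,
    TrialParams,
    trial_params,
)

__all__ = [
    "UnitInformation",
    "CovariatePopulation",
    "TrialVariance",
    "unit_information_binary",
    "build_population",
    "unit_information_continuous",
    "interaction_variance",
    "trial_variance",
    "M1",
    "M2",
    "M3",
    "M4",
]

# Cell pattern matrices: M_ab = X X' at (x, z) = (a, b) with X = (1, x, z, xz)'.
M1 = np.zeros((4, 4))
M1[0, 0] = 1.0
M2 = np.zeros((4, 4))
M2[np.ix_([0, 1], [0, 1])] = 1.0
M3 = np.zeros((4, 4))
M3[np.ix_([0, 2], [0, 2])] = 1.0
M4 = np.ones((4, 4))

#: Default size of the generated population for continuous covariates.
DEFAULT_POPULATION_SIZE = 1_000_000

#: Reciprocal-condition-number threshold below which the information matrix
#: is declared numerically singular (variance reported as infinite).
RCOND_SINGULAR = 1e-12

_QUAD_NODES = 64


@dataclass(frozen=True)
class UnitInformation:
    """A 4x4 unit information matrix, rows/cols ordered
    (intercept, treatment, covariate, interaction)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("unit information must be 4x4")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class CovariatePopulation:
    """Weighted (x, z) population standing in for the joint distribution.

    Monte-Carlo populations carry equal weights 1/N; quadrature populations
    carry product weights of arm fraction and node weight.  ``z`` is
    centered at the analytic trial-wide covariate mean.
    """

    x: np.ndarray
    z: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.z) == len(self.weights)):
            raise ValueError("x, z and weights must have equal length")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class TrialVariance:
    """Anticipated variance of one trial's interaction estimate."""

    trial_id: str
    var_interaction: float
    finite: bool

    @classmethod
    def infinite(cls, trial_id: str) -> "TrialVariance":
        return cls(trial_id=trial_id, var_interaction=np.inf, finite=False)


def _bernoulli_weight(eta: np.ndarray | float) -> np.ndarray | float:
    """Variance function p(1-p) of the logistic model at linear predictor eta."""
    p = expit(eta)
    return p * (1.0 - p)


def unit_information_binary(
    params: TrialParams, probs: BinaryCovariateSummary
) -> UnitInformation:
    """Closed-form unit information for a binary covariate.

    Each (x, z) cell contributes its Bernoulli weight times its constant
    pattern matrix, weighted by the cell's joint probability.
    """
    a, b, g, l = params.alpha, params.beta, params.gamma, params.lambda_
    terms = (
        (_bernoulli_weight(a), M1, probs.p00),
        (_bernoulli_weight(a + b), M2, probs.p10),
        (_bernoulli_weight(a + g), M3, probs.p01),
        (_bernoulli_weight(a + b + g + l), M4, probs.p11),
    )
    matrix = sum(w * m * p for w, m, p in terms)
    return UnitInformation(matrix=matrix)


def _arm_nodes(family: str, mean: float, sd: float, n_nodes: int):
    """Quadrature nodes/weights for one arm's covariate distribution."""
    if family == "normal":
        nodes, wts = np.polynomial.hermite_e.hermegauss(n_nodes)
        return mean + sd * nodes, wts / wts.sum()
    # uniform on mean +/- sqrt(3)*sd (matching the stated mean and SD)
    nodes, wts = np.polynomial.legendre.leggauss(n_nodes)
    half = np.sqrt(3.0) * sd
    return mean + half * nodes, wts / wts.sum()


def build_population(
    trial: TrialAggregate,
    size: int = DEFAULT_POPULATION_SIZE,
    seed: int | None = None,
    method: str = "montecarlo",
) -> CovariatePopulation:
    """Generate the (x, z) population matching a trial's aggregate data.

    Arm membership is allocated in exact proportion (floor for control,
    remainder treatment) — the allocation fraction is known, so randomizing
    it would only add noise.  ``z`` is drawn from (or quadrature-resolved
    over) the arm's assumed distribution and centered by the *analytic*
    trial-wide mean ``(n_C*mean_C + n_T*mean_T)/n`` rather than the realized
    sample mean, again to avoid gratuitous Monte-Carlo noise.
    """
    cov = trial.covariate
    if not isinstance(cov, ContinuousCovariateSummary):
        raise TypeError("build_population requires a continuous covariate summary")
    if cov.degenerate:
        raise ValueError(f"trial {trial.trial_id}: degenerate covariate (sd <= 0)")
    n = trial.n
    frac_c = trial.n_control / n
    overall_mean = frac_c * cov.mean_control + (1 - frac_c) * cov.mean_treat

    if method == "quadrature":
        zc, wc = _arm_nodes(cov.family, cov.mean_control, cov.sd_control, _QUAD_NODES)
        zt, wt = _arm_nodes(cov.family, cov.mean_treat, cov.sd_treat, _QUAD_NODES)
        x = np.concatenate([np.zeros_like(zc), np.ones_like(zt)])
        z = np.concatenate([zc, zt]) - overall_mean
        w = np.concatenate([frac_c * wc, (1 - frac_c) * wt])
        return CovariatePopulation(x=x, z=z, weights=w)
    if method != "montecarlo":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    n_c = int(np.floor(size * frac_c))
    n_t = size - n_c

    def draw(count: int, mean: float, sd: float) -> np.ndarray:
        if cov.family == "normal":
            return rng.normal(mean, sd, count)
        half = np.sqrt(3.0) * sd
        return rng.uniform(mean - half, mean + half, count)

    z = np.concatenate(
        [draw(n_c, cov.mean_control, cov.sd_control), draw(n_t, cov.mean_treat, cov.sd_treat)]
    ) - overall_mean
    x = np.concatenate([np.zeros(n_c), np.ones(n_t)])
    return CovariatePopulation(x=x, z=z, weights=np.full(size, 1.0 / size))


def unit_information_continuous(
    params: TrialParams, pop: CovariatePopulation
) -> UnitInformation:
    """Expected w * X X' over a generated (x, z) population.

    Exploits x in {0,1} (so x^2 = x) to reduce the 16 entries to six
    weighted moments of (w, wx, wz, wxz, wz^2, wxz^2).
    """
    if len(pop) == 0:
        raise ValueError("population is empty")
    x, z, wts = pop.x, pop.z, pop.weights
    eta = params.alpha + params.beta * x + params.gamma * z + params.lambda_ * x * z
    w = _bernoulli_weight(eta) * wts / wts.sum()
    ew = w.sum()
    ewx = (w * x).sum()
    ewz = (w * z).sum()
    ewxz = (w * x * z).sum()
    ewz2 = (w * z * z).sum()
    ewxz2 = (w * x * z * z).sum()
    matrix = np.array(
        [
            [ew, ewx, ewz, ewxz],
            [ewx, ewx, ewxz, ewxz],
            [ewz, ewxz, ewz2, ewxz2],
            [ewxz, ewxz, ewxz2, ewxz2],
        ]
    )
    return UnitInformation(matrix=matrix)


def interaction_variance(
    info: UnitInformation,
    n: int,
    *,
    trial_id: str = "",
    rcond_threshold: float = RCOND_SINGULAR,
) -> TrialVariance:
    """var(lambda_hat) = (4,4) element of the inverse information over n.

    A numerically singular matrix (reciprocal condition number below
    ``rcond_threshold``, e.g. a degenerate covariate) yields an infinite,
    flagged variance rather than an exception.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    m = info.matrix
    if not np.all(np.isfinite(m)):
        return TrialVariance.infinite(trial_id)
    sv = np.linalg.svd(m, compute_uv=False)
    if sv[0] <= 0 or sv[-1] / sv[0] < rcond_threshold:
        return TrialVariance.infinite(trial_id)
    var = np.linalg.inv(m)[3, 3] / n
    if not np.isfinite(var) or var <= 0:
        return TrialVariance.infinite(trial_id)
    return TrialVariance(trial_id=trial_id, var_interaction=float(var), finite=True)


def trial_variance(
    trial: TrialAggregate,
    assumptions: ModelAssumptions,
    *,
    continuity: bool = False,
    population_size: int = DEFAULT_POPULATION_SIZE,
    seed: int | None = None,
    method: str = "montecarlo",
) -> TrialVariance:
    """Anticipated var(lambda_hat_i) for one trial from its aggregates.

    Dispatches on the covariate flavor; trials with a missing or degenerate
    covariate get an infinite (flagged) variance and hence zero weight
    downstream.
    """
    if trial.covariate is None or trial.covariate.degenerate:
        return TrialVariance.infinite(trial.trial_id)
    params = trial_params(trial, assumptions, continuity)
    if isinstance(trial.covariate, BinaryCovariateSummary):
        info = unit_information_binary(params, trial.covariate)
    else:
        pop = build_population(trial, size=population_size, seed=seed, method=method)
        info = unit_information_continuous(params, pop)
    return interaction_variance(info, trial.n, trial_id=trial.trial_id)
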