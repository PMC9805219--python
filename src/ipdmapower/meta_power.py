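"""Second-stage pooling, power and anticipated precision.

Per-trial interaction variances are pooled by inverse variance.  Under a
common interaction the summary variance is ``1 / sum_i 1/v_i``; under a
random-effects model each trial variance is inflated by the between-trial
variance ``tau^2`` first.  Power for a two-sided Wald test at level
``alpha`` of the assumed interaction ``lambda`` is

    Phi(-z + lambda/sqrt(v)) + Phi(-z - lambda/sqrt(v)),   z = z_{1-alpha/2},

and the heterogeneity-adjusted analogue replaces the normal distribution
with a t on S-1 degrees of freedom (S informative trials), mirroring the
Hartung-Knapp style acknowledgement that tau would be estimated in
practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trial_aggregates import ModelAssumptions
from .fisher_information import TrialVariance

__all__ = [
    "MetaPowerResult",
    "pool_common",
    "pool_random",
    "wald_power",
    "t_power",
    "weights",
    "per_trial_power",
    "anticipated_ci",
    "analyze",
]


def _values(variances) -> np.ndarray:
    """Float variances from TrialVariance objects or plain numbers."""
    out = []
    for v in variances:
        if isinstance(v, TrialVariance):
            out.append(v.var_interaction if v.finite else np.inf)
        else:
            out.append(float(v))
    return np.asarray(out, dtype=float)


def pool_common(variances) -> float:
    """Summary variance under a common interaction: reciprocal of the sum
    of reciprocal finite trial variances.  Infinite (non-informative)
    variances contribute nothing."""
    return pool_random(variances, tau=0.0)


def pool_random(variances, tau: float) -> float:
    """Random-effects summary variance: each trial's variance is inflated
    by tau^2 before inverse-variance pooling."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    v = _values(variances)
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("no informative trials: all interaction variances are infinite")
    return float(1.0 / np.sum(1.0 / (v[finite] + tau**2)))


def wald_power(lambda_: float, pooled_variance: float, alpha_level: float = 0.05) -> float:
    """Power of the two-sided Wald test for the summary interaction."""
    if pooled_variance <= 0:
        raise ValueError("pooled_variance must be positive")
    z = stats.norm.ppf(1 - alpha_level / 2)
    shift = lambda_ / math.sqrt(pooled_variance)
    return float(stats.norm.cdf(-z + shift) + stats.norm.cdf(-z - shift))


def t_power(
    lambda_: float,
    pooled_variance_random: float,
    n_trials: int,
    alpha_level: float = 0.05,
) -> float:
    """Heterogeneity-adjusted power using a t-distribution on S-1 df.

    ``pooled_variance_random`` must come from :func:`pool_random`;
    ``n_trials`` is S, the number of informative trials.
    """
    if n_trials < 2:
        raise ValueError("t-based power requires at least 2 informative trials")
    if pooled_variance_random <= 0:
        raise ValueError("pooled variance must be positive")
    df = n_trials - 1
    tcrit = stats.t.ppf(1 - alpha_level / 2, df)
    shift = lambda_ / math.sqrt(pooled_variance_random)
    return float(stats.t.cdf(-tcrit + shift, df) + stats.t.cdf(-tcrit - shift, df))


def weights(variances, tau: float = 0.0) -> np.ndarray:
    """Percentage weight of each trial in the pooled estimate.

    Inverse-variance weights (with tau^2 inflation) normalized to sum to
    100 over informative trials; non-informative trials get exactly 0.
    """
    v = _values(variances)
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("no informative trials")
    w = np.zeros_like(v)
    inv = 1.0 / (v[finite] + tau**2)
    w[finite] = 100.0 * inv / inv.sum()
    return w


def per_trial_power(lambda_: float, variances, alpha_level: float = 0.05) -> np.ndarray:
    """Power of each trial analyzed alone (Wald test on its own variance).

    Non-informative trials are reported at the test size alpha — an
    infinitely imprecise estimate rejects at the nominal rate only.
    """
    v = _values(variances)
    out = np.full_like(v, alpha_level)
    for i, vi in enumerate(v):
        if np.isfinite(vi):
            out[i] = wald_power(lambda_, vi, alpha_level)
    return out


def anticipated_ci(
    lambda_: float, pooled_variance: float, alpha_level: float = 0.05
) -> tuple[float, float]:
    """Anticipated two-sided CI for the summary interaction (log scale),
    lambda +/- z_{1-alpha/2} * sqrt(var)."""
    if pooled_variance <= 0:
        raise ValueError("pooled_variance must be positive")
    z = stats.norm.ppf(1 - alpha_level / 2)
    half = z * math.sqrt(pooled_variance)
    return (lambda_ - half, lambda_ + half)


@dataclass(frozen=True)
class MetaPowerResult:
    """Summary of the anticipated IPD meta-analysis.

    Powers are proportions; ``weights`` are percentages (0-100) summing to
    100 over informative trials, keyed and ordered like the input.  CI
    bounds are on the log ratio-of-odds-ratios scale.
    """

    pooled_variance: float
    power: float
    ci_low: float
    ci_high: float
    weights: dict[str, float]
    per_trial_power: dict[str, float]
    n_trials_informative: int
    model: str  # "common" or "random"

    @property
    def ci_ror(self) -> tuple[float, float]:
        """The anticipated CI exponentiated to the ratio-of-odds-ratios scale."""
        return (math.exp(self.ci_low), math.exp(self.ci_high))


def analyze(
    variances: list[TrialVariance],
    assumptions: ModelAssumptions,
) -> MetaPowerResult:
    """Pool per-trial variances and compute power, weights and the CI.

    Uses the common-effect Wald power when ``assumptions.tau == 0`` and the
    random-effects t-based power otherwise.
    """
    ids = [
        tv.trial_id if isinstance(tv, TrialVariance) else str(i)
        for i, tv in enumerate(variances)
    ]
    v = _values(variances)
    n_inf = int(np.isfinite(v).sum())
    lam, alpha = assumptions.lambda_, assumptions.alpha_level
    if assumptions.tau > 0:
        pooled = pool_random(variances, assumptions.tau)
        power = t_power(lam, pooled, n_inf, alpha)
        model = "random"
    else:
        pooled = pool_common(variances)
        power = wald_power(lam, pooled, alpha)
        model = "common"
    lo, hi = anticipated_ci(lam, pooled, alpha)
    w = weights(variances, assumptions.tau)
    p = per_trial_power(lam, variances, alpha)
    return MetaPowerResult(
        pooled_variance=pooled,
        power=power,
        ci_low=lo,
        ci_high=hi,
        weights=dict(zip(ids, w.tolist())),
        per_trial_power=dict(zip(ids, p.tolist())),
        n_trials_informative=n_inf,
        model=model,
    )
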