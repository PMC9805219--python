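"""Per-trial aggregate data and derivation of first-stage model parameters.

A planned IPD (individual participant data) meta-analysis of randomized
trials is powered here from aggregate data only: arm sizes, arm event
counts, and a summary of the covariate whose interaction with treatment is
of interest.  For a binary covariate the summary is the proportion with
``z = 1`` per arm; for a continuous covariate it is the per-arm mean and SD
of an assumed distribution.

From those aggregates each trial's first-stage logistic model

    logit Pr(y=1) = alpha + beta*x + gamma*z + lambda*x*z

gets its intercept ``alpha`` (control-group log-odds of the event, valid at
the trial-mean covariate value after centering) and treatment main effect
``beta`` (the trial's overall log odds ratio).  The prognostic effect
``gamma`` and the interaction ``lambda`` are user assumptions, not data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Union

import pandas as pd

__all__ = [
    "BinaryCovariateSummary",
    "ContinuousCovariateSummary",
    "TrialAggregate",
    "ModelAssumptions",
    "TrialParams",
    "read_trials",
    "derive_alpha",
    "derive_beta",
    "joint_probs_from_margins",
    "trial_params",
]

logger = logging.getLogger(__name__)

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class BinaryCovariateSummary:
    """Joint distribution of arm ``x`` and binary covariate ``z``.

    ``pab`` is Pr(x=a, z=b); the four cells must sum to one.  A trial in
    which ``z`` never (or always) equals 1 — a single-sex trial, say — is
    *degenerate*: the interaction is not identifiable from it.
    """

    p00: float
    p01: float
    p10: float
    p11: float

    def __post_init__(self) -> None:
        probs = (self.p00, self.p01, self.p10, self.p11)
        if any(p < -_PROB_TOL or p > 1 + _PROB_TOL for p in probs):
            raise ValueError(f"joint probabilities must lie in [0, 1]: {probs}")
        if abs(sum(probs) - 1.0) > _PROB_TOL:
            raise ValueError(f"joint probabilities must sum to 1: sum={sum(probs)!r}")

    @property
    def pr_z1(self) -> float:
        return self.p01 + self.p11

    @property
    def pr_x1(self) -> float:
        return self.p10 + self.p11

    @property
    def degenerate(self) -> bool:
        return self.pr_z1 <= _PROB_TOL or self.pr_z1 >= 1 - _PROB_TOL


@dataclass(frozen=True)
class ContinuousCovariateSummary:
    """Assumed per-arm distribution of a continuous covariate.

    ``family`` is ``"normal"`` (mean/SD per arm) or ``"uniform"`` (matched
    to the same mean and SD, i.e. supported on mean +/- sqrt(3)*SD).
    """

    mean_control: float
    sd_control: float
    mean_treat: float
    sd_treat: float
    family: str = "normal"

    def __post_init__(self) -> None:
        if self.family not in ("normal", "uniform"):
            raise ValueError(f"unknown covariate family {self.family!r}")

    @property
    def degenerate(self) -> bool:
        return not (self.sd_control > 0 and self.sd_treat > 0)


Covariate = Union[BinaryCovariateSummary, ContinuousCovariateSummary]


@dataclass(frozen=True)
class TrialAggregate:
    """One randomized trial's published aggregate data.

    ``covariate`` is ``None`` when the trial did not report the covariate
    (it then contributes no information on the interaction, but is kept so
    reports show it with zero weight rather than dropping it silently).
    Optional per-trial ``lambda_override`` / ``gamma_override`` replace the
    global assumptions for this trial only.
    """

    trial_id: str
    n_control: int
    n_treat: int
    e_control: int
    e_treat: int
    covariate: Covariate | None = None
    lambda_override: float | None = None
    gamma_override: float | None = None

    def __post_init__(self) -> None:
        if self.n_control + self.n_treat <= 0:
            raise ValueError(f"trial {self.trial_id}: total sample size must be positive")
        if not (0 <= self.e_control <= self.n_control):
            raise ValueError(
                f"trial {self.trial_id}: e_control={self.e_control} outside "
                f"[0, n_control={self.n_control}]"
            )
        if not (0 <= self.e_treat <= self.n_treat):
            raise ValueError(
                f"trial {self.trial_id}: e_treat={self.e_treat} outside "
                f"[0, n_treat={self.n_treat}]"
            )

    @property
    def n(self) -> int:
        return self.n_control + self.n_treat

    @property
    def informative(self) -> bool:
        """Whether the trial can contribute to the interaction estimate."""
        return self.covariate is not None and not self.covariate.degenerate


@dataclass(frozen=True)
class ModelAssumptions:
    """User-specified effect sizes and test settings shared by all trials.

    lambda_
        Assumed interaction: change in treatment log odds ratio per one
        covariate unit (exp(lambda) is a ratio of odds ratios).
    gamma
        Prognostic log odds ratio of the covariate per unit; zero by
        default, as it is rarely known in advance.
    tau
        Between-trial SD of the true interaction; zero means a common
        interaction across trials.
    alpha_level
        Two-sided significance level of the Wald (or t) test.
    """

    lambda_: float
    gamma: float = 0.0
    tau: float = 0.0
    alpha_level: float = 0.05

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must lie strictly between 0 and 1")


@dataclass(frozen=True)
class TrialParams:
    """First-stage logistic parameters (alpha, beta, gamma, lambda) for one trial."""

    alpha: float
    beta: float
    gamma: float
    lambda_: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "lambda_"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def derive_alpha(e_control: int, n_control: int, continuity: bool = False) -> float:
    """Control-group log-odds of the event, log(e/(n-e)).

    With mean-centering of the covariate this approximates the model
    intercept.  ``continuity`` adds 0.5 to both cells when e is 0 or n
    (otherwise such counts are an error, so the caller must opt in).
    """
    if not 0 <= e_control <= n_control or n_control <= 0:
        raise ValueError(f"invalid counts e={e_control}, n={n_control}")
    e, ne = float(e_control), float(n_control - e_control)
    if e == 0 or ne == 0:
        if not continuity:
            raise ValueError(
                f"zero cell (e={e_control}, n={n_control}): pass continuity=True "
                "to apply a 0.5 correction"
            )
        e, ne = e + 0.5, ne + 0.5
    return math.log(e / ne)


def derive_beta(
    e_control: int,
    n_control: int,
    e_treat: int,
    n_treat: int,
    continuity: bool = False,
) -> float:
    """Overall treatment log odds ratio from the trial 2x2 table.

    ``continuity`` adds 0.5 to all four cells when any cell is zero.
    """
    cells = [
        float(e_treat),
        float(n_treat - e_treat),
        float(e_control),
        float(n_control - e_control),
    ]
    if any(c < 0 for c in cells):
        raise ValueError("event counts exceed arm sizes")
    if any(c == 0 for c in cells):
        if not continuity:
            raise ValueError(
                "zero cell in the 2x2 table: pass continuity=True to apply a "
                "0.5 correction"
            )
        cells = [c + 0.5 for c in cells]
    et, net, ec, nec = cells
    return math.log((et / net) / (ec / nec))


def joint_probs_from_margins(
    n_control: int,
    n_treat: int,
    prop_z1_control: float,
    prop_z1_treat: float | None = None,
) -> BinaryCovariateSummary:
    """Joint Pr(x=a, z=b) from arm sizes and per-arm covariate prevalence.

    If only an overall prevalence is available, pass it as
    ``prop_z1_control`` and omit ``prop_z1_treat``: randomization justifies
    assuming the same proportion in both arms.
    """
    if prop_z1_treat is None:
        prop_z1_treat = prop_z1_control
    for q in (prop_z1_control, prop_z1_treat):
        if not 0 <= q <= 1:
            raise ValueError(f"proportion {q!r} outside [0, 1]")
    n = n_control + n_treat
    fc, ft = n_control / n, n_treat / n
    return BinaryCovariateSummary(
        p00=fc * (1 - prop_z1_control),
        p01=fc * prop_z1_control,
        p10=ft * (1 - prop_z1_treat),
        p11=ft * prop_z1_treat,
    )


def trial_params(
    trial: TrialAggregate,
    assumptions: ModelAssumptions,
    continuity: bool = False,
) -> TrialParams:
    """Assemble (alpha, beta, gamma, lambda) for one trial.

    alpha and beta come from the trial's own counts; gamma and lambda from
    the global assumptions unless the trial carries per-trial overrides.
    """
    lam = trial.lambda_override if trial.lambda_override is not None else assumptions.lambda_
    gam = trial.gamma_override if trial.gamma_override is not None else assumptions.gamma
    return TrialParams(
        alpha=derive_alpha(trial.e_control, trial.n_control, continuity),
        beta=derive_beta(
            trial.e_control, trial.n_control, trial.e_treat, trial.n_treat, continuity
        ),
        gamma=gam,
        lambda_=lam,
    )


_COUNT_COLUMNS = ["trial_id", "n_control", "e_control", "n_treat", "e_treat"]
_BINARY_COLUMNS = ["prop_z1_control", "prop_z1_treat"]
_CONTINUOUS_COLUMNS = ["mean_control", "sd_control", "mean_treat", "sd_treat"]


def _binary_covariate(row: pd.Series, n_c: int, n_t: int, scale: float) -> Covariate | None:
    if "prop_z1_overall" in row.index and not pd.isna(row.get("prop_z1_overall")):
        return joint_probs_from_margins(n_c, n_t, float(row["prop_z1_overall"]) / scale)
    qc, qt = row.get("prop_z1_control"), row.get("prop_z1_treat")
    if pd.isna(qc) and pd.isna(qt):
        return None
    if pd.isna(qc) or pd.isna(qt):
        # one arm reported: assume the same prevalence in both
        q = float(qt if pd.isna(qc) else qc) / scale
        return joint_probs_from_margins(n_c, n_t, q)
    return joint_probs_from_margins(n_c, n_t, float(qc) / scale, float(qt) / scale)


def _continuous_covariate(row: pd.Series, default_family: str) -> Covariate | None:
    vals = [row.get(c) for c in _CONTINUOUS_COLUMNS]
    if any(pd.isna(v) for v in vals):
        return None
    family = default_family
    if "dist" in row.index and not pd.isna(row.get("dist")):
        family = str(row["dist"]).strip().lower()
    mc, sc, mt, st = (float(v) for v in vals)
    return ContinuousCovariateSummary(mc, sc, mt, st, family=family)


def read_trials(
    path,
    covariate_kind: str,
    *,
    sep: str = ",",
    percent_scale: str = "percent",
    dist: str = "normal",
) -> list[TrialAggregate]:
    """Read per-trial aggregate data from a delimited file.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.  Required columns: ``trial_id``,
        ``n_control``, ``e_control``, ``n_treat``, ``e_treat``; plus, for
        ``covariate_kind="binary"``, ``prop_z1_control``/``prop_z1_treat``
        (or ``prop_z1_overall``), and for ``"continuous"``,
        ``mean_control``/``sd_control``/``mean_treat``/``sd_treat`` with an
        optional ``dist`` column.  Optional ``lambda``/``gamma`` columns
        give per-trial overrides.  Empty cells or ``NA`` mean missing.
    covariate_kind
        ``"binary"`` or ``"continuous"``.
    percent_scale
        ``"percent"`` (0-100, the convention of most baseline tables) or
        ``"proportion"`` (0-1) for the binary-prevalence columns.
    dist
        Default distribution family for continuous covariates.

    Rows whose covariate summary is missing are kept with
    ``covariate=None`` and a logged warning; count inconsistencies raise.
    """
    if covariate_kind not in ("binary", "continuous"):
        raise ValueError(f"covariate_kind must be 'binary' or 'continuous', got {covariate_kind!r}")
    if percent_scale not in ("percent", "proportion"):
        raise ValueError("percent_scale must be 'percent' or 'proportion'")
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""], skipinitialspace=True)
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if covariate_kind == "binary" and "prop_z1_overall" not in df.columns:
        missing += [c for c in _BINARY_COLUMNS if c not in df.columns]
    if covariate_kind == "continuous":
        missing += [c for c in _CONTINUOUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("%s: no data rows", path)
        return []

    scale = 100.0 if percent_scale == "percent" else 1.0
    # iterrows() upcasts mixed-dtype rows; keep ids from the raw column
    ids = df["trial_id"].astype(str).tolist()
    trials: list[TrialAggregate] = []
    for trial_id, (_, row) in zip(ids, df.iterrows()):
        n_c, n_t = int(row["n_control"]), int(row["n_treat"])
        if covariate_kind == "binary":
            cov = _binary_covariate(row, n_c, n_t, scale)
        else:
            cov = _continuous_covariate(row, dist)
        if cov is None:
            logger.warning("trial %s: covariate summary missing; retained with zero weight", trial_id)
        elif cov.degenerate:
            logger.warning("trial %s: degenerate covariate (no variation); zero weight", trial_id)
        lam = row.get("lambda")
        gam = row.get("gamma")
        trials.append(
            TrialAggregate(
                trial_id=trial_id,
                n_control=n_c,
                n_treat=n_t,
                e_control=int(row["e_control"]),
                e_treat=int(row["e_treat"]),
                covariate=cov,
                lambda_override=None if lam is None or pd.isna(lam) else float(lam),
                gamma_override=None if gam is None or pd.isna(gam) else float(gam),
            )
        )
    return trials
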