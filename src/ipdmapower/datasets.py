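"""Bundled example aggregate-data tables.

Two published IPD meta-analysis projects, shipped as the aggregate data a
planner would extract from trial publications:

* ``poynard`` — 4 randomized trials of beta-adrenergic-antagonist drugs to
  prevent gastrointestinal bleeding in cirrhosis (Poynard et al.), with
  per-arm counts, % male and age mean/SD.
* ``steer_oa`` — 31 randomized trials of exercise interventions for knee
  and/or hip osteoarthritis (the STEER-OA project); the binary outcome is
  reporting pain at 3-6 months.  Two trials did not record sex and one
  recruited women only.
"""

from __future__ import annotations

from importlib import resources

from .trial_aggregates import TrialAggregate, read_trials

__all__ = ["poynard_path", "steer_oa_path", "poynard", "steer_oa"]


def _data_path(name: str):
    return resources.files("ipdmapower.data").joinpath(name)


def poynard_path():
    """Path to the 4-trial beta-blocker aggregate-data CSV."""
    return _data_path("poynard.csv")


def steer_oa_path():
    """Path to the 31-trial STEER-OA aggregate-data CSV."""
    return _data_path("steer_oa.csv")


def poynard(covariate_kind: str = "binary") -> list[TrialAggregate]:
    """The 4 beta-blocker trials; ``covariate_kind`` selects sex ("binary")
    or age ("continuous")."""
    with resources.as_file(poynard_path()) as p:
        return read_trials(p, covariate_kind)


def steer_oa(covariate_kind: str = "binary") -> list[TrialAggregate]:
    """The 31 STEER-OA trials; ``covariate_kind`` selects sex ("binary")
    or age ("continuous")."""
    with resources.as_file(steer_oa_path()) as p:
        return read_trials(p, covariate_kind)
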