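import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipdmapower import (
    BinaryCovariateSummary,
    ContinuousCovariateSummary,
    ModelAssumptions,
    TrialAggregate,
    datasets,
    derive_alpha,
    derive_beta,
    joint_probs_from_margins,
    read_trials,
    trial_params,
)

counts = st.integers(min_value=1, max_value=500)


@pytest.mark.parametrize(
    "e, n, expected",
    [(30, 112, math.log(30 / 82)), (5, 10, 0.0), (1, 2, 0.0)],
)
def test_derive_alpha_is_control_log_odds(e, n, expected):
    assert derive_alpha(e, n) == pytest.approx(expected, abs=1e-12)


def test_derive_alpha_zero_cells_require_continuity():
    with pytest.raises(ValueError, match="continuity"):
        derive_alpha(0, 50)
    assert derive_alpha(0, 50, continuity=True) == pytest.approx(
        math.log(0.5 / 50.5), abs=1e-12
    )
    assert derive_alpha(0, 50, continuity=True) == pytest.approx(-4.61512, abs=1e-5)
    with pytest.raises(ValueError, match="continuity"):
        derive_alpha(50, 50)


@pytest.mark.parametrize(
    "args, expected",
    [
        ((30, 112, 19, 118), math.log((19 / 99) / (30 / 82))),  # beta-blocker trial 1
        ((13, 53, 13, 53), 0.0),  # identical arms => null log OR
        ((10, 40, 20, 80), 0.0),  # equal risks, different sizes
    ],
)
def test_derive_beta_log_odds_ratio(args, expected):
    assert derive_beta(*args) == pytest.approx(expected, abs=1e-5)


def test_derive_beta_zero_cell_continuity():
    with pytest.raises(ValueError, match="continuity"):
        derive_beta(11, 49, 0, 30)
    corrected = derive_beta(11, 49, 0, 30, continuity=True)
    assert corrected == pytest.approx(
        math.log((0.5 / 30.5) / (11.5 / 38.5)), abs=1e-12
    )


@settings(max_examples=100, derandomize=True)
@given(ec=counts, nc=counts, et=counts, nt=counts)
def test_derive_beta_antisymmetric_under_arm_swap(ec, nc, et, nt):
    ec, et = min(ec, nc - 1) or 1, min(et, nt - 1) or 1
    nc, nt = max(nc, ec + 1), max(nt, et + 1)
    assert derive_beta(ec, nc, et, nt) == pytest.approx(
        -derive_beta(et, nt, ec, nc), abs=1e-12
    )


def test_joint_probs_worked_example():
    p = joint_probs_from_margins(112, 118, 0.71, 0.71)
    assert (p.p00, p.p01, p.p10, p.p11) == pytest.approx(
        (0.14122, 0.34574, 0.14878, 0.36426), abs=5e-6
    )


@settings(max_examples=100, derandomize=True)
@given(
    nc=counts,
    nt=counts,
    qc=st.floats(0, 1, allow_nan=False),
    qt=st.floats(0, 1, allow_nan=False),
)
def test_joint_probs_sum_to_one_and_match_arm_margin(nc, nt, qc, qt):
    p = joint_probs_from_margins(nc, nt, qc, qt)
    assert p.p00 + p.p01 + p.p10 + p.p11 == pytest.approx(1.0, abs=1e-9)
    assert p.pr_x1 == pytest.approx(nt / (nc + nt), abs=1e-12)


def test_joint_probs_overall_fallback_and_degenerate_flag():
    same = joint_probs_from_margins(50, 50, 0.4)
    split = joint_probs_from_margins(50, 50, 0.4, 0.4)
    assert same == split
    assert joint_probs_from_margins(50, 50, 0.5, 0.5) == BinaryCovariateSummary(
        0.25, 0.25, 0.25, 0.25
    )
    degenerate = joint_probs_from_margins(50, 50, 0.0, 0.0)
    assert degenerate.p01 == degenerate.p11 == 0.0
    assert degenerate.degenerate


def test_trial_aggregate_count_invariants():
    with pytest.raises(ValueError, match="e_control"):
        TrialAggregate("t", n_control=10, n_treat=10, e_control=11, e_treat=0)
    with pytest.raises(ValueError, match="positive"):
        TrialAggregate("t", n_control=0, n_treat=0, e_control=0, e_treat=0)


def test_model_assumptions_validation():
    with pytest.raises(ValueError):
        ModelAssumptions(lambda_=0.1, tau=-0.1)
    with pytest.raises(ValueError):
        ModelAssumptions(lambda_=0.1, alpha_level=1.0)


def test_read_trials_poynard_binary(poynard_sex_trials):
    trials = poynard_sex_trials
    assert len(trials) == 4
    t1 = trials[0]
    assert (t1.n_control, t1.e_control, t1.n_treat, t1.e_treat) == (112, 30, 118, 19)
    # percent columns are rescaled to proportions
    assert t1.covariate.pr_z1 == pytest.approx(0.71, abs=1e-12)
    assert all(t.informative for t in trials)


def test_read_trials_steer_missing_and_degenerate(steer_sex_trials):
    trials = steer_sex_trials
    assert len(trials) == 31
    by_id = {t.trial_id: t for t in trials}
    assert by_id["18"].covariate is None and by_id["19"].covariate is None
    assert by_id["20"].covariate is not None and by_id["20"].covariate.degenerate
    assert sum(not t.informative for t in trials) == 3


def test_read_trials_roundtrip_preserves_counts(tmp_path):
    for path in (datasets.poynard_path(), datasets.steer_oa_path()):
        src = pd.read_csv(path)
        trials = read_trials(path, "binary")
        out = pd.DataFrame(
            {
                "trial_id": [t.trial_id for t in trials],
                "n_control": [t.n_control for t in trials],
                "e_control": [t.e_control for t in trials],
                "n_treat": [t.n_treat for t in trials],
                "e_treat": [t.e_treat for t in trials],
            }
        )
        for col in ["n_control", "e_control", "n_treat", "e_treat"]:
            assert (out[col].to_numpy() == src[col].to_numpy()).all()


def test_read_trials_errors_and_edge_cases(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("trial_id,n_control,e_control,n_treat\n1,10,2,10\n")
    with pytest.raises(ValueError, match="e_treat"):
        read_trials(p, "binary")

    p2 = tmp_path / "inconsistent.csv"
    p2.write_text(
        "trial_id,n_control,e_control,n_treat,e_treat,prop_z1_control,prop_z1_treat\n"
        "tX,10,12,10,1,50,50\n"
    )
    with pytest.raises(ValueError, match="tX"):
        read_trials(p2, "binary")

    empty = tmp_path / "empty.csv"
    empty.write_text(
        "trial_id,n_control,e_control,n_treat,e_treat,prop_z1_control,prop_z1_treat\n"
    )
    assert read_trials(empty, "binary") == []


def test_read_trials_proportion_scale_and_overall_column(tmp_path):
    p = tmp_path / "props.csv"
    p.write_text(
        "trial_id,n_control,e_control,n_treat,e_treat,prop_z1_overall\n1,50,10,50,12,0.4\n"
    )
    (trial,) = read_trials(p, "binary", percent_scale="proportion")
    assert trial.covariate.pr_z1 == pytest.approx(0.4, abs=1e-12)


def test_read_trials_continuous_with_dist_and_overrides(tmp_path):
    p = tmp_path / "cont.csv"
    p.write_text(
        "trial_id,n_control,e_control,n_treat,e_treat,"
        "mean_control,sd_control,mean_treat,sd_treat,dist,lambda,gamma\n"
        "1,50,10,50,12,60,8,61,9,uniform,0.05,\n"
        "2,40,9,40,11,62,7,63,8,,,0.1\n"
    )
    trials = read_trials(p, "continuous")
    assert isinstance(trials[0].covariate, ContinuousCovariateSummary)
    assert trials[0].covariate.family == "uniform"
    assert trials[1].covariate.family == "normal"
    asm = ModelAssumptions(lambda_=0.02, gamma=0.0)
    p1 = trial_params(trials[0], asm)
    p2 = trial_params(trials[1], asm)
    assert p1.lambda_ == 0.05 and p1.gamma == 0.0
    assert p2.lambda_ == 0.02 and p2.gamma == 0.1
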