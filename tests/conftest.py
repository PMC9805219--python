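import math

import numpy as np
import pytest

from ipdmapower import ModelAssumptions, datasets
from ipdmapower.cli import compute_trial_variances

# Assumed interaction sizes used throughout: a 30% higher treatment odds
# ratio for males vs females, and the same 30% spread over a 10-year age
# difference (so per-year lambda = log(1.3)/10).
LAMBDA_SEX = math.log(1.3)
LAMBDA_AGE = math.log(1.3) / 10


@pytest.fixture(scope="session")
def poynard_sex_trials():
    return datasets.poynard("binary")


@pytest.fixture(scope="session")
def poynard_age_trials():
    return datasets.poynard("continuous")


@pytest.fixture(scope="session")
def steer_sex_trials():
    return datasets.steer_oa("binary")


@pytest.fixture(scope="session")
def steer_age_trials():
    return datasets.steer_oa("continuous")


@pytest.fixture(scope="session")
def poynard_sex_variances(poynard_sex_trials):
    asm = ModelAssumptions(lambda_=LAMBDA_SEX)
    return compute_trial_variances(poynard_sex_trials, asm)


@pytest.fixture(scope="session")
def steer_age_variances(steer_age_trials):
    """Per-trial age-interaction variances at the default Monte-Carlo size."""
    asm = ModelAssumptions(lambda_=LAMBDA_AGE)
    return compute_trial_variances(steer_age_trials, asm, seed=2022)
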