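"""Shared fixtures: small synthetic cohorts and (expensive) calibrated fits.

The calibration fixtures are session-scoped because an MCMC-SAEM fit is by
far the most expensive object in the suite; every test that needs a fitted
map shares the same run.
"""

import numpy as np
import pytest

from coursemap import calibrate, generate_cohort, make_ground_truth_map
from coursemap.calibration import SAEMConfig


@pytest.fixture(scope="session")
def easy_truth():
    return make_ground_truth_map(3, seed=5)


@pytest.fixture(scope="session")
def easy_cohort(easy_truth):
    cohort, covariates = generate_cohort(easy_truth, 60, visits_per_subject=4, seed=2)
    return cohort, covariates


@pytest.fixture(scope="session")
def easy_config():
    return SAEMConfig(n_iter=1200, n_burn_in=700, seed=1)


@pytest.fixture(scope="session")
def easy_fit(easy_cohort, easy_config):
    cohort, _ = easy_cohort
    with np.errstate(all="ignore"):
        cmap, effects, trace = calibrate(cohort.data, easy_config)
    return cmap, effects, trace


@pytest.fixture(scope="session")
def recovery_truth():
    truth = make_ground_truth_map(4, seed=7)
    truth.sigma_noise = 0.05
    return truth


@pytest.fixture(scope="session")
def recovery_cohort(recovery_truth):
    cohort, covariates = generate_cohort(
        recovery_truth, 200, visits_per_subject=5, seed=11
    )
    return cohort, covariates


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort):
    cohort, _ = recovery_cohort
    with np.errstate(all="ignore"):
        cmap, effects, trace = calibrate(cohort.data, SAEMConfig(seed=3))
    return cmap, effects, trace
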