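"""Shared fixtures: small seed-controlled synthetic cohorts.

Session-scoped so the (cheap but not free) waveform rendering and detection
run once per test session.
"""

import dataclasses

import pytest

from pttbp.config import RunConfig
from pttbp.pipeline import collect_subject_data, fit_and_calibrate
from pttbp.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def short_config() -> CohortConfig:
    """Default study conditions at a 60 s recording length."""
    return dataclasses.replace(CohortConfig(), duration_s=60.0)


@pytest.fixture(scope="session")
def noise_free_cohort(short_config):
    """4 rendered subjects with every stochastic dial at zero."""
    return generate_cohort(4, short_config.noise_free(), seed=21)


@pytest.fixture(scope="session")
def default_cohort(short_config):
    """8 rendered subjects under the default (noisy, heterogeneous) cohort."""
    return generate_cohort(8, short_config, seed=3)


@pytest.fixture(scope="session")
def calibrated_default(default_cohort):
    """Profiles + population coefficients for the default cohort."""
    run = RunConfig(population_fit_scope="pooled")
    data, _ = collect_subject_data(default_cohort.sessions, run)
    return fit_and_calibrate(data, run)
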