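import numpy as np
import pytest

from reachatten.config import (
    DesignConfig,
    PopulationConfig,
    SegmentationParams,
)
from reachatten.synthetic_data import simulate_cohort


def noise_free_population(**overrides) -> PopulationConfig:
    """Population with every noise source and SD set to zero.

    Every participant is identical and every trial deterministic: reaction
    time 220 ms, duration 542 ms, exact 2 N test forces, default
    attenuation profile.
    """
    kwargs = dict(
        rt_between_sd_ms=0.0,
        rt_within_sd_ms=0.0,
        duration_between_sd_ms=0.0,
        duration_within_sd_mean_ms=0.0,
        duration_within_sd_sd_ms=0.0,
        kinematic_noise_sd_cm=0.0,
        force_noise_sd_n=0.0,
        baseline_pse_sd_n=0.0,
        baseline_jnd_sd_n=0.0,
        slope_sd=0.0,
        dip_sd=0.0,
        residual_sd=0.0,
    )
    kwargs.update(overrides)
    return PopulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_design() -> DesignConfig:
    return DesignConfig(reps_per_reaching_type=4, reps_baseline=2)


@pytest.fixture(scope="session")
def seg_params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture(scope="session")
def clean_trace_cohort(small_design):
    """Noise-free full-trace cohort: deterministic, passes every QC filter."""
    return simulate_cohort(
        3,
        design=small_design,
        population=noise_free_population(),
        seed=11,
        trace_mode="full",
    )


@pytest.fixture(scope="session")
def default_lm_cohort(small_design):
    """Default-noise landmark-mode cohort for distributional checks."""
    return simulate_cohort(
        6, design=small_design, seed=7, trace_mode="landmarks"
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
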