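import dataclasses

import pytest
from hypothesis import settings

import brainagebp as bab

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture()
def small_config():
    """A quick-to-simulate cohort: 40 subjects, 4 waves, low-dim features."""
    return bab.SimulationConfig(n_ma=20, n_oa=20, feature_dim=30, n_latent=2,
                                seed=7)


@pytest.fixture()
def small_cohort(small_config):
    subjects, visits = bab.build_design(small_config, seed=7)
    visits = bab.simulate_bp(subjects, visits, small_config, seed=7)
    return subjects, visits


@pytest.fixture()
def noise_free_config():
    """Deterministic generator limit: no slope spread, no reading noise."""
    return dataclasses.replace(
        bab.SimulationConfig(n_ma=10, n_oa=10, seed=3),
        map_slope_sd=0.0, sbp_slope_sd=0.0, reading_noise_sd=0.0,
        wave_jitter_sd=0.0, wave_jitter_mean=0.0,
    )
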