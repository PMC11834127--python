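"""Shared fixtures: small synthetic cohorts and deterministic RNGs."""

import numpy as np
import pytest

from asemlab import AnalysisConfig, SimulationConfig, simulate_cohort
from asemlab.config import LatencyPopulation


@pytest.fixture(scope="session")
def analysis_cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def clean_sim_cfg():
    """Noise-free, event-free configuration: the generative identity case."""
    return SimulationConfig(
        n_participants=2, trials_per_cell=1, seed=42,
        asem_trial_sd=0.0, noise_sd_eye=0.0, noise_sd_cursor=0.0,
        aim_error_sd=0.0, saccade_rate=0.0, blink_prob=0.0,
    )


@pytest.fixture(scope="session")
def clean_cohort(clean_sim_cfg):
    return simulate_cohort(clean_sim_cfg)


@pytest.fixture(scope="session")
def noisy_sim_cfg():
    return SimulationConfig(n_participants=3, trials_per_cell=3, seed=7)


@pytest.fixture(scope="session")
def noisy_cohort(noisy_sim_cfg):
    return simulate_cohort(noisy_sim_cfg)


@pytest.fixture(scope="session")
def recovery_latency_population():
    """Coupling-identified latency model: no coherence-certainty component.

    With the Gaussian-of-coherence amplitude at zero the only path from
    coherence to latency runs through ASEM velocity, so regressions of
    latency on signed ASEM velocity estimate the generative beta1.
    """
    return LatencyPopulation(c=(0.0, 0.0), beta1=(-0.03, 0.01))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
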