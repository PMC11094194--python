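import numpy as np
import pytest

from sprde.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_sim_config():
    """Deterministic generator: template surface only, no stochastic effects."""
    return SimulationConfig(
        noise_sigma=0.0,
        dropout=0.0,
        pos_jitter_row=0.0,
        pos_jitter_col=0.0,
        amp_jitter=0.0,
        spill_gain=0.0,
        frame_gain_range=(1.0, 1.0),
        baseline_range=(0.0, 0.0),
        seed=0,
    )


@pytest.fixture
def tiny_cohort_config():
    """Four subjects, four frames each: enough for end-to-end smoke runs."""
    return SimulationConfig(n_subjects=4, frames_per_subject=4, seed=7)
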