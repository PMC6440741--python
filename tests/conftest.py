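import numpy as np
import pytest

from somabms import PsychometricFit, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fit240():
    """Observer matching the group-mean calibration anchors."""
    return PsychometricFit(t50=2.40, slope=2.05)


@pytest.fixture
def fast_sim_config():
    """One-run reduced-trial configuration for quick simulation tests."""
    return SimulationConfig(n_runs=1, n_subjects=2, seed=7)
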