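import numpy as np
import pytest

from psyfusion.synthetic import BandSpec, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Short 2-subject session config for fast structural tests."""
    return SimConfig(n_subjects=2, n_volumes=120, injection_index=30, seed=7)


@pytest.fixture
def quiet_eeg_cfg():
    """Short EEG-only config with no oscillators (pure 1/f background)."""
    return SimConfig(
        n_volumes=120, injection_index=30, seed=9,
        bands=BandSpec(amplitudes={b: 0.0 for b in ("delta", "theta", "alpha", "beta", "gamma")}),
    )
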