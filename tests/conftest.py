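import numpy as np
import pytest

from neurostates.preprocess import BoldMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def piecewise_data(n_states: int, state_len: int, n_voxels: int, seed: int = 0,
                   noise_sd: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant pattern matrix and its planted 1-based boundaries."""
    r = np.random.default_rng(seed)
    patterns = r.standard_normal((n_states, n_voxels))
    labels = np.repeat(np.arange(n_states), state_len)
    x = patterns[labels] + noise_sd * r.standard_normal((n_states * state_len, n_voxels))
    boundaries = np.arange(1, n_states) * state_len + 1
    return x, boundaries


@pytest.fixture
def three_state_data():
    x, b = piecewise_data(n_states=3, state_len=10, n_voxels=10, seed=3)
    return x, b


@pytest.fixture
def bold(rng):
    return BoldMatrix(values=rng.standard_normal((60, 8)), tr=2.47)
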