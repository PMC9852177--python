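import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ecdf_sup_distance(draws: np.ndarray, grid: np.ndarray, cdf_values: np.ndarray) -> float:
    """Sup distance between the empirical cdf of draws and a reference cdf
    evaluated on a grid."""
    emp = np.searchsorted(np.sort(draws), grid, side="right") / draws.size
    return float(np.abs(emp - np.asarray(cdf_values)).max())
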