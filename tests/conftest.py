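import numpy as np
import pytest

from guidedreading.materials import default_texts
from guidedreading.simulator import SimReaderParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def texts():
    return default_texts(0)


@pytest.fixture
def step_reader():
    """Deterministic threshold reader: span 3 at 350 ms."""
    return SimReaderParams(true_span=3, threshold_time_ms=350.0)


def brute_force_edit_distance(a: str, b: str) -> int:
    """Independent oracle: plain recursive edit distance with memo."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == len(a):
            return len(b) - j
        if j == len(b):
            return len(a) - i
        return min(
            d(i + 1, j + 1) + (a[i] != b[j]),
            d(i + 1, j) + 1,
            d(i, j + 1) + 1,
        )

    return d(0, 0)
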