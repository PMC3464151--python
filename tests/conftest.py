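import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20120806)


def random_dataset(rng, n, kind="float"):
    """Small random data sets for oracle grids: floats, tied integers, or
    arithmetic progressions (equal central gaps)."""
    if kind == "int":
        return rng.integers(0, 6, size=n).astype(float)
    if kind == "progression":
        step = float(rng.integers(1, 5))
        return np.arange(n, dtype=float) * step
    return rng.uniform(0.0, 100.0, size=n)
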