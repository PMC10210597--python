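import numpy as np
import pytest

from envsca import CategoricalSeries, case_params, simulate_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_series():
    """A short deterministic 3-state series."""
    return CategoricalSeries(
        values=["a", "b", "c", "a", "b", "c", "a", "b"],
        state_space=("a", "b", "c"),
    )


@pytest.fixture
def case1_series():
    """One moderately long series from the slow-cycling preset group."""
    return simulate_series(case_params(1, 1), 400, np.random.default_rng(7))


def random_series(rng, T, m=3):
    space = tuple(f"s{i}" for i in range(m))
    vals = [space[i] for i in rng.integers(0, m, size=T)]
    return CategoricalSeries(values=vals, state_space=space)
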