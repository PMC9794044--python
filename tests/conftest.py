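import numpy as np
import pytest

from hawkdove.population import build_population


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def make_population():
    """Factory for small populations from per-group strategy lists."""

    def _make(group_strategies, capacity=10_000, **kwargs):
        return build_population(
            group_strategies, capacity=capacity, **kwargs
        )

    return _make
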