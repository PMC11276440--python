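import numpy as np
import pytest

from alfaspec import SpectraSet, WavenumberAxis


@pytest.fixture
def tiny_axis() -> WavenumberAxis:
    return WavenumberAxis(np.array([2000.0, 1500.0, 1000.0]))


@pytest.fixture
def tiny_set(tiny_axis) -> SpectraSet:
    X = np.array([[0.1, 0.5, 0.2], [0.3, 0.7, 0.4]])
    return SpectraSet(
        axis=tiny_axis,
        X=X,
        sample_ids=("a", "b"),
        y=np.array([9.5, 12.0]),
        mode="absorbance",
    )


def make_set(n: int = 8, p: int = 40, seed: int = 0) -> SpectraSet:
    """Small random absorbance set with a linear y-signal for model tests."""
    rng = np.random.default_rng(seed)
    axis = WavenumberAxis(np.linspace(4000.0, 400.0, p))
    signal = np.exp(-0.5 * ((axis.values - 1630.0) / 120.0) ** 2)
    y = rng.uniform(9.0, 22.0, size=n)
    X = np.outer(y / 15.0, signal) + 0.01 * rng.normal(size=(n, p))
    return SpectraSet(
        axis=axis,
        X=X,
        sample_ids=tuple(f"s{i}" for i in range(n)),
        y=y,
        mode="absorbance",
    )
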