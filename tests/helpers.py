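import numpy as np

from alfaspec import SpectraSet, WavenumberAxis


def small_noisy_set(n: int = 4, p: int = 120, seed: int = 5) -> SpectraSet:
    """Absorbance set with a peak, a sloping baseline and mild noise."""
    rng = np.random.default_rng(seed)
    axis = WavenumberAxis(np.linspace(4000.0, 400.0, p))
    u = (axis.values - 400.0) / 3600.0
    X = np.empty((n, p))
    y = rng.uniform(9.0, 22.0, size=n)
    for i in range(n):
        X[i] = (
            0.2
            + 0.1 * u
            + (y[i] / 15.0) * np.exp(-0.5 * ((axis.values - 1630.0) / 80.0) ** 2)
            + 0.005 * rng.normal(size=p)
        )
    return SpectraSet(
        axis=axis,
        X=X,
        sample_ids=tuple(f"s{i}" for i in range(n)),
        y=y,
        mode="absorbance",
    )
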