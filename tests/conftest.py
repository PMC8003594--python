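import numpy as np
import pytest

from tracedose import PKModel, TimeActivitySeries, predict

#: serial-sacrifice design: 3 animals at each of 1, 3, 6, 24, 72 h
TIMEPOINTS = np.array([1.0, 3.0, 6.0, 24.0, 72.0])
T_GRID = np.repeat(TIMEPOINTS, 3)
ANIMALS = tuple(f"t{t:g}_m{i % 3 + 1}" for i, t in enumerate(T_GRID))


def make_series(
    model: PKModel,
    cv: float = 0.0,
    seed: int = 0,
    organ: str = "organ",
    t=T_GRID,
    animals=ANIMALS,
) -> TimeActivitySeries:
    """%IA/g series from a ground-truth model with median-preserving
    multiplicative lognormal noise."""
    y = predict(model, t)
    if cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log(1.0 + cv * cv))
        y = y * np.exp(sigma * rng.standard_normal(len(t)))
    return TimeActivitySeries(organ, t, y, animals)


@pytest.fixture
def biexp_truth() -> PKModel:
    return PKModel("biexp", (5.0, 0.8, 1.0, 0.02))


@pytest.fixture
def uw_truth() -> PKModel:
    return PKModel("uptake_washout", (30.4, 0.74, 0.0087))
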