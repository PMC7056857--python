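import numpy as np
import pytest

from somscape import (
    TrainingMatrix,
    build_lattice,
    map_assignments,
    three_group_fixture,
    train_som,
    two_blob_fixture,
)


@pytest.fixture(scope="session")
def butterfly_two_blob():
    """Two well-separated blobs trained on a butterfly map (seed 7)."""
    data, labels = two_blob_fixture(seed=7)
    lat = build_lattice("butterfly", 4)
    tm = train_som(data, lat, seed=7)
    hits = map_assignments(tm, data)
    return data, labels, tm, hits


@pytest.fixture(scope="session")
def trefoil_three_group():
    """Three equidistant groups trained on a trefoil map (seed 11)."""
    data, labels = three_group_fixture(seed=11)
    lat = build_lattice("trefoil", 4)
    tm = train_som(data, lat, seed=11)
    hits = map_assignments(tm, data)
    return data, labels, tm, hits


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(30, 3))
    return TrainingMatrix(X, [f"g{i}" for i in range(30)], ["a", "b", "c"])
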