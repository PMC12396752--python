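import numpy as np
import pytest

from ocotillo.objectives import LabelledTable
from ocotillo.synthetic import GeneratorSpec, make_feature_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_table():
    """The generator's default planted-feature table (n=400, d=12, k=3, r=3)."""
    table, truth = make_feature_table(GeneratorSpec())
    return table, truth


@pytest.fixture(scope="session")
def two_class_table():
    """A small two-class table with strong separation along the informative axes."""
    spec = GeneratorSpec(n_samples=100, n_features=6, n_informative=2, n_redundant=2,
                         n_classes=2, class_separation=8.0, seed=7)
    table, truth = make_feature_table(spec)
    return table, truth


def make_blob_table(n_per_class=50, sep=10.0, d=3, seed=0):
    """Two Gaussian blobs separated only along feature 0."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(2 * n_per_class, d))
    y = np.repeat([0, 1], n_per_class)
    x[y == 1, 0] += sep
    return LabelledTable(x, y)
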