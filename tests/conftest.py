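import numpy as np
import pytest

from cloudtongue import default_config, generate_taste_dataset
from cloudtongue.fixtures import flavor_descriptors, lexicons, region_multipliers


@pytest.fixture(scope="session")
def descriptors():
    return flavor_descriptors()


@pytest.fixture(scope="session")
def flavor_lexicons():
    return lexicons()


@pytest.fixture(scope="session")
def published_multipliers():
    return region_multipliers()


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic e-tongue table (4 flavors x 20), seed 1."""
    return generate_taste_dataset(default_config(), seed=1)


@pytest.fixture(scope="session")
def feature_matrix(default_dataset):
    cols = [c for c in default_dataset.columns if c.startswith("ch")]
    return default_dataset[cols].to_numpy(dtype=float)


@pytest.fixture(scope="session")
def labels(default_dataset):
    return default_dataset["flavor"].to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def separable_clusters(n_per_class=15, n_classes=4, spread=0.05, seed=0):
    """Tiny toy dataset: well-separated Gaussian blobs on a 2-D grid."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [4, 0], [0, 4], [4, 4]], dtype=float)[:n_classes]
    X = np.vstack(
        [c + spread * rng.standard_normal((n_per_class, 2)) for c in centers]
    )
    y = np.repeat([f"class{i}" for i in range(n_classes)], n_per_class)
    return X, y
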