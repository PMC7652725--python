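import numpy as np
import pytest

from pulmf.data_io import AssociationDataset
from pulmf.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """4 microbes x 3 diseases with a mix of degrees, incl. a zero-degree microbe."""
    Y = np.array(
        [
            [1, 0, 0],
            [1, 1, 0],
            [0, 0, 1],
            [0, 0, 0],
        ],
        dtype=float,
    )
    return AssociationDataset(
        microbe_labels=[f"m{i}" for i in range(4)],
        disease_labels=[f"d{j}" for j in range(3)],
        Y=Y,
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """A 60 x 20 planted dataset shared across tests (session-scoped: read-only)."""
    spec = SyntheticSpec(n=60, m=20, r_true=3, density_target=0.08, noise_flip=0.0, seed=7)
    return generate(spec)


def random_similarity(rng, k):
    """Random symmetric nonnegative similarity with unit diagonal."""
    S = rng.random((k, k))
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S
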