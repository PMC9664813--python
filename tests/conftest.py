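import numpy as np
import pytest

from bdhns import AssociationMatrix, BDHNSModel, SyntheticParams, generate_dataset
from bdhns.similarity import SimilarityMatrix


@pytest.fixture(scope="session")
def toy_dataset():
    """Small but complete synthetic bundle (9 diseases x 18 microbes)."""
    params = SyntheticParams(
        n_diseases=9, n_microbes=18, blocks=3, p_in=0.5, p_out=0.05, seed=11
    )
    return generate_dataset(params)


@pytest.fixture(scope="session")
def default_dataset():
    """Synthetic bundle at the generator defaults (15 x 60, 3 blocks)."""
    return generate_dataset(SyntheticParams(seed=7))


@pytest.fixture(scope="session")
def fitted_default(default_dataset):
    model = BDHNSModel(default_dataset.associations, default_dataset.annotations)
    return model.fit()


def random_association_matrix(rng, n_d, n_m, density=0.3):
    """A random binary association matrix with at least one edge."""
    values = (rng.random((n_d, n_m)) < density).astype(float)
    if not values.any():
        values[rng.integers(n_d), rng.integers(n_m)] = 1.0
    return AssociationMatrix(
        values,
        tuple(f"d{i}" for i in range(n_d)),
        tuple(f"m{j}" for j in range(n_m)),
    )


def random_similarity(rng, ids, kind):
    """A random symmetric similarity matrix with unit diagonal."""
    n = len(ids)
    raw = rng.random((n, n))
    values = (raw + raw.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, tuple(ids), kind)
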