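import numpy as np
import pytest

from sparsekm import CSRMatrix, MixtureSpec, PriorConfig, generate

ALL_MEASURES = ["SQE", "KLD", "JSD", "BATMET", "COS"]


@pytest.fixture(scope="session")
def prior01() -> PriorConfig:
    return PriorConfig(0.01)


@pytest.fixture(scope="session")
def small_mixture():
    """Well-separated 3-cluster multinomial mixture (150 x 100)."""
    spec = MixtureSpec(n_per_cluster=50, n_cols=100, k_true=3, alpha=0.05, seed=11)
    return generate(spec)


@pytest.fixture(scope="session")
def disjoint_mixture():
    """Clusters planted on disjoint gene blocks (the infinite-separation limit)."""
    spec = MixtureSpec(n_per_cluster=40, n_cols=120, k_true=3, disjoint=True, seed=5)
    return generate(spec)


def random_sparse_rows(n, d, nnz, rng, max_count=50):
    """Dense array of n sparse nonnegative integer rows with ~nnz entries each."""
    out = np.zeros((n, d))
    for i in range(n):
        k = rng.integers(max(1, nnz - 5), nnz + 6)
        idx = rng.choice(d, size=min(k, d), replace=False)
        out[i, idx] = rng.integers(1, max_count, size=len(idx))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
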