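import numpy as np
import pytest

from atmkit.synthetic import PlantedBlock, PlantedModel, synth_tensor
from atmkit.tensor import SparseTensor3


@pytest.fixture(scope="session")
def rank3_block_model() -> PlantedModel:
    """Noiseless 3-block planted model on a 50 x 40 x 10 grid (seed 42)."""
    blocks = [
        PlantedBlock(
            terms=tuple(range(b * 16, (b + 1) * 16)),
            genes=tuple(range(b * 13, (b + 1) * 13)),
            tfs=tuple(range(b * 3, (b + 1) * 3)),
            intensity=5.0 * 0.8**b,
        )
        for b in range(3)
    ]
    return PlantedModel(50, 40, 10, blocks, noise_rate=0.0, seed=42)


@pytest.fixture(scope="session")
def rank3_block_tensor(rank3_block_model) -> SparseTensor3:
    X, _ = synth_tensor(rank3_block_model)
    return X


@pytest.fixture(scope="session")
def dense_rank3_tensor() -> tuple[SparseTensor3, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Noiseless rank-3 tensor with uniform(0,1) factors (50 x 40 x 10, seed 42)."""
    rng = np.random.default_rng(42)
    A = rng.uniform(size=(50, 3))
    B = rng.uniform(size=(40, 3))
    C = rng.uniform(size=(10, 3))
    dense = np.einsum("ir,jr,kr->ijk", A, B, C)
    ii, jj, kk = np.nonzero(dense)
    X = SparseTensor3.from_entries((50, 40, 10), zip(ii, jj, kk, dense[ii, jj, kk]))
    return X, (A, B, C)


def random_sparse_tensor(dims, density, rng) -> SparseTensor3:
    """Seeded random COO tensor with positive values."""
    m, n, p = dims
    total = m * n * p
    nnz = max(1, int(total * density))
    flat = rng.choice(total, size=nnz, replace=False)
    i, rem = np.divmod(flat, n * p)
    j, k = np.divmod(rem, p)
    vals = rng.uniform(0.5, 3.0, size=nnz)
    return SparseTensor3.from_entries(dims, zip(i, j, k, vals))
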