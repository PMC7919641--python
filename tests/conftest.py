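import numpy as np
import pandas as pd
import pytest

from pgxpipe import simulate
from pgxpipe.features import PREDICTORS


def make_dataset(n_variants=2000, n_genes=200, pgx_fraction=0.2, seed=0, config=None):
    """Paper-like synthetic dataset: (genes, variants, afs, X, y)."""
    genes = simulate.generate_genes(n_genes, pgx_fraction, seed=seed)
    cfg = config or simulate.SimulationConfig(
        n_genes=n_genes, n_variants=n_variants, pgx_fraction=pgx_fraction, seed=seed
    )
    variants, afs = simulate.generate_variant_table(genes, n_variants, cfg)
    X = variants.set_index("variant_id")[list(PREDICTORS)]
    y = variants["label"].to_numpy()
    return genes, variants, afs, X, y


@pytest.fixture(scope="session")
def small_dataset():
    return make_dataset(n_variants=2000, seed=7)


@pytest.fixture(scope="session")
def small_genes():
    return simulate.generate_genes(200, 0.2, seed=1)


@pytest.fixture
def separable_data():
    """Linearly separable two-class toy data."""
    rng = np.random.default_rng(0)
    n = 400
    y = np.zeros(n, dtype=bool)
    y[:80] = True
    X = rng.normal(size=(n, 4))
    X[y, 0] += 10.0
    X = pd.DataFrame(X, columns=[f"f{i}" for i in range(4)])
    return X, y
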