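import numpy as np
import pytest

import scview as sv


def make_random_dataset(seed: int):
    """A small randomized synthetic dataset for round-trip properties."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 5))
    spec = sv.SimSpec(
        n_cells=int(rng.integers(20, 80)),
        n_genes=int(rng.integers(30, 60)),
        k_clusters=k,
        de_genes_per_cluster=int(rng.integers(1, 5)),
        fold_change=float(rng.uniform(2, 6)),
        baseline_mean=float(rng.uniform(0.5, 4)),
        dispersion=float(rng.uniform(0.1, 1.0)),
        condition_fraction=0.5 if rng.random() < 0.5 else None,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    ds, truth = sv.generate_clustered_dataset(spec)
    return ds, truth


@pytest.fixture(scope="session")
def clustered():
    """90 cells x 60 genes, 3 clusters with 5 planted markers each."""
    return sv.generate_clustered_dataset(
        sv.SimSpec(
            n_cells=90,
            n_genes=60,
            k_clusters=3,
            de_genes_per_cluster=5,
            condition_fraction=0.5,
            seed=11,
        )
    )


@pytest.fixture()
def small_counts_dataset():
    """Hand-built 3 cells x 2 genes dataset with known counts."""
    import pandas as pd
    import scipy.sparse as sp

    counts = sp.csr_matrix(np.array([[1, 0], [0, 2], [3, 0]], dtype=np.int64))
    return sv.CellDataset.from_counts(
        counts,
        cell_table=pd.DataFrame(index=pd.Index(["c1", "c2", "c3"], name="cell")),
        gene_table=pd.DataFrame(
            {"symbol": ["ACTB", "GAPDH"]},
            index=pd.Index(["g1", "g2"], name="gene_id"),
        ),
    )
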