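import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from screlmap import (
    CellExpressionDataset,
    SyntheticConfig,
    generate_dataset,
    normalize_log1p,
)


def make_dataset(counts, cell_types, normalized=None, **kw):
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cell_ids = [f"c{i}" for i in range(n_cells)]
    gene_ids = [f"g{j}" for j in range(n_genes)]
    obs = pd.DataFrame({"cell_type": list(cell_types)}, index=cell_ids)
    return CellExpressionDataset(
        counts=sp.csr_matrix(counts),
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        obs=obs,
        normalized=sp.csr_matrix(np.asarray(normalized)) if normalized is not None else None,
        **kw,
    )


@pytest.fixture
def toy_dataset():
    """6 cells x 4 genes, two cell types, written-out counts."""
    counts = [
        [1, 0, 2, 0],
        [2, 1, 0, 0],
        [0, 0, 3, 1],
        [5, 2, 0, 0],
        [4, 0, 1, 0],
        [3, 1, 0, 2],
    ]
    return make_dataset(counts, ["A", "A", "A", "B", "B", "B"])


@pytest.fixture(scope="session")
def planted_dataset():
    """Seeded synthetic dataset with a fold-4 program in one type, normalized."""
    cfg = SyntheticConfig(
        n_genes=600,
        cell_type_sizes={"prog": 150, "other1": 150, "other2": 150},
        program_genes=[f"G{i:05d}" for i in range(20)],
        program_types=["prog"],
        program_fold=4.0,
        seed=11,
    )
    ds, truth = generate_dataset(cfg)
    return normalize_log1p(ds), truth


@pytest.fixture(scope="session")
def null_dataset():
    """Seeded synthetic dataset with no planted program, normalized."""
    cfg = SyntheticConfig(
        n_genes=2000,
        cell_type_sizes={f"t{i}": 150 for i in range(4)},
        program_fold=1.0,
        seed=23,
    )
    ds, _ = generate_dataset(cfg)
    return normalize_log1p(ds)
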