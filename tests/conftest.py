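import numpy as np
import pytest

import deconvbench as db


def make_cem(counts, cell_type=None, donor=None, gene_ids=None, cell_ids=None):
    """Small helper to build a CellExpressionMatrix from a plain array."""
    counts = np.asarray(counts, dtype=float)
    n_genes, n_cells = counts.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if cell_ids is None:
        cell_ids = [f"c{i}" for i in range(n_cells)]
    if cell_type is None:
        cell_type = ["T"] * n_cells
    if donor is None:
        donor = ["D0"] * n_cells
    return db.CellExpressionMatrix(counts, gene_ids, cell_ids, cell_type, donor)


@pytest.fixture(scope="session")
def pancreas():
    return db.make_benchmark_fixture("pancreas_like", seed=7)


@pytest.fixture(scope="session")
def pancreas_qc(pancreas):
    return db.qc_filter(pancreas)


@pytest.fixture(scope="session")
def pancreas_split(pancreas_qc):
    X, _ = pancreas_qc
    return db.split_train_test(X, mode="by_cell", seed=1)


@pytest.fixture(scope="session")
def pancreas_stats(pancreas_split):
    train, _ = pancreas_split
    return db.rank_genes(train)


@pytest.fixture(scope="session")
def pancreas_markers(pancreas_stats):
    return db.select_markers(pancreas_stats, "all")


@pytest.fixture(scope="session")
def pancreas_reference(pancreas_split):
    train, _ = pancreas_split
    return db.build_reference(train)


@pytest.fixture(scope="session")
def pancreas_mixtures(pancreas_split):
    _, test = pancreas_split
    return db.generate_mixtures(test, db.CompositionRules(n_mixtures=200, seed=3))


@pytest.fixture(scope="session")
def pbmc():
    return db.make_benchmark_fixture("pbmc_like", seed=11)


@pytest.fixture(scope="session")
def pbmc_qc(pbmc):
    return db.qc_filter(pbmc)
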