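"""Count-matrix I/O, quality control and train/test splitting.

The central data structure is :class:`CellExpressionMatrix`, a dense
gene x cell raw-count matrix with per-cell ``cell_type`` and ``donor``
labels.  Supported on-disk layouts:

* a directory with ``matrix.mtx`` (Matrix Market), ``genes.tsv``
  (gene_id, symbol) and ``cells.tsv`` (cell_id, cell_type, donor);
* a single delimited text file (TSV/CSV) whose header row holds cell
  ids and whose first column holds gene ids, accompanied by a cell
  metadata TSV.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class QCError(ValueError):
    """Raised when quality control empties the matrix or inputs are invalid."""


@dataclasses.dataclass
class CellExpressionMatrix:
    """Gene x cell raw count matrix with cell-type and donor labels.

    Parameters
    ----------
    counts
        2-D non-negative array, genes in rows, cells in columns.
    gene_ids, cell_ids
        Unique identifiers for rows / columns.
    cell_type, donor
        One label per cell.
    true_markers
        Optional ground-truth marker map (cell type -> gene ids), carried
        along by the synthetic generator so marker recall can be scored.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_type: np.ndarray
    donor: np.ndarray
    true_markers: dict | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        self.donor = np.asarray(self.donor, dtype=object)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.counts.ndim != 2:
            raise QCError("counts must be a 2-D gene x cell matrix")
        if not np.all(np.isfinite(self.counts)):
            raise QCError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise QCError("counts contain negative values")
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise QCError(
                f"{len(self.gene_ids)} gene annotations for {n_genes} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise QCError(
                f"{len(self.cell_ids)} cell annotations for {n_cells} columns"
            )
        if len(self.cell_type) != n_cells or len(self.donor) != n_cells:
            raise QCError("cell_type/donor must have one entry per cell")
        if len(set(self.gene_ids)) != n_genes:
            raise QCError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise QCError("cell_ids are not unique")

    # -- convenience -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def cell_types(self) -> list:
        """Sorted unique cell-type labels."""
        return sorted(set(self.cell_type))

    def subset_genes(self, index) -> "CellExpressionMatrix":
        index = np.asarray(index)
        return CellExpressionMatrix(
            self.counts[index, :],
            self.gene_ids[index],
            self.cell_ids,
            self.cell_type,
            self.donor,
            true_markers=self.true_markers,
        )

    def subset_cells(self, index) -> "CellExpressionMatrix":
        index = np.asarray(index)
        return CellExpressionMatrix(
            self.counts[:, index],
            self.gene_ids,
            self.cell_ids[index],
            self.cell_type[index],
            self.donor[index],
            true_markers=self.true_markers,
        )

    def copy(self) -> "CellExpressionMatrix":
        return CellExpressionMatrix(
            self.counts.copy(),
            self.gene_ids.copy(),
            self.cell_ids.copy(),
            self.cell_type.copy(),
            self.donor.copy(),
            true_markers=None if self.true_markers is None else dict(self.true_markers),
        )


@dataclasses.dataclass
class QCReport:
    """Bookkeeping for every removal performed by :func:`qc_filter`."""

    n_genes_in: int
    n_genes_out: int
    n_cells_in: int
    n_cells_out: int
    genes_removed_by_rule: dict
    cells_removed_by_rule: dict
    cell_types_dropped: list

    def to_frame(self) -> pd.DataFrame:
        rows = [("genes", rule, n) for rule, n in self.genes_removed_by_rule.items()]
        rows += [("cells", rule, n) for rule, n in self.cells_removed_by_rule.items()]
        rows.append(("summary", "genes_in", self.n_genes_in))
        rows.append(("summary", "genes_out", self.n_genes_out))
        rows.append(("summary", "cells_in", self.n_cells_in))
        rows.append(("summary", "cells_out", self.n_cells_out))
        rows.append(("summary", "cell_types_dropped", len(self.cell_types_dropped)))
        return pd.DataFrame(rows, columns=["axis", "rule", "count"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts(path, format: str | None = None, cell_meta=None) -> CellExpressionMatrix:
    """Read a labelled count matrix from disk.

    ``path`` may be a directory in the MTX layout, a ``.mtx`` file with
    sibling ``genes.tsv``/``cells.tsv``, or a delimited text matrix (in
    which case ``cell_meta`` must point at a TSV with columns
    ``cell_id``, ``cell_type``, ``donor``; it defaults to a sibling
    ``cells.tsv``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input path does not exist: {path}")
    if format is None:
        if path.is_dir() or path.suffix == ".mtx":
            format = "mtx"
        else:
            format = "delimited"
    if format == "mtx":
        return _read_mtx(path)
    if format == "delimited":
        return _read_delimited(path, cell_meta)
    raise ValueError(f"unknown format {format!r}")


def _read_mtx(path: Path) -> CellExpressionMatrix:
    if path.is_dir():
        mtx_path = path / "matrix.mtx"
        genes_path = path / "genes.tsv"
        cells_path = path / "cells.tsv"
    else:
        mtx_path = path
        genes_path = path.parent / "genes.tsv"
        cells_path = path.parent / "cells.tsv"
    for p in (mtx_path, genes_path, cells_path):
        if not p.exists():
            raise FileNotFoundError(f"missing annotation or matrix file: {p}")
    mat = spio.mmread(mtx_path)
    counts = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=np.float64)
    genes = pd.read_csv(genes_path, sep="\t")
    cells = pd.read_csv(cells_path, sep="\t")
    for col in ("cell_id", "cell_type", "donor"):
        if col not in cells.columns:
            raise QCError(f"cells annotation lacks required column {col!r}")
    if "gene_id" not in genes.columns:
        raise QCError("genes annotation lacks required column 'gene_id'")
    if counts.shape[0] != len(genes):
        raise QCError(
            f"matrix has {counts.shape[0]} genes but annotation lists {len(genes)}"
        )
    if counts.shape[1] != len(cells):
        raise QCError(
            f"matrix has {counts.shape[1]} cells but annotation lists {len(cells)}"
        )
    return CellExpressionMatrix(
        counts,
        genes["gene_id"].to_numpy(),
        cells["cell_id"].to_numpy(),
        cells["cell_type"].to_numpy(),
        cells["donor"].to_numpy(),
    )


def _read_delimited(path: Path, cell_meta) -> CellExpressionMatrix:
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if cell_meta is None:
        cell_meta = path.parent / "cells.tsv"
    cell_meta = Path(cell_meta)
    if not cell_meta.exists():
        raise FileNotFoundError(f"missing cell metadata file: {cell_meta}")
    cells = pd.read_csv(cell_meta, sep="\t").set_index("cell_id")
    missing = [c for c in df.columns if c not in cells.index]
    if missing:
        raise QCError(f"cells missing from metadata: {missing[:5]}")
    cells = cells.loc[list(df.columns)]
    return CellExpressionMatrix(
        df.to_numpy(dtype=np.float64),
        df.index.to_numpy(),
        np.asarray(df.columns, dtype=object),
        cells["cell_type"].to_numpy(),
        cells["donor"].to_numpy(),
    )


def write_counts(X: CellExpressionMatrix, path) -> Path:
    """Write ``X`` as ``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    counts = X.counts
    if np.allclose(counts, np.round(counts)):
        mat = sparse.coo_matrix(counts.astype(np.int64))
    else:
        mat = sparse.coo_matrix(counts)
    spio.mmwrite(path / "matrix.mtx", mat)
    pd.DataFrame({"gene_id": X.gene_ids, "symbol": X.gene_ids}).to_csv(
        path / "genes.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"cell_id": X.cell_ids, "cell_type": X.cell_type, "donor": X.donor}
    ).to_csv(path / "cells.tsv", sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def robust_z(x: np.ndarray, scale: float = 1.4826) -> np.ndarray:
    """Deviation from the median in MAD units (consistency-scaled).

    A zero MAD yields zeros: with more than half the values identical we
    have no robust spread estimate, so no value is flagged.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * scale
    if mad == 0:
        return np.zeros_like(x)
    return (x - med) / mad


def _genes_matching(gene_ids, explicit, prefixes) -> np.ndarray:
    if explicit is not None:
        explicit = set(explicit)
        return np.array([g in explicit for g in gene_ids])
    return np.array([any(str(g).upper().startswith(p) for p in prefixes) for g in gene_ids])


def qc_filter(
    X: CellExpressionMatrix,
    n_mads: float = 3.0,
    min_frac_cells: float = 0.05,
    min_count: float = 1,
    min_cells_per_type: int = 50,
    mito_gene_set=None,
    ribo_gene_set=None,
    mito_prefixes=("MT-",),
    ribo_prefixes=("RPL", "RPS"),
    mad_scale: float = 1.4826,
    two_sided: bool = True,
    max_passes: int = 20,
) -> tuple[CellExpressionMatrix, QCReport]:
    """Apply the benchmark's QC rules, strictly in order.

    1. Drop all-zero genes, then remaining zero-variance genes.
    2. Drop cells whose library size, mitochondrial fraction or
       ribosomal fraction lies more than ``n_mads`` MADs from the median
       (two-sided by default; upper-sided with ``two_sided=False``).
    3. Keep genes with count > ``min_count`` in at least
       ``min_frac_cells`` of the remaining cells, regardless of type.
    4. Keep only cell types with at least ``min_cells_per_type`` cells.

    Because each removal shifts the medians/fractions the later rules
    see, the four rules are repeated (in order) until a full pass
    removes nothing, so the filter is idempotent on its own output.
    ``max_passes=1`` gives the plain single-pass behaviour.
    """
    genes_removed: dict[str, int] = {
        "all_zero": 0,
        "zero_variance": 0,
        "low_prevalence": 0,
    }
    cells_removed: dict[str, int] = {
        "library_size": 0,
        "mito_fraction": 0,
        "ribo_fraction": 0,
        "small_cell_type": 0,
    }
    types_dropped: set = set()
    X_in = X
    for _ in range(max_passes):
        X, pass_genes, pass_cells, pass_types = _qc_pass(
            X,
            n_mads=n_mads,
            min_frac_cells=min_frac_cells,
            min_count=min_count,
            min_cells_per_type=min_cells_per_type,
            mito_gene_set=mito_gene_set,
            ribo_gene_set=ribo_gene_set,
            mito_prefixes=mito_prefixes,
            ribo_prefixes=ribo_prefixes,
            mad_scale=mad_scale,
            two_sided=two_sided,
        )
        for rule, n in pass_genes.items():
            genes_removed[rule] += n
        for rule, n in pass_cells.items():
            cells_removed[rule] += n
        types_dropped |= pass_types
        if sum(pass_genes.values()) == 0 and sum(pass_cells.values()) == 0:
            break
    report = QCReport(
        n_genes_in=X_in.n_genes,
        n_genes_out=X.n_genes,
        n_cells_in=X_in.n_cells,
        n_cells_out=X.n_cells,
        genes_removed_by_rule=genes_removed,
        cells_removed_by_rule=cells_removed,
        cell_types_dropped=sorted(types_dropped),
    )
    return X, report


def _qc_pass(
    X: CellExpressionMatrix,
    n_mads: float,
    min_frac_cells: float,
    min_count: float,
    min_cells_per_type: int,
    mito_gene_set,
    ribo_gene_set,
    mito_prefixes,
    ribo_prefixes,
    mad_scale: float,
    two_sided: bool,
) -> tuple[CellExpressionMatrix, dict, dict, set]:
    genes_removed: dict[str, int] = {}
    cells_removed: dict[str, int] = {}

    counts = X.counts
    # rule 1: all-zero then zero-variance genes
    nonzero = counts.sum(axis=1) > 0
    genes_removed["all_zero"] = int(np.sum(~nonzero))
    variance = counts.var(axis=1)
    zero_var = nonzero & (variance == 0)
    genes_removed["zero_variance"] = int(np.sum(zero_var))
    keep_genes = nonzero & ~zero_var
    X1 = X.subset_genes(np.flatnonzero(keep_genes))
    if X1.n_genes == 0:
        raise QCError("no genes left after removing zero/zero-variance rows")

    # rule 2: MAD-based cell filters
    lib = X1.library_sizes
    flag = np.zeros(X1.n_cells, dtype=bool)
    reason = np.full(X1.n_cells, "", dtype=object)

    def _apply(metric: np.ndarray, name: str) -> None:
        z = robust_z(metric, scale=mad_scale)
        bad = (np.abs(z) > n_mads) if two_sided else (z > n_mads)
        new = bad & ~flag
        reason[new] = name
        flag[new] = True

    _apply(lib, "library_size")
    mito_mask = _genes_matching(X1.gene_ids, mito_gene_set, mito_prefixes)
    if mito_mask.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(lib > 0, X1.counts[mito_mask].sum(axis=0) / lib, 0.0)
        _apply(frac, "mito_fraction")
    ribo_mask = _genes_matching(X1.gene_ids, ribo_gene_set, ribo_prefixes)
    if ribo_mask.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(lib > 0, X1.counts[ribo_mask].sum(axis=0) / lib, 0.0)
        _apply(frac, "ribo_fraction")
    for name in ("library_size", "mito_fraction", "ribo_fraction"):
        cells_removed[name] = int(np.sum(reason == name))
    X2 = X1.subset_cells(np.flatnonzero(~flag))
    if X2.n_cells == 0:
        raise QCError("no cells left after MAD filtering")

    # rule 3: prevalence filter on remaining cells
    n_expressing = (X2.counts > min_count).sum(axis=1)
    keep = n_expressing >= min_frac_cells * X2.n_cells
    genes_removed["low_prevalence"] = int(np.sum(~keep))
    X3 = X2.subset_genes(np.flatnonzero(keep))
    if X3.n_genes == 0:
        raise QCError("no genes left after the prevalence filter")

    # rule 4: small cell types
    types, type_counts = np.unique(X3.cell_type, return_counts=True)
    small = {t for t, n in zip(types, type_counts) if n < min_cells_per_type}
    keep_cells = np.array([t not in small for t in X3.cell_type])
    cells_removed["small_cell_type"] = int(np.sum(~keep_cells))
    X4 = X3.subset_cells(np.flatnonzero(keep_cells))
    if X4.n_cells == 0:
        raise QCError("no cells left after dropping small cell types")

    return X4, genes_removed, cells_removed, small


# ---------------------------------------------------------------------------
# Train/test splitting
# ---------------------------------------------------------------------------

def split_train_test(
    X: CellExpressionMatrix, mode: str = "by_cell", seed: int = 0
) -> tuple[CellExpressionMatrix, CellExpressionMatrix]:
    """Split into balanced train/test halves.

    ``by_cell``: per cell type, cells are shuffled and divided 50:50,
    with the extra cell of an odd group going to the training split.
    ``by_donor``: donors are shuffled and assigned half to each split
    before selecting cells, so no donor spans both splits.
    """
    rng = np.random.default_rng(seed)
    if mode == "by_cell":
        train_idx: list[int] = []
        test_idx: list[int] = []
        for t in X.cell_types():
            idx = np.flatnonzero(X.cell_type == t)
            if len(idx) < 2:
                raise QCError(f"cell type {t!r} has fewer than 2 cells; cannot split")
            idx = rng.permutation(idx)
            n_train = math.ceil(len(idx) / 2)
            train_idx.extend(idx[:n_train])
            test_idx.extend(idx[n_train:])
    elif mode == "by_donor":
        donors = sorted(set(X.donor))
        if len(donors) < 2:
            raise QCError(
                "by_donor split requires at least 2 donors; got "
                f"{len(donors)} ({donors})"
            )
        order = rng.permutation(len(donors))
        n_train = math.ceil(len(donors) / 2)
        train_donors = {donors[i] for i in order[:n_train]}
        in_train = np.array([d in train_donors for d in X.donor])
        train_idx = list(np.flatnonzero(in_train))
        test_idx = list(np.flatnonzero(~in_train))
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    train_idx = np.sort(np.asarray(train_idx, dtype=int))
    test_idx = np.sort(np.asarray(test_idx, dtype=int))
    return X.subset_cells(train_idx), X.subset_cells(test_idx)
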