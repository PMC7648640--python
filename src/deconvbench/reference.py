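"""Reference (signature) matrix construction and manipulation.

The reference C holds, per gene and cell type, the arithmetic mean of
raw counts over the training cells of that type; transformation and
normalization are applied downstream, exactly as for the mixtures.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io_qc import CellExpressionMatrix
from .markers import MarkerSet


@dataclasses.dataclass
class ReferenceMatrix:
    values: np.ndarray  # genes x cell types
    gene_ids: np.ndarray
    cell_type_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_type_ids = list(self.cell_type_ids)
        if self.values.shape != (len(self.gene_ids), len(self.cell_type_ids)):
            raise ValueError("reference dimensions do not match annotations")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_type_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def build_reference(train: CellExpressionMatrix) -> ReferenceMatrix:
    """Per-type mean of raw counts; columns ordered by sorted cell type id."""
    types = train.cell_types()
    cols = [train.counts[:, train.cell_type == t].mean(axis=1) for t in types]
    return ReferenceMatrix(np.column_stack(cols), train.gene_ids, types)


def subset_to_markers(C: ReferenceMatrix, markers: MarkerSet) -> ReferenceMatrix:
    """Restrict rows to the union of all marker genes, original order kept."""
    union = set(markers.all_genes())
    if not union:
        raise ValueError("marker set is empty; cannot subset the reference")
    unknown = union - set(C.gene_ids)
    if unknown:
        raise ValueError(f"marker genes absent from reference: {sorted(unknown)[:5]}")
    keep = np.array([g in union for g in C.gene_ids])
    sub = ReferenceMatrix(C.values[keep], C.gene_ids[keep], C.cell_type_ids)
    if np.linalg.matrix_rank(sub.values) < len(sub.cell_type_ids):
        warnings.warn(
            "marker-subset reference is rank deficient; proportions may not "
            "be identifiable",
            stacklevel=2,
        )
    return sub


def drop_cell_type(
    C: ReferenceMatrix, markers: MarkerSet, victim: str
) -> tuple[ReferenceMatrix, MarkerSet]:
    """Remove a cell type's column and (for the bulk path) its marker genes."""
    if victim not in C.cell_type_ids:
        raise ValueError(f"cell type {victim!r} not in reference ({C.cell_type_ids})")
    keep_cols = [j for j, t in enumerate(C.cell_type_ids) if t != victim]
    if not keep_cols:
        raise ValueError("dropping this cell type would empty the reference")
    new_ref = ReferenceMatrix(
        C.values[:, keep_cols],
        C.gene_ids,
        [C.cell_type_ids[j] for j in keep_cols],
    )
    new_markers = MarkerSet(
        strategy=markers.strategy,
        markers={t: list(g) for t, g in markers.markers.items() if t != victim},
        table=markers.table[markers.table["cell_type"] != victim].reset_index(drop=True),
        params=dict(markers.params),
    )
    return new_ref, new_markers


def celltype_correlations(
    C: ReferenceMatrix, markers: MarkerSet | None = None, scope: str = "all_genes"
) -> pd.DataFrame:
    """Pairwise Pearson correlations between cell-type expression profiles.

    ``scope="markers_only"`` restricts to the marker-subset reference
    (requires ``markers``); constant profiles yield NaN rows/columns.
    """
    if scope == "markers_only":
        if markers is None:
            raise ValueError("markers_only scope requires a MarkerSet")
        C = subset_to_markers(C, markers)
    elif scope != "all_genes":
        raise ValueError(f"unknown scope {scope!r}")
    if len(C.cell_type_ids) < 2:
        raise ValueError("need at least 2 cell types for correlations")
    vals = C.values
    sd = vals.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=C.cell_type_ids, columns=C.cell_type_ids)
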