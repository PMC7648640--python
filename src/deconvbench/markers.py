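"""Per-type gene ranking, the eight marker-selection strategies, and the
marker non-specificity statistic.

Expression is TMM-normalized log2 counts-per-million with pseudo-count 1;
per-gene significance comes from a Welch two-sample t-test of the own
type against all other cells, BH-adjusted across genes within each type.
The fold change of a (gene, type) pair is taken against the highest mean
among the *other* types ("second-highest" from the own type's view).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .io_qc import CellExpressionMatrix
from .normalize import tmm_cpm

STRATEGIES = (
    "all",
    "pos_fc",
    "top_n2",
    "top_50p_logFC",
    "bottom_50p_logFC",
    "top_50p_AveExpr",
    "bottom_50p_AveExpr",
    "random5",
)


@dataclasses.dataclass
class GeneStats:
    """Tidy per-(gene, type) statistics plus the per-type log2 mean matrix."""

    table: pd.DataFrame  # gene, cell_type, logFC, AveExpr, p_adj, frac_expressed
    log_means: pd.DataFrame  # genes x cell types, log2(CPM + 1) means
    params: dict

    @property
    def genes(self) -> list:
        return list(self.log_means.index)

    @property
    def cell_types(self) -> list:
        return list(self.log_means.columns)


@dataclasses.dataclass
class MarkerSet:
    strategy: str
    markers: dict  # cell type -> ordered gene list
    table: pd.DataFrame  # cell_type, gene, logFC, AveExpr, p_adj, strategy
    params: dict

    def all_genes(self) -> list:
        """Union of all types' markers, de-duplicated, first-seen order."""
        seen: dict = {}
        for t in sorted(self.markers):
            for g in self.markers[t]:
                seen.setdefault(g, None)
        return list(seen)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def rank_genes(
    train: CellExpressionMatrix,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    min_expr_frac: float = 0.30,
    pseudocount: float = 1.0,
) -> GeneStats:
    """Compute per-(gene, type) logFC / AveExpr / adjusted p / expression fraction.

    Genes without a positive count in at least ``min_expr_frac`` of the
    cells of at least one type are excluded up front.
    """
    types = train.cell_types()
    if len(types) < 2:
        raise ValueError("rank_genes requires at least 2 cell types")
    masks = {t: train.cell_type == t for t in types}
    for t in types:
        if masks[t].sum() < 2:
            raise ValueError(f"cell type {t!r} has fewer than 2 cells")

    raw = train.counts
    frac_expr = np.column_stack([(raw[:, masks[t]] > 0).mean(axis=1) for t in types])
    retained = frac_expr.max(axis=1) >= min_expr_frac
    if retained.sum() == 0:
        raise ValueError("no gene passes the expression-fraction filter")

    logexpr = np.log2(tmm_cpm(raw) + pseudocount)
    logexpr = logexpr[retained]
    frac_expr = frac_expr[retained]
    genes = train.gene_ids[retained]

    means = np.column_stack([logexpr[:, masks[t]].mean(axis=1) for t in types])
    # per (gene, type): logFC against the highest mean among the other types
    order = np.argsort(means, axis=1)
    top1 = means[np.arange(len(genes)), order[:, -1]]
    top2 = means[np.arange(len(genes)), order[:, -2]]
    is_top = np.zeros_like(means, dtype=bool)
    is_top[np.arange(len(genes)), order[:, -1]] = True
    others_max = np.where(is_top, top2[:, None], top1[:, None])
    logfc = means - others_max

    ave_expr = logexpr.mean(axis=1)

    p_adj = np.empty_like(means)
    for j, t in enumerate(types):
        a = logexpr[:, masks[t]]
        b = logexpr[:, ~masks[t]]
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = sstats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.where(np.isfinite(p), p, 1.0)
        p_adj[:, j] = multipletests(p, method="fdr_bh")[1]

    rows = []
    for j, t in enumerate(types):
        rows.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "cell_type": t,
                    "logFC": logfc[:, j],
                    "AveExpr": ave_expr,
                    "p_adj": p_adj[:, j],
                    "frac_expressed": frac_expr[:, j],
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    log_means = pd.DataFrame(means, index=genes, columns=types)
    return GeneStats(
        table=table,
        log_means=log_means,
        params={
            "fc_threshold": fc_threshold,
            "alpha": alpha,
            "min_expr_frac": min_expr_frac,
            "pseudocount": pseudocount,
        },
    )


def _base_assignment(
    stats: GeneStats, fc_threshold: float, alpha: float
) -> pd.DataFrame:
    """Assign each qualifying gene to exactly one cell type.

    A gene qualifies through its highest-expressing type when that
    type's logFC clears the threshold; otherwise, a strongly *negative*
    fold change (low in one type, high in the others) still qualifies it
    as a negative marker for that type.
    """
    log_thr = math.log2(fc_threshold)
    wide_fc = stats.table.pivot(index="gene", columns="cell_type", values="logFC")
    wide_p = stats.table.pivot(index="gene", columns="cell_type", values="p_adj")
    ave = stats.table.drop_duplicates("gene").set_index("gene")["AveExpr"]

    records = []
    for g in wide_fc.index:
        fc_row = wide_fc.loc[g]
        p_row = wide_p.loc[g]
        t_pos = fc_row.idxmax()
        if fc_row[t_pos] >= log_thr and p_row[t_pos] < alpha:
            records.append((g, t_pos, fc_row[t_pos], ave[g], p_row[t_pos]))
            continue
        t_neg = fc_row.idxmin()
        if fc_row[t_neg] <= -log_thr and p_row[t_neg] < alpha:
            records.append((g, t_neg, fc_row[t_neg], ave[g], p_row[t_neg]))
    return pd.DataFrame(
        records, columns=["gene", "cell_type", "logFC", "AveExpr", "p_adj"]
    )


def _ordered(group: pd.DataFrame, key: str) -> pd.DataFrame:
    """Deterministic descending order: key, then AveExpr, then gene id."""
    return group.sort_values(
        [key, "AveExpr", "gene"], ascending=[False, False, True]
    )


def select_markers(
    stats: GeneStats,
    strategy: str,
    seed: int = 0,
    fc_threshold: float | None = None,
    alpha: float | None = None,
) -> MarkerSet:
    """Produce one of the eight marker-selection strategies.

    The base set (strategy ``all``) consists of genes with
    ``|logFC| >= log2(fc_threshold)`` and BH-adjusted p below ``alpha``,
    each assigned to a single cell type.  ``random5`` draws five
    filter-passing genes per type as a negative control; "top/bottom
    50%" halves use the ceiling on odd counts, so the two halves overlap
    in at most one gene.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    fc_threshold = stats.params["fc_threshold"] if fc_threshold is None else fc_threshold
    alpha = stats.params["alpha"] if alpha is None else alpha
    base = _base_assignment(stats, fc_threshold, alpha)
    types = stats.cell_types

    import warnings

    markers: dict = {}
    frames = []
    if strategy == "random5":
        rng = np.random.default_rng(seed)
        pool = np.asarray(stats.genes, dtype=object)
        for t in types:
            chosen = rng.choice(pool, size=5, replace=False)
            markers[t] = list(chosen)
            sub = stats.table[
                (stats.table["cell_type"] == t) & stats.table["gene"].isin(chosen)
            ][["gene", "cell_type", "logFC", "AveExpr", "p_adj"]]
            frames.append(sub)
    else:
        for t in types:
            group = base[base["cell_type"] == t]
            if strategy == "all":
                sel = _ordered(group, "logFC")
            elif strategy == "pos_fc":
                sel = _ordered(group[group["logFC"] > 0], "logFC")
            elif strategy == "top_n2":
                sel = _ordered(group, "logFC").head(2)
            elif strategy in ("top_50p_logFC", "bottom_50p_logFC"):
                ordered = _ordered(group, "logFC")
                n_half = math.ceil(len(ordered) / 2)
                sel = ordered.head(n_half) if strategy.startswith("top") else ordered.tail(n_half)
            elif strategy in ("top_50p_AveExpr", "bottom_50p_AveExpr"):
                ordered = _ordered(group, "AveExpr")
                n_half = math.ceil(len(ordered) / 2)
                sel = ordered.head(n_half) if strategy.startswith("top") else ordered.tail(n_half)
            else:  # pragma: no cover
                raise AssertionError(strategy)
            if len(sel) == 0:
                warnings.warn(
                    f"cell type {t!r} has no markers under strategy {strategy!r}",
                    stacklevel=2,
                )
            markers[t] = list(sel["gene"])
            frames.append(sel)

    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["gene", "cell_type", "logFC", "AveExpr", "p_adj"])
    )
    table = table.assign(strategy=strategy)
    return MarkerSet(
        strategy=strategy,
        markers=markers,
        table=table,
        params={"fc_threshold": fc_threshold, "alpha": alpha, "seed": seed},
    )


def marker_specificity(
    stats: GeneStats, markers: MarkerSet, fc_threshold: float
) -> float:
    """Percentage of markers that also qualify for a secondary cell type.

    For a marker with expression ranking t1 > t2 > t3 ... across types,
    the gene is non-specific when the fold change between the second-
    and third-highest types also clears ``fc_threshold``, i.e. the gene
    would have been called a marker of t2 had t1 been absent.  Only
    positive markers enter the computation: a negative marker has no
    "cell type where it was found with the highest fold change".
    """
    if markers.strategy != "all":
        raise ValueError("marker_specificity expects the strategy-'all' MarkerSet")
    log_thr = math.log2(fc_threshold)
    means = stats.log_means

    positive = markers.table[markers.table["logFC"] > 0]
    marker_genes = list(zip(positive["cell_type"], positive["gene"]))
    if not marker_genes:
        return 0.0
    n_nonspecific = 0
    for t, g in marker_genes:
        row = np.sort(means.loc[g].to_numpy())[::-1]
        if len(row) < 3:
            continue
        if row[1] - row[2] >= log_thr:
            n_nonspecific += 1
    return 100.0 * n_nonspecific / len(marker_genes)
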