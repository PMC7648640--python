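"""Scoring, the missing-cell-type experiment, and the benchmark driver."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_qc import CellExpressionMatrix, qc_filter, split_train_test
from .markers import rank_genes, select_markers
from .pseudobulk import CompositionRules, MixtureSet, generate_mixtures
from .reference import (
    ReferenceMatrix,
    build_reference,
    celltype_correlations,
    drop_cell_type,
    subset_to_markers,
)
from .solvers import DEFAULT_METHODS, deconvolve

GRANULARITIES = ("per_mixture_median", "per_mixture", "per_celltype", "pooled")


def _check_shapes(P_E, P_C) -> tuple[np.ndarray, np.ndarray]:
    P_E = np.asarray(P_E, dtype=float)
    P_C = np.asarray(P_C, dtype=float)
    if P_E.shape != P_C.shape:
        raise ValueError(f"shape mismatch: expected {P_E.shape}, computed {P_C.shape}")
    if P_E.ndim == 1:
        P_E, P_C = P_E[None, :], P_C[None, :]
    return P_E, P_C


def rmse(P_E, P_C, granularity: str = "per_mixture_median"):
    """Root-mean-square error between true and estimated proportions.

    ``per_mixture_median``: median over mixtures of per-mixture RMSE
    (the headline statistic); ``per_mixture``: the vector itself;
    ``per_celltype``: per-type RMSE over mixtures (used by the removal
    analysis); ``pooled``: over all entries.
    """
    P_E, P_C = _check_shapes(P_E, P_C)
    err2 = (P_E - P_C) ** 2
    if granularity == "per_mixture_median":
        return float(np.median(np.sqrt(err2.mean(axis=0))))
    if granularity == "per_mixture":
        return np.sqrt(err2.mean(axis=0))
    if granularity == "per_celltype":
        return np.sqrt(err2.mean(axis=1))
    if granularity == "pooled":
        return float(np.sqrt(err2.mean()))
    raise ValueError(f"unknown granularity {granularity!r}")


def _pearson_1d(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def pearson(P_E, P_C, granularity: str = "pooled"):
    """Pearson correlation at the chosen granularity; NaN for constants."""
    P_E, P_C = _check_shapes(P_E, P_C)
    if granularity == "pooled":
        return _pearson_1d(P_E.ravel(), P_C.ravel())
    if granularity == "per_mixture":
        return np.array([_pearson_1d(P_E[:, j], P_C[:, j]) for j in range(P_E.shape[1])])
    if granularity == "per_celltype":
        return np.array([_pearson_1d(P_E[i], P_C[i]) for i in range(P_E.shape[0])])
    if granularity == "per_mixture_median":
        vals = pearson(P_E, P_C, "per_mixture")
        return float(np.nanmedian(vals))
    raise ValueError(f"unknown granularity {granularity!r}")


def relative_error_by_magnitude(P_E, P_C, bins=None) -> pd.DataFrame:
    """Summarize |p_hat - p| / p per bin of the expected proportion.

    Zero expected proportions are excluded; default bins are deciles of
    (0, 1].
    """
    P_E, P_C = _check_shapes(P_E, P_C)
    if bins is None:
        bins = np.linspace(0.0, 1.0, 11)
    bins = np.asarray(bins, dtype=float)
    p = P_E.ravel()
    mask = p > 0
    p = p[mask]
    rel = np.abs(P_C.ravel()[mask] - p) / p
    which = np.digitize(p, bins, right=True)
    rows = []
    for b in range(1, len(bins)):
        sel = which == b
        rows.append(
            {
                "bin_low": bins[b - 1],
                "bin_high": bins[b],
                "n": int(sel.sum()),
                "mean_rel_error": float(rel[sel].mean()) if sel.any() else float("nan"),
                "median_rel_error": float(np.median(rel[sel])) if sel.any() else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def align_proportions(
    P_C: np.ndarray, computed_types: list, full_types: list
) -> np.ndarray:
    """Expand a computed-proportion matrix to ``full_types`` rows, zeros
    for cell types absent from the (possibly reduced) reference."""
    out = np.zeros((len(full_types), P_C.shape[1]))
    index = {t: i for i, t in enumerate(computed_types)}
    for i, t in enumerate(full_types):
        if t in index:
            out[i] = P_C[index[t]]
    return out


# ---------------------------------------------------------------------------
# Missing-cell-type experiment
# ---------------------------------------------------------------------------

def removal_experiment(
    mixtures: MixtureSet,
    C: ReferenceMatrix,
    markers,
    methods=("nnls",),
    normalizations=("none", "column"),
    victims=None,
    transform_kind="linear",
    fold_threshold: float = 2.0,
) -> dict:
    """Score deconvolution with each victim cell type dropped from C.

    For each victim, only mixtures actually containing the victim are
    scored, against the full-reference baseline restricted to the same
    mixtures; per remaining cell type the RMSE fold change is reported
    and flagged when it reaches ``fold_threshold``.  Returns a dict with
    the tidy ``report`` and the marker/all-gene correlation matrices.
    """
    if victims is None:
        victims = list(C.cell_type_ids)
    full_types = mixtures.cell_type_ids
    rows = []
    for method in methods:
        for norm in normalizations:
            base = deconvolve(
                mixtures,
                C,
                markers=markers,
                method=method,
                transform_kind=transform_kind,
                scaling_t=norm,
                scaling_c=norm,
            )
            if base.skipped:
                rows.append(
                    {
                        "method": method,
                        "normalization": norm,
                        "victim": None,
                        "cell_type": None,
                        "skipped": True,
                        "skip_reason": base.skip_reason,
                    }
                )
                continue
            P_base = align_proportions(base.P_C, base.cell_type_ids, full_types)
            for victim in victims:
                present = mixtures.P_E[full_types.index(victim)] > 0
                if not present.any():
                    rows.append(
                        {
                            "method": method,
                            "normalization": norm,
                            "victim": victim,
                            "cell_type": None,
                            "skipped": True,
                            "skip_reason": "victim absent from all mixtures",
                        }
                    )
                    continue
                C_red, markers_red = drop_cell_type(C, markers, victim)
                red = deconvolve(
                    mixtures,
                    C_red,
                    markers=markers_red,
                    method=method,
                    transform_kind=transform_kind,
                    scaling_t=norm,
                    scaling_c=norm,
                )
                P_red = align_proportions(red.P_C, red.cell_type_ids, full_types)
                sub = np.flatnonzero(present)
                base_rmse = rmse(
                    mixtures.P_E[:, sub], P_base[:, sub], "per_celltype"
                )
                red_rmse = rmse(mixtures.P_E[:, sub], P_red[:, sub], "per_celltype")
                for i, t in enumerate(full_types):
                    if t == victim:
                        continue
                    fold = (
                        red_rmse[i] / base_rmse[i] if base_rmse[i] > 0 else float("inf")
                    )
                    rows.append(
                        {
                            "method": method,
                            "normalization": norm,
                            "victim": victim,
                            "cell_type": t,
                            "n_mixtures": int(present.sum()),
                            "rmse_baseline": float(base_rmse[i]),
                            "rmse_removed": float(red_rmse[i]),
                            "fold_change": float(fold),
                            "flagged": bool(fold >= fold_threshold),
                            "skipped": False,
                        }
                    )
    report = pd.DataFrame(rows)
    return {
        "report": report,
        "correlations_markers": celltype_correlations(C, markers, "markers_only"),
        "correlations_all_genes": celltype_correlations(C, scope="all_genes"),
    }


# ---------------------------------------------------------------------------
# Full benchmark driver
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EvaluationReport:
    """Tidy table of RMSE/Pearson keyed by the full grid coordinates."""

    table: pd.DataFrame
    manifest: dict

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def run_benchmark(config) -> EvaluationReport:
    """Execute QC -> split -> reference -> markers -> mixtures -> grid.

    ``config`` is a :class:`deconvbench.config.PipelineConfig`.  Every
    skipped combination is recorded with its reason; results are
    deterministic under the config's master seed.
    """
    from .config import PipelineConfig, stage_seed

    if not isinstance(config, PipelineConfig):
        raise TypeError("run_benchmark expects a PipelineConfig")
    if not config.methods:
        raise ValueError("empty method list")

    X = config.load_data()
    Xqc, qc_report = qc_filter(
        X,
        n_mads=config.qc_n_mads,
        min_frac_cells=config.qc_min_frac_cells,
        min_cells_per_type=config.qc_min_cells_per_type,
    )
    train, test = split_train_test(
        Xqc, mode=config.split_mode, seed=stage_seed(config.seed, "split")
    )
    C = build_reference(train)
    stats = rank_genes(
        train,
        fc_threshold=config.fc_threshold,
        alpha=config.marker_alpha,
        min_expr_frac=config.marker_min_expr_frac,
    )
    marker_sets = {
        s: select_markers(stats, s, seed=stage_seed(config.seed, f"markers:{s}"))
        for s in config.marker_strategies
    }
    rules = config.composition_rules()
    mixtures = generate_mixtures(test, rules, seed=stage_seed(config.seed, "mixtures"))

    rows = []
    for transform_kind in config.transforms:
        for scaling_t in config.scaling_t:
            for scaling_c in config.scaling_c:
                for method in config.methods:
                    for strategy, markers in marker_sets.items():
                        result = deconvolve(
                            mixtures,
                            C,
                            markers=markers,
                            method=method,
                            transform_kind=transform_kind,
                            scaling_t=scaling_t,
                            scaling_c=scaling_c,
                            solver_kwargs=config.solver_kwargs.get(method),
                        )
                        row = {
                            "method": method,
                            "transform": transform_kind,
                            "scalingT": scaling_t,
                            "scalingC": scaling_c,
                            "marker_strategy": strategy,
                            "pool_size": rules.pool_size,
                            "removed_cell_type": "none",
                            "n_mixtures": mixtures.n_mixtures,
                        }
                        if result.skipped:
                            row.update(
                                {
                                    "skipped": True,
                                    "skip_reason": result.skip_reason,
                                    "rmse_median": float("nan"),
                                    "rmse_pooled": float("nan"),
                                    "pearson": float("nan"),
                                }
                            )
                        else:
                            P_C = align_proportions(
                                result.P_C, result.cell_type_ids, mixtures.cell_type_ids
                            )
                            ok = ~np.asarray(result.degenerate)
                            P_E = mixtures.P_E
                            row.update(
                                {
                                    "skipped": False,
                                    "skip_reason": None,
                                    "rmse_median": rmse(
                                        P_E[:, ok], P_C[:, ok], "per_mixture_median"
                                    ),
                                    "rmse_pooled": rmse(P_E[:, ok], P_C[:, ok], "pooled"),
                                    "pearson": pearson(P_E[:, ok], P_C[:, ok], "pooled"),
                                    "n_degenerate": int((~ok).sum()),
                                }
                            )
                        rows.append(row)
    table = pd.DataFrame(rows)
    manifest = {
        "config": config.to_dict(),
        "qc": {
            "n_genes_out": qc_report.n_genes_out,
            "n_cells_out": qc_report.n_cells_out,
            "cell_types_dropped": qc_report.cell_types_dropped,
        },
        "n_train_cells": train.n_cells,
        "n_test_cells": test.n_cells,
        "cell_types": mixtures.cell_type_ids,
    }
    return EvaluationReport(table=table, manifest=manifest)
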