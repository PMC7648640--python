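"""Scaling/normalization strategies with closed-form definitions.

Implemented kinds (mirroring the benchmark's non-single-cell-specific
rows, plus ``none``): column (total-count), column/global min-max,
column/global z-score, row, quantile, upper quartile, TPM, TMM with CPM
rescaling, LogNormalize folded back to linear scale, and median of
ratios.  Single-cell-specific normalizations are supported only through
:func:`register_normalizer` (a plugin hook), never re-implemented here.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sstats

NORMALIZATIONS = (
    "none",
    "column",
    "column_minmax",
    "column_zscore",
    "row",
    "global_minmax",
    "global_zscore",
    "quantile",
    "upper_quartile",
    "tpm",
    "tmm",
    "lognormalize_linear",
    "median_ratios",
)

#: plugin registry for external (e.g. single-cell-specific) normalizers
_PLUGINS: dict = {}


class NormalizationError(ValueError):
    pass


@dataclasses.dataclass
class NormalizationKind:
    kind: str
    parameters: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in NORMALIZATIONS and self.kind not in _PLUGINS:
            raise ValueError(
                f"unknown normalization {self.kind!r}; choose from {NORMALIZATIONS} "
                "or register a plugin"
            )


def register_normalizer(name: str, fn) -> None:
    """Register an external normalizer callable ``fn(matrix) -> matrix``."""
    _PLUGINS[name] = fn


def _as_kind(n) -> NormalizationKind:
    if isinstance(n, NormalizationKind):
        return n
    return NormalizationKind(str(n))


# ---------------------------------------------------------------------------
# TMM internals (canonical published defaults)
# ---------------------------------------------------------------------------

def tmm_factors(
    M: np.ndarray,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    weighting: bool = True,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scale factors, geometric mean 1.

    The reference column is the one whose upper quartile of library-size
    fractions is closest to the mean upper quartile.  Genes with a zero
    in reference or sample are excluded; M-values are trimmed two-sided
    at 30% and A-values at 5%, with inverse-asymptotic-variance weights.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise NormalizationError("TMM requires non-negative input")
    lib = M.sum(axis=0)
    if np.any(lib <= 0):
        raise NormalizationError("TMM: column with zero library size")
    frac = M / lib[None, :]
    uq = np.percentile(frac, 75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    n_cols = M.shape[1]
    factors = np.ones(n_cols)
    for j in range(n_cols):
        if j == ref:
            continue
        obs, nobs = M[:, j], lib[j]
        refc, nref = M[:, ref], lib[ref]
        ok = (obs > 0) & (refc > 0)
        if ok.sum() == 0:
            continue
        obs, refc = obs[ok], refc[ok]
        m = np.log2((obs / nobs) / (refc / nref))
        a = 0.5 * np.log2((obs / nobs) * (refc / nref))
        w = (nobs - obs) / (nobs * obs) + (nref - refc) / (nref * refc)
        finite = np.isfinite(m) & np.isfinite(a) & np.isfinite(w)
        m, a, w = m[finite], a[finite], w[finite]
        if len(m) == 0:
            continue
        if np.max(np.abs(m)) < 1e-6:  # identical columns up to scale
            continue
        n = len(m)
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * sum_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = sstats.rankdata(m)
        rank_a = sstats.rankdata(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0:
            continue
        if weighting:
            factors[j] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
        else:
            factors[j] = 2 ** np.mean(m[keep])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def tmm_cpm(M: np.ndarray, **kwargs) -> np.ndarray:
    """TMM-normalized counts per million (effective library sizes)."""
    M = np.asarray(M, dtype=float)
    factors = tmm_factors(M, **kwargs)
    eff_lib = M.sum(axis=0) * factors
    return M / eff_lib[None, :] * 1e6


# ---------------------------------------------------------------------------
# Individual schemes
# ---------------------------------------------------------------------------

def _quantile_normalize(M: np.ndarray) -> np.ndarray:
    """Classic quantile normalization; ties get the mean reference value."""
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    ref = np.sort(M, axis=0).mean(axis=1)
    out = np.empty_like(M)
    ranks_axis = np.arange(1, n + 1)
    for j in range(M.shape[1]):
        ranks = sstats.rankdata(M[:, j], method="average")
        out[:, j] = np.interp(ranks, ranks_axis, ref)
    return out


def _median_ratios(M: np.ndarray) -> np.ndarray:
    from .transforms import size_factors_median_ratios

    if np.any(M < 0):
        raise NormalizationError("median_ratios requires non-negative counts")
    if not np.allclose(M, np.round(M), atol=1e-6):
        import warnings

        warnings.warn(
            "median_ratios applied to non-integer values (e.g. a mean reference "
            "matrix); proceeding, but the scheme is defined for integer counts",
            stacklevel=3,
        )
    positive = np.all(M > 0, axis=1)
    if positive.sum() < 1:
        raise NormalizationError(
            "median_ratios: no gene with positive counts in every column"
        )
    logM = np.log(M[positive])
    log_geomean = logM.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logM - log_geomean, axis=0))
    return M / factors[None, :]


def normalize(M: np.ndarray, n="none", on_constant: str = "error") -> np.ndarray:
    """Apply a normalization scheme column-/row-/matrix-wise.

    ``on_constant`` controls z-scoring of constant columns: ``"error"``
    raises, ``"zero"`` fills with zeros.
    """
    nk = _as_kind(n)
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise NormalizationError("normalization input contains non-finite values")
    kind = nk.kind
    p = nk.parameters

    if kind in _PLUGINS:
        return np.asarray(_PLUGINS[kind](M), dtype=float)
    if kind == "none":
        return M.copy()
    if kind == "column":
        colsum = M.sum(axis=0)
        if np.any(colsum <= 0):
            raise NormalizationError("column normalization: column sums to zero")
        return M / colsum[None, :]
    if kind == "row":
        rowsum = M.sum(axis=1)
        if np.any(rowsum <= 0):
            raise NormalizationError("row normalization: row sums to zero")
        return M / rowsum[:, None]
    if kind == "column_minmax":
        lo, hi = M.min(axis=0), M.max(axis=0)
        span = hi - lo
        if np.any(span == 0):
            if on_constant == "error":
                raise NormalizationError("column_minmax: constant column")
            span = np.where(span == 0, 1.0, span)
        return (M - lo[None, :]) / span[None, :]
    if kind == "global_minmax":
        lo, hi = M.min(), M.max()
        if hi == lo:
            raise NormalizationError("global_minmax: constant matrix")
        return (M - lo) / (hi - lo)
    if kind == "column_zscore":
        mean, sd = M.mean(axis=0), M.std(axis=0, ddof=0)
        if np.any(sd == 0):
            if on_constant == "error":
                raise NormalizationError("column_zscore: constant column")
            sd = np.where(sd == 0, 1.0, sd)
        return (M - mean[None, :]) / sd[None, :]
    if kind == "global_zscore":
        sd = M.std(ddof=0)
        if sd == 0:
            raise NormalizationError("global_zscore: constant matrix")
        return (M - M.mean()) / sd
    if kind == "quantile":
        return _quantile_normalize(M)
    if kind == "upper_quartile":
        q = np.percentile(M, 75, axis=0)
        if np.any(q <= 0):
            raise NormalizationError(
                "upper_quartile: a column's 75th percentile is zero (all "
                "normalization factors would be infinite or NA)"
            )
        return M / q[None, :]
    if kind == "tpm":
        lengths = p.get("gene_lengths")
        if lengths is None:
            lengths = np.ones(M.shape[0])
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != (M.shape[0],) or np.any(lengths <= 0):
            raise NormalizationError("tpm: gene_lengths must be positive, one per gene")
        rate = M / lengths[:, None]
        colsum = rate.sum(axis=0)
        if np.any(colsum <= 0):
            raise NormalizationError("tpm: column sums to zero")
        return rate / colsum[None, :] * 1e6
    if kind == "tmm":
        return tmm_cpm(M)
    if kind == "lognormalize_linear":
        scale = float(p.get("scale_factor", 1e4))
        colsum = M.sum(axis=0)
        if np.any(colsum <= 0):
            raise NormalizationError("lognormalize_linear: column sums to zero")
        if np.any(M < 0):
            raise NormalizationError("lognormalize_linear requires non-negative input")
        return np.expm1(np.log1p(M / colsum[None, :] * scale))
    if kind == "median_ratios":
        return _median_ratios(M)
    raise NormalizationError(f"unknown normalization {kind!r}")


# ---------------------------------------------------------------------------
# Compatibility checking
# ---------------------------------------------------------------------------

#: solvers whose model assumes non-negative inputs
_NONNEG_SOLVERS = {"nnls", "qp", "dwls"}
_ZSCORE_KINDS = {"column_zscore", "global_zscore"}


@dataclasses.dataclass
class CompatibilityResult:
    ok: bool
    reason: str | None = None


def check_compatibility(t, n, method: str, sparse_input: bool = False) -> CompatibilityResult:
    """Decide whether a (transform, normalization, solver) combination runs.

    Infeasible combinations are skipped with a reason, never silently
    dropped.
    """
    from .transforms import TransformKind  # local import to avoid cycle at load

    tk = t if isinstance(t, TransformKind) else TransformKind(str(t))
    nk = _as_kind(n)
    if nk.kind == "median_ratios" and tk.kind != "linear":
        return CompatibilityResult(
            False, "median_ratios requires linear integer counts"
        )
    if nk.kind == "upper_quartile" and sparse_input:
        return CompatibilityResult(
            False,
            "upper_quartile fails on sparse single-cell input (zero quartiles)",
        )
    if nk.kind in _ZSCORE_KINDS and method in _NONNEG_SOLVERS:
        return CompatibilityResult(
            False,
            f"{nk.kind} produces negative values, incompatible with the "
            f"non-negativity model of {method}",
        )
    return CompatibilityResult(True)
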