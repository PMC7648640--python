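"""Data transformations: linear, log, sqrt and a NB variance stabilizer.

``vst`` is a functional stand-in for the classic parametric
variance-stabilizing transformation: counts are size-factor normalized
(median of ratios, with a library-size fallback for sparse matrices),
per-gene dispersions are estimated by method of moments, the trend
``alpha(mu) = a1/mu + a0`` is fitted by least squares on positive
estimates, and the closed-form integral transform for the NB variance
function is applied on a log2-like scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np

TRANSFORMS = ("linear", "log", "sqrt", "vst")


@dataclasses.dataclass
class TransformKind:
    kind: str
    parameters: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.kind!r}; choose from {TRANSFORMS}")


def _as_kind(t) -> TransformKind:
    if isinstance(t, TransformKind):
        return t
    return TransformKind(str(t))


def size_factors_median_ratios(M: np.ndarray) -> np.ndarray:
    """Per-column size factors via the median-of-ratios scheme.

    Genes with a zero anywhere (geometric mean 0) are excluded; if fewer
    than 10 usable genes remain (sparse single-cell matrices), fall back
    to library-size factors scaled to geometric mean 1.
    """
    M = np.asarray(M, dtype=float)
    positive = np.all(M > 0, axis=1)
    if positive.sum() >= 10:
        logM = np.log(M[positive])
        log_geomean = logM.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logM - log_geomean, axis=0))
    else:
        lib = M.sum(axis=0)
        if np.any(lib <= 0):
            raise ValueError("cannot compute size factors: zero library size")
        factors = lib / np.exp(np.mean(np.log(lib)))
    return factors


def fit_dispersion_trend(M_norm: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a1/mu + a0 on method-of-moments dispersions.

    Returns (a0, a1), both clamped to small positive floors so the
    closed-form transform stays defined.
    """
    mu = M_norm.mean(axis=1)
    var = M_norm.var(axis=1, ddof=1) if M_norm.shape[1] > 1 else np.zeros_like(mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var - mu) / mu**2
    ok = np.isfinite(disp) & (disp > 0) & (mu > 0)
    if ok.sum() < 2:
        return 0.1, 0.0
    A = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(A, disp[ok], rcond=None)
    a0 = max(float(coef[0]), 1e-8)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def vst_closed_form(q: np.ndarray, a0: float, a1: float) -> np.ndarray:
    """Closed-form NB variance stabilizer on normalized counts ``q``."""
    q = np.asarray(q, dtype=float)
    inner = (1 + a1 + 2 * a0 * q + 2 * np.sqrt(a0 * q * (1 + a1 + a0 * q))) / (4 * a0)
    return np.log2(inner)


def transform(M: np.ndarray, t="linear") -> np.ndarray:
    """Apply one of the four benchmark transformations elementwise.

    ``linear`` is the identity, ``log`` is ln(1 + x), ``sqrt`` is the
    elementwise square root, ``vst`` is described in the module
    docstring.  Input must be finite and non-negative.
    """
    t = _as_kind(t)
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("transform input contains non-finite values")
    if np.any(M < 0):
        raise ValueError("transform input contains negative values")
    if t.kind == "linear":
        return M.copy()
    if t.kind == "log":
        return np.log1p(M)
    if t.kind == "sqrt":
        return np.sqrt(M)
    # vst
    factors = size_factors_median_ratios(M)
    q = M / factors[None, :]
    if "dispersion" in t.parameters:
        a0, a1 = float(t.parameters["dispersion"]), 0.0
    else:
        a0, a1 = fit_dispersion_trend(q)
    return vst_closed_form(q, a0, a1)


def inverse_transform(M: np.ndarray, t) -> np.ndarray:
    """Invert ``log``/``sqrt`` (and ``linear``); vst is not invertible here."""
    t = _as_kind(t)
    if t.kind == "linear":
        return np.asarray(M, dtype=float).copy()
    if t.kind == "log":
        return np.expm1(M)
    if t.kind == "sqrt":
        return np.square(M)
    raise ValueError(f"transform {t.kind!r} has no registered inverse")
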