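"""Deconvolution solvers implemented from their mathematical definitions.

All solvers take a signature matrix ``C`` (genes x cell types) and one
mixture column ``t`` and return a raw coefficient vector; proportions
come from :func:`postprocess_proportions` (clip negatives, renormalize).
External published methods are not re-implemented — the registry accepts
external callables via :func:`register_solver`.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize as sopt


class SolverError(RuntimeError):
    pass


def _check_inputs(C: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    C = np.asarray(C, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    if C.ndim != 2 or C.shape[0] != t.shape[0]:
        raise SolverError(f"shape mismatch: C {C.shape} vs t {t.shape}")
    if not (np.all(np.isfinite(C)) and np.all(np.isfinite(t))):
        raise SolverError("non-finite values in solver input")
    return C, t


def _warn_rank(C: np.ndarray) -> None:
    if np.linalg.matrix_rank(C) < C.shape[1]:
        warnings.warn("rank-deficient signature matrix; solution not unique", stacklevel=3)


# ---------------------------------------------------------------------------
# Least-squares family
# ---------------------------------------------------------------------------

def solve_ols(C, t) -> np.ndarray:
    """Unconstrained least squares (minimum-norm on rank deficiency)."""
    C, t = _check_inputs(C, t)
    _warn_rank(C)
    coef, *_ = np.linalg.lstsq(C, t, rcond=None)
    return coef


def solve_nnls(C, t) -> np.ndarray:
    """Non-negative least squares (active set)."""
    C, t = _check_inputs(C, t)
    _warn_rank(C)
    coef, _ = sopt.nnls(C, t)
    return coef


def solve_rlr(
    C, t, huber_c: float = 1.345, max_iter: int = 100, tol: float = 1e-8
) -> np.ndarray:
    """Robust linear regression: IRLS with Huber weights and MAD scale."""
    C, t = _check_inputs(C, t)
    coef, *_ = np.linalg.lstsq(C, t, rcond=None)
    for _ in range(max_iter):
        resid = t - C @ coef
        scale = np.median(np.abs(resid - np.median(resid))) * 1.4826
        if scale <= 1e-12:
            return coef  # (near-)exact fit, weights undefined
        u = np.abs(resid) / scale
        with np.errstate(divide="ignore"):
            w = np.where(u <= huber_c, 1.0, huber_c / u)
        sw = np.sqrt(w)
        new_coef, *_ = np.linalg.lstsq(C * sw[:, None], t * sw, rcond=None)
        if np.max(np.abs(new_coef - coef)) < tol:
            return new_coef
        coef = new_coef
    warnings.warn("RLR did not converge within max_iter; returning last iterate", stacklevel=2)
    return coef


def solve_qp(C, t) -> np.ndarray:
    """Least squares on the probability simplex (p >= 0, sum p = 1).

    Solved exactly by enumerating active sets: for every support, the
    equality-constrained KKT system is solved and the best feasible
    candidate wins.  Exact for the small type counts used here; falls
    back to SLSQP above 12 types.
    """
    C, t = _check_inputs(C, t)
    k = C.shape[1]
    if k > 12:
        return _solve_qp_slsqp(C, t)
    Q = C.T @ C
    c = C.T @ t
    best_obj, best_p = np.inf, None
    for support in range(1, 1 << k):
        idx = [j for j in range(k) if support >> j & 1]
        nf = len(idx)
        K = np.zeros((nf + 1, nf + 1))
        K[:nf, :nf] = Q[np.ix_(idx, idx)]
        K[:nf, nf] = 1.0
        K[nf, :nf] = 1.0
        rhs = np.concatenate([c[idx], [1.0]])
        try:
            sol = np.linalg.solve(K, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        p_f = sol[:nf]
        if np.any(p_f < -1e-9):
            continue
        p = np.zeros(k)
        p[idx] = np.clip(p_f, 0.0, None)
        s = p.sum()
        if s <= 0 or abs(s - 1.0) > 1e-6:
            continue
        p /= s
        obj = p @ Q @ p - 2 * c @ p
        if obj < best_obj - 1e-15:
            best_obj, best_p = obj, p
    if best_p is None:  # pragma: no cover - simplex is never empty
        return _solve_qp_slsqp(C, t)
    return best_p


def _solve_qp_slsqp(C: np.ndarray, t: np.ndarray) -> np.ndarray:
    k = C.shape[1]
    res = sopt.minimize(
        lambda p: 0.5 * np.sum((C @ p - t) ** 2),
        np.full(k, 1.0 / k),
        jac=lambda p: C.T @ (C @ p - t),
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    p = np.clip(res.x, 0.0, None)
    return p / p.sum()


# ---------------------------------------------------------------------------
# Penalized regression
# ---------------------------------------------------------------------------

def _gene_folds(n: int, n_folds: int, rng: np.random.Generator) -> list:
    idx = rng.permutation(n)
    return [idx[f::n_folds] for f in range(n_folds)]


def solve_penalized(
    C,
    t,
    penalty: str = "ridge",
    lambda_grid=None,
    mixing: float = 0.5,
    cv_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Ridge / lasso / elastic-net fit with lambda chosen by gene-fold CV.

    Ridge uses the closed form ``(C'C + lambda I)^-1 C't``; lasso and
    elastic net use scikit-learn's coordinate descent without intercept.
    """
    C, t = _check_inputs(C, t)
    if penalty not in ("ridge", "lasso", "elastic_net"):
        raise SolverError(f"unknown penalty {penalty!r}")
    if lambda_grid is None:
        lambda_grid = np.logspace(-6, 2, 9)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise SolverError("empty lambda grid")

    rng = np.random.default_rng(seed)
    folds = _gene_folds(C.shape[0], min(cv_folds, C.shape[0]), rng)

    def _fit(Ctr, ttr, lam):
        if penalty == "ridge":
            k = Ctr.shape[1]
            return np.linalg.solve(Ctr.T @ Ctr + lam * np.eye(k), Ctr.T @ ttr)
        from sklearn.linear_model import ElasticNet, Lasso

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if penalty == "lasso":
                model = Lasso(alpha=lam, fit_intercept=False, max_iter=50_000)
            else:
                model = ElasticNet(
                    alpha=lam, l1_ratio=mixing, fit_intercept=False, max_iter=50_000
                )
            model.fit(Ctr, ttr)
        return model.coef_

    cv_err = np.zeros(len(lambda_grid))
    for i, lam in enumerate(lambda_grid):
        for fold in folds:
            mask = np.ones(C.shape[0], dtype=bool)
            mask[fold] = False
            coef = _fit(C[mask], t[mask], lam)
            cv_err[i] += np.sum((C[fold] @ coef - t[fold]) ** 2)
    best = lambda_grid[int(np.argmin(cv_err))]
    return _fit(C, t, best)


# ---------------------------------------------------------------------------
# nu-SVR (CIBERSORT-style)
# ---------------------------------------------------------------------------

def solve_svr(C, t, nu_grid=(0.25, 0.5, 0.75)) -> np.ndarray:
    """Linear nu-SVR on z-scored inputs, best-of-grid by fit RMSE.

    The signature matrix is standardized matrix-wide, the mixture to its
    own mean/sd; the coefficients of the nu with the lowest RMSE between
    fitted and observed mixture are returned raw (negatives handled in
    post-processing).
    """
    from sklearn.svm import NuSVR

    C, t = _check_inputs(C, t)
    c_sd = C.std(ddof=1)
    t_sd = t.std(ddof=1)
    if c_sd == 0 or t_sd == 0:
        raise SolverError("constant inputs; SVR undefined")
    X = (C - C.mean()) / c_sd
    y = (t - t.mean()) / t_sd

    best_rmse, best_coef = np.inf, None
    for nu in nu_grid:
        try:
            model = NuSVR(kernel="linear", nu=nu, C=1.0)
            model.fit(X, y)
        except Exception:  # noqa: BLE001 - a failed nu is skipped, not fatal
            continue
        pred = model.predict(X)
        rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        if rmse < best_rmse:
            best_rmse, best_coef = rmse, model.coef_.ravel().copy()
    if best_coef is None:
        raise SolverError("SVR failed at every nu in the grid")
    return best_coef


# ---------------------------------------------------------------------------
# Dampened weighted least squares
# ---------------------------------------------------------------------------

def _weighted_nnls(C: np.ndarray, t: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    coef, _ = sopt.nnls(C * sw[:, None], t * sw)
    return coef


def solve_dwls(
    C,
    t,
    damping_grid=None,
    cv_folds: int = 4,
    max_iter: int = 50,
    tol: float = 1e-7,
    seed: int = 0,
) -> np.ndarray:
    """Iterative weighted NNLS with dampened inverse-squared-fit weights.

    Gene weights are ``1 / (C p)^2`` capped at ``d * min(w)``; the
    damping constant ``d`` is chosen once by cross-validation on gene
    subsets from the initial NNLS fit (``d = 1`` collapses to equal
    weights, i.e. plain NNLS; ``d -> inf`` leaves weights uncapped).
    """
    C, t = _check_inputs(C, t)
    if damping_grid is None:
        damping_grid = 2.0 ** np.arange(0, 11)
    damping_grid = np.asarray(damping_grid, dtype=float)

    p = solve_nnls(C, t)

    def _weights(p_hat: np.ndarray, d: float) -> np.ndarray:
        fitted = C @ p_hat
        with np.errstate(divide="ignore"):
            w = 1.0 / fitted**2
        finite = w[np.isfinite(w)]
        if finite.size == 0:
            return np.ones_like(fitted)
        w_min = finite.min()
        cap = d * w_min
        if not np.isfinite(cap):
            cap = finite.max()
        return np.clip(w, None, cap)

    rng = np.random.default_rng(seed)
    folds = _gene_folds(C.shape[0], min(cv_folds, C.shape[0]), rng)
    cv_err = np.zeros(len(damping_grid))
    for i, d in enumerate(damping_grid):
        w = _weights(p, d)
        for fold in folds:
            mask = np.ones(C.shape[0], dtype=bool)
            mask[fold] = False
            coef = _weighted_nnls(C[mask], t[mask], w[mask])
            cv_err[i] += np.sum(w[fold] * (C[fold] @ coef - t[fold]) ** 2)
    d_best = float(damping_grid[int(np.argmin(cv_err))])

    for _ in range(max_iter):
        w = _weights(p, d_best)
        p_new = _weighted_nnls(C, t, w)
        if np.max(np.abs(p_new - p)) < tol:
            return p_new
        p = p_new
    return p


# ---------------------------------------------------------------------------
# Post-processing and the registry
# ---------------------------------------------------------------------------

def postprocess_proportions(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Clip negatives and renormalize to the simplex.

    Returns ``(proportions, degenerate)``; an all-non-positive raw vector
    is degenerate and reported as NaNs.
    """
    raw = np.asarray(raw, dtype=float).ravel()
    if np.any(np.isnan(raw)):
        raise SolverError("NaN in raw coefficients")
    clipped = np.clip(raw, 0.0, None)
    total = clipped.sum()
    if total <= 0 or not np.isfinite(total):
        return np.full_like(clipped, np.nan), True
    return clipped / total, False


SOLVERS: dict = {
    "ols": solve_ols,
    "nnls": solve_nnls,
    "rlr": solve_rlr,
    "qp": solve_qp,
    "ridge": lambda C, t, **kw: solve_penalized(C, t, penalty="ridge", **kw),
    "lasso": lambda C, t, **kw: solve_penalized(C, t, penalty="lasso", **kw),
    "elastic_net": lambda C, t, **kw: solve_penalized(C, t, penalty="elastic_net", **kw),
    "svr": solve_svr,
    "dwls": solve_dwls,
}

#: the benchmark's default method list mirrors its top bulk performers
DEFAULT_METHODS = ("nnls", "svr", "rlr", "qp", "dwls")


def register_solver(name: str, fn) -> None:
    """Register an external solver callable ``fn(C, t, **kw) -> coefficients``."""
    SOLVERS[name] = fn


# ---------------------------------------------------------------------------
# End-to-end deconvolution of a MixtureSet
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DeconvolutionResult:
    P_C: np.ndarray | None  # cell types x mixtures (NaN where degenerate)
    raw_estimates: np.ndarray | None
    cell_type_ids: list
    mixture_ids: list
    method: str
    metadata: dict
    degenerate: np.ndarray | None = None
    skipped: bool = False
    skip_reason: str | None = None

    def proportions_frame(self):
        import pandas as pd

        return pd.DataFrame(self.P_C, index=self.cell_type_ids, columns=self.mixture_ids)


def deconvolve(
    mixtures,
    C,
    markers=None,
    method: str = "nnls",
    transform_kind="linear",
    scaling_t="none",
    scaling_c="none",
    solver_kwargs: dict | None = None,
) -> DeconvolutionResult:
    """Run one grid cell: subset to markers, transform, normalize, solve.

    Incompatible combinations are returned as recorded skips, not
    failures.  ``mixtures`` is a :class:`~deconvbench.pseudobulk.MixtureSet`,
    ``C`` a :class:`~deconvbench.reference.ReferenceMatrix`.
    """
    from .normalize import check_compatibility, normalize
    from .reference import subset_to_markers
    from .transforms import transform as apply_transform

    if method not in SOLVERS:
        raise SolverError(f"unknown method {method!r}; registered: {sorted(SOLVERS)}")
    meta = {
        "method": method,
        "transform": str(getattr(transform_kind, "kind", transform_kind)),
        "scalingT": str(getattr(scaling_t, "kind", scaling_t)),
        "scalingC": str(getattr(scaling_c, "kind", scaling_c)),
        "marker_strategy": None if markers is None else markers.strategy,
    }
    for scaling in (scaling_t, scaling_c):
        compat = check_compatibility(transform_kind, scaling, method)
        if not compat.ok:
            return DeconvolutionResult(
                P_C=None,
                raw_estimates=None,
                cell_type_ids=list(C.cell_type_ids),
                mixture_ids=list(mixtures.mixture_ids),
                method=method,
                metadata=meta,
                skipped=True,
                skip_reason=compat.reason,
            )

    if markers is not None:
        C = subset_to_markers(C, markers)
    gene_index = {g: i for i, g in enumerate(mixtures.gene_ids)}
    missing = [g for g in C.gene_ids if g not in gene_index]
    if missing:
        raise SolverError(f"reference genes absent from mixtures: {missing[:5]}")
    rows = [gene_index[g] for g in C.gene_ids]
    T_mat = mixtures.T[rows, :]

    T_mat = apply_transform(T_mat, transform_kind)
    C_mat = apply_transform(C.values, transform_kind)
    T_mat = normalize(T_mat, scaling_t, on_constant="zero")
    C_mat = normalize(C_mat, scaling_c, on_constant="zero")

    solver = SOLVERS[method]
    kwargs = dict(solver_kwargs or {})
    n_mix = T_mat.shape[1]
    k = C_mat.shape[1]
    raw = np.zeros((k, n_mix))
    P = np.zeros((k, n_mix))
    degenerate = np.zeros(n_mix, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for m in range(n_mix):
            coef = solver(C_mat, T_mat[:, m], **kwargs)
            raw[:, m] = coef
            props, degen = postprocess_proportions(coef)
            P[:, m] = props
            degenerate[m] = degen

    return DeconvolutionResult(
        P_C=P,
        raw_estimates=raw,
        cell_type_ids=list(C.cell_type_ids),
        mixture_ids=list(mixtures.mixture_ids),
        method=method,
        metadata=meta,
        degenerate=degenerate,
    )
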