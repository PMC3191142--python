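"""Bivariate VAR fitting and Geweke Granger-causality measures.

A series x Granger-causes y when x's past improves prediction of y beyond
y's own past.  Both series are modelled jointly as a vector autoregression
of order p: the *full* model regresses each series on p lags of both series
(plus an intercept), the *restricted* model on its own lags only.  Geweke's
measures are log variance ratios of the nested fits::

    F_{x->y} = ln( var(y | own past) / var(y | both pasts) )
    F_{y->x} = ln( var(x | own past) / var(x | both pasts) )
    F_{x.y}  = ln( var_f(x) var_f(y) / det Sigma_f )      (instantaneous)

with Sigma_f the 2x2 innovation covariance of the full model.  All are
nonnegative and invariant under per-series affine transforms.

Two fitters are provided: ordinary least squares, and Fast Orthogonal
Search (FOS) — a greedy regressor-selection scheme that admits candidate
terms one at a time by largest residual-variance reduction, computed via
Gram-Schmidt orthogonalization against the already-admitted terms, and
stops when the best relative reduction falls below a threshold.  At
threshold zero FOS admits every candidate and reproduces OLS exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

DEFAULT_ORDER = 5
DEFAULT_FOS_THRESHOLD = 1e-3

_RANK_TOL = 1e-10

Fitter = Literal["ols", "fos"]


# ---------------------------------------------------------------------------
# low-level design/Gram helpers (shared with the surrogate machinery)

def _validate_pair(x: np.ndarray, y: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if order < 1:
        raise ValueError("order must be >= 1")
    if x.size <= 10 * order:
        raise ValueError(f"need more than 10 x order = {10 * order} points")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("constant series: rank-deficient design")
    return x, y


def _lag_stack(series: np.ndarray, order: int) -> np.ndarray:
    """Matrix of lagged copies, shape (T - order, order); column k is lag k+1."""
    t = series.size
    return np.column_stack([series[order - lag : t - lag] for lag in range(1, order + 1)])


def _ols_fit(design: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares coefficients and residual vector."""
    coeffs, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient design (constant or duplicated series)")
    return coeffs, target - design @ coeffs


def _fos_select(
    gram: np.ndarray,
    xty: np.ndarray,
    yty: float,
    threshold: float,
    forced: tuple[int, ...] = (0,),
) -> tuple[list[int], float]:
    """Greedy orthogonal search on the normal equations.

    Parameters are the candidate Gram matrix ``gram`` (M x M), the
    candidate-target inner products ``xty`` (M,), and the target squared
    norm ``yty``.  Candidates in ``forced`` are admitted unconditionally
    first (the intercept); thereafter the candidate with the largest
    residual-sum-of-squares reduction is admitted while the best relative
    reduction (against the current RSS) is at least ``threshold``.

    Returns the admitted index list and the final RSS.
    """
    m = gram.shape[0]
    diag = np.diag(gram).copy()
    alpha = np.zeros((m, m))  # projections of candidates on orthonormal basis
    d_res = diag.copy()  # residual squared norms of candidates
    c_res = xty.astype(float).copy()  # residual correlations with target
    rss = float(yty)
    selected: list[int] = []
    available = np.ones(m, dtype=bool)

    def admit(j: int) -> None:
        nonlocal rss
        k = len(selected)
        scale = np.sqrt(d_res[j])
        a_new = (gram[:, j] - alpha[:, :k] @ alpha[j, :k]) / scale
        beta = c_res[j] / scale
        alpha[:, k] = a_new
        d_res_new = d_res - a_new**2
        c_res_new = c_res - a_new * beta
        d_res[:] = np.maximum(d_res_new, 0.0)
        c_res[:] = c_res_new
        rss = max(rss - beta**2, 0.0)
        selected.append(j)
        available[j] = False

    for j in forced:
        if d_res[j] <= _RANK_TOL * max(diag[j], 1.0):
            raise ValueError("forced regressor is degenerate")
        admit(j)

    while available.any():
        usable = available & (d_res > _RANK_TOL * np.maximum(diag, 1.0))
        if not usable.any():
            break
        reduction = np.where(usable, c_res**2 / np.where(usable, d_res, 1.0), -np.inf)
        j = int(np.argmax(reduction))
        if rss <= 0.0 or reduction[j] / rss < threshold:
            break
        admit(j)
    return selected, rss


def _solve_subset(gram: np.ndarray, xty: np.ndarray, subset: list[int], m: int) -> np.ndarray:
    """Least-squares coefficients of the admitted subset, zeros elsewhere."""
    coeffs = np.zeros(m)
    sub = np.array(subset, dtype=int)
    coeffs[sub] = np.linalg.solve(gram[np.ix_(sub, sub)], xty[sub])
    return coeffs


# ---------------------------------------------------------------------------
# public dataclasses

@dataclass(frozen=True)
class VarModel:
    """Fitted bivariate VAR of order p.

    Coefficient layout per equation: ``intercept``, ``own`` (lags 1..p of
    the equation's own series), ``cross`` (lags 1..p of the other series).
    Residual variances use divisor ``n_effective`` = T - p.
    """

    order: int
    n_effective: int
    coefficients: dict[str, dict[str, np.ndarray | float]]
    residual_variance_full: dict[str, float]
    residual_variance_restricted: dict[str, float]
    residual_covariance: np.ndarray

    def __post_init__(self) -> None:
        for eq in ("x", "y"):
            if self.residual_variance_full[eq] < 0 or self.residual_variance_restricted[eq] < 0:
                raise ValueError("negative residual variance")


@dataclass(frozen=True)
class GCResult:
    """Geweke causality measures for one ordered pair, with optional
    surrogate p-values (filled by the surrogate module)."""

    f_x_to_y: float
    f_y_to_x: float
    f_instantaneous: float
    p_x_to_y: float | None = None
    p_y_to_x: float | None = None
    significant_x_to_y: bool | None = None
    significant_y_to_x: bool | None = None


# ---------------------------------------------------------------------------
# fitting

def _fit(
    x: np.ndarray,
    y: np.ndarray,
    order: int,
    method: Fitter,
    fos_threshold: float,
) -> VarModel:
    x, y = _validate_pair(x, y, order)
    p = order
    n = x.size - p
    ones = np.ones(n)
    lx = _lag_stack(x, p)
    ly = _lag_stack(y, p)
    tx = x[p:]
    ty = y[p:]
    # column order: intercept, own lags, cross lags (per equation)
    full_x = np.column_stack([ones, lx, ly])
    full_y = np.column_stack([ones, ly, lx])
    restr_x = np.column_stack([ones, lx])
    restr_y = np.column_stack([ones, ly])

    def fit_one(design: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if method == "ols":
            return _ols_fit(design, target)
        gram = design.T @ design
        xty = design.T @ target
        subset, _ = _fos_select(gram, xty, float(target @ target), fos_threshold)
        coeffs = _solve_subset(gram, xty, subset, design.shape[1])
        return coeffs, target - design @ coeffs

    cf_x, res_fx = fit_one(full_x, tx)
    cf_y, res_fy = fit_one(full_y, ty)
    cr_x, res_rx = fit_one(restr_x, tx)
    cr_y, res_ry = fit_one(restr_y, ty)

    cov = np.array(
        [
            [res_fx @ res_fx, res_fx @ res_fy],
            [res_fy @ res_fx, res_fy @ res_fy],
        ]
    ) / n
    return VarModel(
        order=p,
        n_effective=n,
        coefficients={
            "x": {
                "intercept": float(cf_x[0]),
                "own": cf_x[1 : p + 1].copy(),
                "cross": cf_x[p + 1 :].copy(),
                "restricted_intercept": float(cr_x[0]),
                "restricted_own": cr_x[1:].copy(),
            },
            "y": {
                "intercept": float(cf_y[0]),
                "own": cf_y[1 : p + 1].copy(),
                "cross": cf_y[p + 1 :].copy(),
                "restricted_intercept": float(cr_y[0]),
                "restricted_own": cr_y[1:].copy(),
            },
        },
        residual_variance_full={"x": float(res_fx @ res_fx) / n, "y": float(res_fy @ res_fy) / n},
        residual_variance_restricted={"x": float(res_rx @ res_rx) / n, "y": float(res_ry @ res_ry) / n},
        residual_covariance=cov,
    )


def fit_var_ols(x: np.ndarray, y: np.ndarray, order: int = DEFAULT_ORDER) -> VarModel:
    """Fit the full and restricted bivariate VAR by ordinary least squares."""
    return _fit(x, y, order, "ols", 0.0)


def fit_var_fos(
    x: np.ndarray,
    y: np.ndarray,
    order: int = DEFAULT_ORDER,
    mse_reduction_threshold: float = DEFAULT_FOS_THRESHOLD,
) -> VarModel:
    """Fit by Fast Orthogonal Search (greedy term selection).

    The intercept is always admitted; lag candidates enter greedily while
    the best relative residual-variance reduction is at least
    ``mse_reduction_threshold``.  Un-admitted candidates get coefficient
    zero.  Threshold 0 reproduces :func:`fit_var_ols`.
    """
    if mse_reduction_threshold < 0:
        raise ValueError("mse_reduction_threshold must be >= 0")
    return _fit(x, y, order, "fos", mse_reduction_threshold)


def geweke_from_model(model: VarModel) -> GCResult:
    """Geweke measures from a fitted model (F fields only).

    Values are clipped at zero: OLS guarantees nonnegativity through
    nesting, FOS can produce tiny negative ratios when the greedy search
    stops at different subsets.
    """
    vfx = model.residual_variance_full["x"]
    vfy = model.residual_variance_full["y"]
    vrx = model.residual_variance_restricted["x"]
    vry = model.residual_variance_restricted["y"]
    if min(vfx, vfy) <= 0.0:
        raise ValueError("zero residual variance: series is perfectly predictable")
    det = float(np.linalg.det(model.residual_covariance))
    f_inst = max(0.0, float(np.log(vfx * vfy / det))) if det > 0 else float("inf")
    return GCResult(
        f_x_to_y=max(0.0, float(np.log(vry / vfy))),
        f_y_to_x=max(0.0, float(np.log(vrx / vfx))),
        f_instantaneous=f_inst,
    )


def geweke_measures(
    x: np.ndarray,
    y: np.ndarray,
    order: int = DEFAULT_ORDER,
    fitter: Fitter = "fos",
    fos_threshold: float = DEFAULT_FOS_THRESHOLD,
) -> GCResult:
    """Fit the bivariate VAR and return the Geweke measures."""
    if fitter == "ols":
        model = fit_var_ols(x, y, order)
    elif fitter == "fos":
        model = fit_var_fos(x, y, order, fos_threshold)
    else:
        raise ValueError(f"unknown fitter {fitter!r}")
    return geweke_from_model(model)


# ---------------------------------------------------------------------------
# model / results objects

class BivariateVAR:
    """Bivariate VAR model for one ordered pair of ROI time courses.

    Parameters
    ----------
    x, y : array-like, shape (T,)
        The two series (already preprocessed).
    order : int
        VAR order p; default 5 (inter-regional BOLD delays of roughly
        8 s at TR = 2 s).

    Examples
    --------
    >>> rng = np.random.default_rng(0)
    >>> x = rng.normal(size=2000)
    >>> y = np.empty_like(x)
    >>> y[0] = rng.normal()
    >>> y[1:] = 0.9 * x[:-1] + rng.normal(size=1999)
    >>> res = BivariateVAR(x, y, order=5).fit(method="ols")
    >>> res.f_x_to_y > 0.4 and res.f_y_to_x < 0.02
    True
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, order: int = DEFAULT_ORDER):
        self.x, self.y = _validate_pair(x, y, order)
        self.order = order

    def fit(
        self,
        method: Fitter = "fos",
        fos_threshold: float = DEFAULT_FOS_THRESHOLD,
    ) -> "BivariateVARResults":
        if method == "ols":
            model = fit_var_ols(self.x, self.y, self.order)
        else:
            model = fit_var_fos(self.x, self.y, self.order, fos_threshold)
        return BivariateVARResults(self, model, method)


class BivariateVARResults:
    """Fit results: coefficients, residual variances and Geweke measures."""

    def __init__(self, model: BivariateVAR, var_model: VarModel, method: Fitter):
        self.model = model
        self.var_model = var_model
        self.method = method
        self.gc = geweke_from_model(var_model)

    @property
    def f_x_to_y(self) -> float:
        return self.gc.f_x_to_y

    @property
    def f_y_to_x(self) -> float:
        return self.gc.f_y_to_x

    @property
    def f_instantaneous(self) -> float:
        return self.gc.f_instantaneous

    def summary(self) -> str:
        vm = self.var_model
        lines = [
            "Bivariate VAR Granger causality",
            "===============================",
            f"order: {vm.order}    n_effective: {vm.n_effective}    fitter: {self.method}",
            "",
            f"F_x->y: {self.f_x_to_y:.6f}",
            f"F_y->x: {self.f_y_to_x:.6f}",
            f"F_inst: {self.f_instantaneous:.6f}",
            "",
            "residual variances (full | restricted)",
            f"  x: {vm.residual_variance_full['x']:.6f} | {vm.residual_variance_restricted['x']:.6f}",
            f"  y: {vm.residual_variance_full['y']:.6f} | {vm.residual_variance_restricted['y']:.6f}",
        ]
        for eq in ("x", "y"):
            own = np.array2string(vm.coefficients[eq]["own"], precision=4)
            cross = np.array2string(vm.coefficients[eq]["cross"], precision=4)
            lines.append(f"  eq {eq}: own {own} cross {cross}")
        return "\n".join(lines)
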