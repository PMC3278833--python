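"""First-order vector autoregression estimators for gene networks.

The expression series is cast into the standard lagged regression

    Y = Z beta + E,     Y[t] = y(t+1),  Z[t] = y(t),  t = 0 .. T-2

and the I x I coefficient matrix beta (row = regulator, column = target) is
estimated column-by-column: ordinary least squares when T - 1 exceeds the
number of genes, or penalized regression (ridge, lasso, elastic net) with the
objective

    (1/2n) ||y_j - Z b||^2 + lambda * ( alpha ||b||_1 + (1-alpha)/2 ||b||_2^2 )

otherwise.  alpha = 0 is ridge (closed form), alpha = 1 the lasso, alpha in
(0,1) the elastic net (cyclic coordinate descent).

Penalty tuning follows the conventions of the reference coordinate-descent
software (glmnet): penalties are tuned per target gene by leave-one-out
cross-validation with predictors standardized and an intercept fitted within
each training fold; lasso and elastic net search a 100-value log-spaced
solution-path grid grown from the data and select the largest penalty whose
CV error is within one standard error of the minimum (the "1-SE" rule),
breaking exact ties toward the sparser model; ridge searches the fixed grid
{0.001, 0.1, 1, 10, 100} and selects the CV minimum (smallest lambda on
ties).  Standardization, intercept and selection rule are all exposed as
arguments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._solvers import MAX_SWEEPS, cd_path_gram, loocv_errors_gram
from .simulator import ExpressionMatrix

__all__ = [
    "RegressionDesign",
    "MVARModel",
    "ConvergenceError",
    "build_design",
    "fit_ols",
    "fit_penalized",
    "loocv_tune",
    "lambda_path",
    "RIDGE_LAMBDA_GRID",
    "ENET_ALPHA_GRID",
]

RIDGE_LAMBDA_GRID: tuple[float, ...] = (0.001, 0.1, 1.0, 10.0, 100.0)
ENET_ALPHA_GRID: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 10))

CD_TOL = 1e-7
N_LAMBDAS = 100


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge within the sweep budget."""


@dataclass
class RegressionDesign:
    """Aligned response/predictor matrices of the lag-1 regression."""

    Y: np.ndarray  # (T-1) x I responses, rows t = 1 .. T-1
    Z: np.ndarray  # (T-1) x I predictors, rows t = 0 .. T-2
    gene_labels: list[str]

    def __post_init__(self) -> None:
        self.Y = np.ascontiguousarray(self.Y, dtype=float)
        self.Z = np.ascontiguousarray(self.Z, dtype=float)
        if self.Y.shape != self.Z.shape:
            raise ValueError("Y and Z must have identical shapes")
        if len(self.gene_labels) != self.Y.shape[1]:
            raise ValueError("gene_labels length must match the number of genes")

    @property
    def n_samples(self) -> int:
        return self.Y.shape[0]

    @property
    def n_genes(self) -> int:
        return self.Y.shape[1]


@dataclass
class MVARModel:
    """Estimated lag-1 coefficient matrix with penalty metadata.

    beta_hat[i, j] estimates the effect of regulator i on target j; lambda_,
    alpha, dof (number of nonzero coefficients) and resid_sigma2 (residual
    variance) are per-target arrays of length I.  intercept holds the
    per-target intercepts (zero when none was fitted).
    """

    beta_hat: np.ndarray
    penalty: str
    lambda_: np.ndarray
    alpha: np.ndarray
    dof: np.ndarray
    resid_sigma2: np.ndarray
    gene_labels: list[str]
    intercept: np.ndarray | None = None
    rank_deficient: bool = False
    cv_sse: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.intercept is None:
            self.intercept = np.zeros(self.beta_hat.shape[1])

    @property
    def n_genes(self) -> int:
        return self.beta_hat.shape[0]


def build_design(data: ExpressionMatrix) -> RegressionDesign:
    """Lay the series out as (T-1) aligned response/predictor rows.

    Row t of Z is the expression vector one step before row t of Y.  No
    centering or scaling is applied here; estimators handle that themselves.
    """
    if data.n_timepoints < 2:
        raise ValueError(f"need at least 2 time points, got {data.n_timepoints}")
    series = data.values.T  # T x I
    return RegressionDesign(
        Y=series[1:], Z=series[:-1], gene_labels=list(data.gene_labels)
    )


def _finalize(
    design: RegressionDesign,
    beta_hat: np.ndarray,
    penalty: str,
    lambda_: np.ndarray,
    alpha: np.ndarray,
    intercept: np.ndarray | None = None,
    rank_deficient: bool = False,
    cv_sse: np.ndarray | None = None,
) -> MVARModel:
    """Attach per-target dof and residual variance to a fitted matrix."""
    n = design.n_samples
    resid = design.Y - design.Z @ beta_hat
    if intercept is not None:
        resid = resid - intercept
    rss = (resid**2).sum(axis=0)
    dof = (beta_hat != 0).sum(axis=0).astype(float)
    # residual dof = n - d, with d capped so the denominator stays >= 1
    denom = np.maximum(n - np.minimum(dof, n - 1), 1.0)
    sigma2 = np.maximum(rss / denom, np.finfo(float).eps)
    return MVARModel(
        beta_hat=beta_hat,
        penalty=penalty,
        lambda_=np.asarray(lambda_, dtype=float),
        alpha=np.asarray(alpha, dtype=float),
        dof=dof,
        resid_sigma2=sigma2,
        gene_labels=list(design.gene_labels),
        intercept=intercept,
        rank_deficient=rank_deficient,
        cv_sse=cv_sse,
    )


def fit_ols(design: RegressionDesign) -> MVARModel:
    """Ordinary least squares fit beta = (Z'Z)^-1 Z'Y.

    Requires more design rows than genes for a unique solution; a
    rank-deficient normal matrix falls back to the minimum-norm
    pseudo-inverse solution with a warning and is flagged on the model.
    """
    Z, Y = design.Z, design.Y
    beta_hat, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
    deficient = rank < design.n_genes
    if deficient:
        warnings.warn(
            f"design matrix has rank {rank} < {design.n_genes}; "
            "returning the minimum-norm least-squares solution",
            stacklevel=2,
        )
    zeros = np.zeros(design.n_genes)
    return _finalize(design, beta_hat, "ols", zeros, zeros, rank_deficient=deficient)


def _ridge_solve(G: np.ndarray, XY: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Ridge columns b_j = (G + lam_j I)^-1 XY[:, j] for per-target lam.

    The penalty enters the normal equations unscaled (the classical ridge
    parameterization on which the grid {0.001, ..., 100} is expressed),
    unlike the lasso/enet path scale which divides the loss by n.
    """
    p = G.shape[0]
    lam = np.broadcast_to(np.asarray(lam, dtype=float), (XY.shape[1],))
    beta = np.empty((p, XY.shape[1]))
    for lj in np.unique(lam):
        cols = np.nonzero(lam == lj)[0]
        beta[:, cols] = np.linalg.solve(G + lj * np.eye(p), XY[:, cols])
    return beta


def fit_penalized(
    design: RegressionDesign,
    penalty: str,
    lambda_: float | np.ndarray,
    alpha: float | np.ndarray | None = None,
    tol: float = CD_TOL,
) -> MVARModel:
    """Penalized fit at fixed regularization (no tuning, no standardization).

    ``lambda_`` and ``alpha`` may be scalars or per-target arrays.  Ridge is
    solved in closed form; lasso and elastic net by cyclic coordinate
    descent, iterated until the largest variance-weighted squared
    coefficient update in a sweep falls below ``tol`` times the response
    variance.
    """
    if penalty not in ("ridge", "lasso", "enet"):
        raise ValueError(f"unknown penalty {penalty!r}")
    I = design.n_genes
    lam = np.broadcast_to(np.asarray(lambda_, dtype=float), (I,)).copy()
    if (lam < 0).any():
        raise ValueError("lambda_ must be >= 0")
    if penalty == "ridge":
        alpha_arr = np.zeros(I)
    elif penalty == "lasso":
        alpha_arr = np.ones(I)
    else:
        if alpha is None:
            raise ValueError("elastic net requires alpha")
        alpha_arr = np.broadcast_to(np.asarray(alpha, dtype=float), (I,)).copy()
        if ((alpha_arr <= 0) | (alpha_arr >= 1)).any():
            raise ValueError("elastic-net alpha must lie in (0, 1)")

    Z, Y = design.Z, design.Y
    n = design.n_samples
    G = Z.T @ Z
    XY = Z.T @ Y
    if penalty == "ridge":
        beta_hat = _ridge_solve(G, XY, lam)
        return _finalize(design, beta_hat, penalty, lam, alpha_arr)

    yty_all = (Y**2).sum(axis=0)
    beta_hat = np.empty((I, I))
    for j in range(I):
        coefs, sweeps = cd_path_gram(
            G, XY[:, j], yty_all[j], n, np.array([lam[j]]),
            float(alpha_arr[j]), tol, MAX_SWEEPS,
        )
        if sweeps[0] >= MAX_SWEEPS:
            raise ConvergenceError(
                f"coordinate descent did not converge for target "
                f"{design.gene_labels[j]!r} after {MAX_SWEEPS} sweeps"
            )
        beta_hat[:, j] = coefs[0]
    return _finalize(design, beta_hat, penalty, lam, alpha_arr)


def _column_stats(
    Z: np.ndarray, standardize: bool, intercept: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Column locations and scales used for full-data fits.

    With an intercept, columns are centered at their means; scales are the
    population standard deviations (about the mean with an intercept, about
    zero without).  Constant columns get unit scale.
    """
    n = Z.shape[0]
    m = Z.mean(axis=0) if intercept else np.zeros(Z.shape[1])
    if standardize:
        sd = np.sqrt(((Z - m) ** 2).sum(axis=0) / n)
        sd[sd <= 1e-12] = 1.0
    else:
        sd = np.ones(Z.shape[1])
    return m, sd


def lambda_path(
    Z: np.ndarray,
    y: np.ndarray,
    l1_ratio: float,
    n_lambdas: int = N_LAMBDAS,
    standardize: bool = True,
    intercept: bool = True,
) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max (all-zero solution) downward.

    lambda_max = max|Z_s' y_c| / (n * l1_ratio) on the standardized/centered
    scale; the grid spans down to lambda_max * 1e-4 when rows exceed
    predictors, 1e-2 otherwise.
    """
    n, p = Z.shape
    m, sd = _column_stats(Z, standardize, intercept)
    yc = y - y.mean() if intercept else y
    lam_max = np.max(np.abs((Z - m).T @ yc / sd)) / (n * max(l1_ratio, 1e-12))
    if lam_max <= 0:
        return np.zeros(1)
    eps = 1e-4 if n > p else 1e-2
    return np.geomspace(lam_max, lam_max * eps, n_lambdas)


def _truncate_grid(
    grid: np.ndarray,
    coefs: np.ndarray,
    G: np.ndarray,
    Xy: np.ndarray,
    yty: float,
) -> int:
    """Number of leading path penalties to keep, by deviance saturation.

    Mirrors the reference path solver's early stopping: the descending
    penalty path is cut once the fraction of deviance explained increases by
    less than 1e-5 of itself between consecutive penalties, or exceeds
    0.999 — the tail of the path only refines an essentially saturated fit
    and would otherwise dominate CV comparisons with noise.
    """
    if yty <= 0:
        return 1
    rss = yty - 2.0 * coefs @ Xy + np.einsum("kp,pq,kq->k", coefs, G, coefs)
    rsq = 1.0 - rss / yty
    for k in range(1, len(grid)):
        if rsq[k] > 0.999 or rsq[k] - rsq[k - 1] < 1e-5 * max(rsq[k], 0.0):
            return k + 1
    return len(grid)


def _select(errs: np.ndarray, grid: np.ndarray, rule: str) -> int:
    """Index into a *descending* penalty grid per the selection rule.

    ``errs`` is (n_folds, n_lambdas).  "min": smallest mean CV error,
    ties toward the smallest penalty.  "1se": largest penalty whose mean CV
    error is within one standard error of the minimum.
    """
    mean = errs.mean(axis=0)
    if rule == "min":
        order = np.lexsort((grid, mean))
        return int(order[0])
    if rule == "1se":
        k_min = int(np.lexsort((grid, mean))[0])
        se = errs[:, k_min].std(ddof=1) / np.sqrt(errs.shape[0])
        within = np.nonzero(mean <= mean[k_min] + se)[0]
        return int(within[0])  # grid is descending: first index = largest lam
    raise ValueError(f"unknown selection rule {rule!r}")


def _loocv_ridge(
    design: RegressionDesign,
    grid: np.ndarray,
    standardize: bool,
    intercept: bool,
) -> np.ndarray:
    """Per-fold, per-penalty, per-target squared LOOCV errors for ridge.

    Exact leave-one-out refits with fold-wise centering/standardization,
    vectorized across targets (all targets share the fold design).
    Returns an (n, n_lambdas, I) error array.
    """
    Z, Y = design.Z, design.Y
    n, p = Z.shape
    G = Z.T @ Z
    XY = Z.T @ Y
    col_sum = Z.sum(axis=0)
    y_sum = Y.sum(axis=0)
    errs = np.empty((n, len(grid), design.n_genes))
    for i in range(n):
        zi = Z[i]
        nf = n - 1
        Gi = G - np.outer(zi, zi)
        XYi = XY - np.outer(zi, Y[i])
        if intercept:
            m = (col_sum - zi) / nf
            ym = (y_sum - Y[i]) / nf
            Gi = Gi - nf * np.outer(m, m)
            XYi = XYi - nf * np.outer(m, ym)
        else:
            m = np.zeros(p)
            ym = np.zeros(design.n_genes)
        if standardize:
            sd = np.sqrt(np.clip(np.diag(Gi) / nf, 1e-24, None))
            sd[sd <= 1e-12] = 1.0
            Gi = Gi / np.outer(sd, sd)
            XYi = XYi / sd[:, None]
        else:
            sd = np.ones(p)
        z_scaled = (zi - m) / sd
        for il, lam in enumerate(grid):
            beta = np.linalg.solve(Gi + lam * np.eye(p), XYi)
            pred = ym + z_scaled @ beta
            errs[i, il] = (Y[i] - pred) ** 2
    return errs


def loocv_tune(
    data: ExpressionMatrix,
    penalty: str,
    lambda_grid: np.ndarray | None = None,
    alpha_grid: np.ndarray | None = None,
    standardize: bool = True,
    fit_intercept: bool = True,
    selection: str | None = None,
) -> MVARModel:
    """Leave-one-out cross-validated penalty selection and final fit.

    Each design row is held out in turn, the model refit on the remaining
    rows for every candidate penalty (with the fold's own standardization
    and intercept), and squared prediction error on the held-out row
    accumulated.  The penalty is chosen per target gene — by the 1-SE rule
    for lasso/enet, by the CV minimum for ridge (override via ``selection``)
    — and the final model is refit on all rows and reported on the original
    data scale.  For lasso/enet, the lambda grid defaults to the per-target
    solution path; for enet, every (alpha, lambda) combination over the
    alpha grid {0.1, ..., 0.9} competes.
    """
    if penalty not in ("ridge", "lasso", "enet"):
        raise ValueError(f"unknown penalty {penalty!r}")
    if data.n_timepoints < 3:
        raise ValueError("LOOCV needs at least 3 time points (2 design rows)")
    rule = selection or ("min" if penalty == "ridge" else "1se")
    design = build_design(data)
    Z, Y = design.Z, design.Y
    n, I = design.n_samples, design.n_genes
    m_full, sd_full = _column_stats(Z, standardize, fit_intercept)
    Zs = (Z - m_full) / sd_full
    Gs = Zs.T @ Zs

    if penalty == "ridge":
        grid = np.asarray(
            RIDGE_LAMBDA_GRID if lambda_grid is None else lambda_grid, dtype=float
        )
        if grid.size == 0:
            raise ValueError("empty lambda grid")
        errs = _loocv_ridge(design, grid, standardize, fit_intercept)
        best_lam = np.empty(I)
        best_sse = np.empty(I)
        for j in range(I):
            k = _select(errs[:, :, j], grid, rule)
            best_lam[j] = grid[k]
            best_sse[j] = errs[:, k, j].sum()
        ym_full = Y.mean(axis=0) if fit_intercept else np.zeros(I)
        beta_s = _ridge_solve(Gs, Zs.T @ (Y - ym_full), best_lam)
        beta_hat = beta_s / sd_full[:, None]
        intercept = ym_full - m_full @ beta_hat if fit_intercept else None
        return _finalize(
            design, beta_hat, "ridge", best_lam, np.zeros(I),
            intercept=intercept, cv_sse=best_sse,
        )

    if penalty == "lasso":
        alphas = np.array([1.0])
    else:
        alphas = np.asarray(
            ENET_ALPHA_GRID if alpha_grid is None else alpha_grid, dtype=float
        )
        if alphas.size == 0:
            raise ValueError("empty alpha grid")

    Zc = np.ascontiguousarray(Z)
    best_lam = np.empty(I)
    best_alpha = np.empty(I)
    best_sse = np.empty(I)
    beta_hat = np.empty((I, I))
    ym_full = Y.mean(axis=0) if fit_intercept else np.zeros(I)
    for j in range(I):
        y = np.ascontiguousarray(Y[:, j])
        yc = y - ym_full[j]
        Xy_s = Zs.T @ yc
        yty_c = float(yc @ yc)
        # the mixing weight alpha is chosen by the minimum CV error over its
        # whole curve (ties toward the smaller alpha); the selection rule is
        # then applied within the winning curve
        chosen: tuple[float, float, np.ndarray, np.ndarray, np.ndarray] | None = None
        for a in alphas:
            grid = (
                lambda_path(Zc, y, a, standardize=standardize, intercept=fit_intercept)
                if lambda_grid is None
                else np.asarray(lambda_grid, dtype=float)
            )
            if grid.size == 0:
                raise ValueError("empty lambda grid")
            # full-data path first: its deviance saturation truncates the
            # grid the CV folds are evaluated on.  The response is scaled to
            # unit variance and the penalty grid divided by its scale (the
            # reference software's internal normalization; the reported
            # penalty then weights L1 invariantly but L2 inversely to the
            # response scale)
            ys = np.sqrt(yty_c / n) if yty_c > 0 else 1.0
            full_coefs, sweeps = cd_path_gram(
                Gs, Xy_s / ys, yty_c / ys**2, n, grid / ys,
                float(a), CD_TOL, MAX_SWEEPS,
            )
            full_coefs = full_coefs * ys
            if sweeps[-1] >= MAX_SWEEPS:
                raise ConvergenceError(
                    f"coordinate descent did not converge for target "
                    f"{design.gene_labels[j]!r} after {MAX_SWEEPS} sweeps"
                )
            if lambda_grid is None:
                keep = _truncate_grid(grid, full_coefs, Gs, Xy_s, yty_c)
                grid, full_coefs = grid[:keep], full_coefs[:keep]
            errs = loocv_errors_gram(
                Zc, y, grid, float(a), CD_TOL, MAX_SWEEPS,
                standardize, fit_intercept, True,
            )
            cand = (float(errs.mean(axis=0).min()), float(a))
            if chosen is None or cand < chosen[:2]:
                chosen = (*cand, grid, errs, full_coefs)
        _, alpha_j, grid_j, errs_j, coefs_j = chosen
        k_j = _select(errs_j, grid_j, rule)
        best_sse[j] = errs_j[:, k_j].sum()
        best_lam[j] = grid_j[k_j]
        best_alpha[j] = alpha_j
        beta_hat[:, j] = coefs_j[k_j] / sd_full

    intercept = ym_full - m_full @ beta_hat if fit_intercept else None
    return _finalize(
        design, beta_hat, penalty, best_lam,
        best_alpha if penalty == "enet" else np.ones(I),
        intercept=intercept, cv_sse=best_sse,
    )
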