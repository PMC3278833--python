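"""Gram-based cyclic coordinate descent for lasso / elastic-net paths.

The penalized least-squares objective, per response vector y and predictor
matrix Z with n rows, is

    (1/2n) ||y - Z b||^2 + lam * ( l1 * ||b||_1 + (1 - l1)/2 * ||b||_2^2 )

with l1 = 1 for the lasso, l1 in (0,1) for the elastic net.  The solver works
entirely on the Gram statistics (Z'Z, Z'y, y'y), so leave-one-out folds are
rank-1 downdates instead of refits from raw data; paths are warm-started from
the previous penalty value.  Convergence follows the reference
coordinate-descent software (glmnet): a sweep terminates the iteration when
the largest variance-weighted squared coefficient update,
max_j (G_jj/n) * delta_j^2, falls below ``tol`` times the response variance
y'y/n.

The LOOCV driver optionally centers the response and centers/standardizes the
predictors *within each training fold* (the convention of reference
coordinate-descent software); coefficients then live on the standardized
scale and held-out predictions are formed with the fold's own location and
scale.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_SWEEPS = 10_000


@njit(cache=True)
def _objective(G, Xy, yty, n, beta, lam, l1):
    lin = 0.0
    quad = 0.0
    pen1 = 0.0
    pen2 = 0.0
    p = beta.shape[0]
    for j in range(p):
        lin += Xy[j] * beta[j]
        pen1 += abs(beta[j])
        pen2 += beta[j] * beta[j]
        acc = 0.0
        for k in range(p):
            acc += G[j, k] * beta[k]
        quad += beta[j] * acc
    return 0.5 * (yty - 2.0 * lin + quad) / n + lam * (
        l1 * pen1 + 0.5 * (1.0 - l1) * pen2
    )


@njit(cache=True)
def cd_path_gram(G, Xy, yty, n, lam_grid, l1, tol, max_sweeps):
    """Coordinate-descent solution path over a penalty grid.

    Returns (coefs, sweeps): coefs has shape (n_lambdas, p); sweeps[i] is the
    number of full cyclic sweeps used at lam_grid[i] (== max_sweeps signals
    non-convergence).  beta is warm-started along the grid.
    """
    p = G.shape[0]
    n_lam = lam_grid.shape[0]
    coefs = np.zeros((n_lam, p))
    sweeps = np.zeros(n_lam, dtype=np.int64)
    beta = np.zeros(p)
    thr = tol * max(yty / n, 1e-30)
    for il in range(n_lam):
        lam = lam_grid[il]
        nl1 = n * lam * l1
        nl2 = n * lam * (1.0 - l1)
        it = 0
        while it < max_sweeps:
            it += 1
            dlx = 0.0
            for j in range(p):
                acc = 0.0
                for k in range(p):
                    acc += G[j, k] * beta[k]
                rho = Xy[j] - acc + G[j, j] * beta[j]
                denom = G[j, j] + nl2
                if denom <= 0.0:
                    bj = 0.0
                elif rho > nl1:
                    bj = (rho - nl1) / denom
                elif rho < -nl1:
                    bj = (rho + nl1) / denom
                else:
                    bj = 0.0
                d = bj - beta[j]
                beta[j] = bj
                w = (G[j, j] / n) * d * d
                if w > dlx:
                    dlx = w
            if dlx < thr:
                break
        coefs[il] = beta
        sweeps[il] = it
    return coefs, sweeps


@njit(cache=True)
def loocv_errors_gram(
    Z, y, lam_grid, l1, tol, max_sweeps, standardize, intercept, scale_y
):
    """Per-fold squared LOOCV prediction errors along a penalty grid.

    Each row of Z is held out in turn.  The remaining rows' Gram statistics
    are obtained by rank-1 downdate; when ``intercept`` the fold response and
    predictors are mean-centered, and when ``standardize`` the predictors are
    additionally scaled to unit (population) variance, all on the Gram
    statistics directly.  With ``scale_y`` the fold response is further
    scaled to unit variance and the penalty grid divided by the fold's
    response scale — the internal normalization of the reference software,
    under which the reported penalty weights the L1 term invariantly but the
    L2 term inversely to the response scale.  Returns an (n, n_lambdas)
    matrix of squared errors on the held-out rows, suitable for both the
    minimum-error and the one-standard-error selection rules.
    """
    n, p = Z.shape
    n_lam = lam_grid.shape[0]
    G = np.dot(Z.T, Z)
    Xy = np.dot(Z.T, y)
    yty = np.dot(y, y)
    col_sum = np.zeros(p)
    for i in range(n):
        for j in range(p):
            col_sum[j] += Z[i, j]
    y_sum = np.sum(y)
    errs = np.empty((n, n_lam))
    m = np.zeros(p)
    sd = np.ones(p)
    for i in range(n):
        zi = Z[i]
        nf = n - 1
        Gi = G - np.outer(zi, zi)
        Xyi = Xy - zi * y[i]
        ytyi = yty - y[i] * y[i]
        ym = 0.0
        if intercept:
            for j in range(p):
                m[j] = (col_sum[j] - zi[j]) / nf
            ym = (y_sum - y[i]) / nf
            Gi = Gi - nf * np.outer(m, m)
            Xyi = Xyi - nf * m * ym
            ytyi = ytyi - nf * ym * ym
        else:
            for j in range(p):
                m[j] = 0.0
        if standardize:
            for j in range(p):
                v = Gi[j, j] / nf
                sd[j] = np.sqrt(v) if v > 1e-24 else 1.0
            Gi = Gi / np.outer(sd, sd)
            Xyi = Xyi / sd
        else:
            for j in range(p):
                sd[j] = 1.0
        if scale_y:
            ys2 = ytyi / nf
            ys = np.sqrt(ys2) if ys2 > 1e-24 else 1.0
            coefs, _ = cd_path_gram(
                Gi, Xyi / ys, ytyi / (ys * ys), nf, lam_grid / ys, l1, tol, max_sweeps
            )
            coefs = coefs * ys
        else:
            coefs, _ = cd_path_gram(Gi, Xyi, ytyi, nf, lam_grid, l1, tol, max_sweeps)
        z_scaled = (zi - m) / sd
        for il in range(n_lam):
            err = y[i] - ym - np.dot(coefs[il], z_scaled)
            errs[i, il] = err * err
    return errs
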