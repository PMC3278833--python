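"""From estimated coefficients to a network: edge detection, approximate
significance of penalized coefficients, and FDR-controlled selection.

Edges are declared where |beta_hat| exceeds a small magnitude cutoff
(default 1e-4).  For real-data workflows a coefficient-level test is
available: the sampling variance of a penalized coefficient is approximated
with the ridge-type sandwich

    (Z'Z + lam W^-)^-1  Z'Z  (Z'Z + lam W^-)^-1

where W is the diagonal matrix of |beta_hat| for the target's regression and
W^- its generalized inverse, so the statistic beta_k / sqrt(sigma2 * w_k) is
referred to a t distribution whose degrees of freedom equal the number of
nonzero coefficients.  P-values over all I^2 coefficients are corrected
together by the Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mvar import MVARModel, RegressionDesign
from .topology import ConnectivityMatrix

__all__ = [
    "SignificanceResult",
    "detect_edges",
    "coefficient_pvalues",
    "fdr_select",
    "write_edge_table",
]

DEFAULT_EPSILON = 1e-4


@dataclass
class SignificanceResult:
    """Coefficient p-values and the BH rejection mask at FDR level q."""

    pvalues: np.ndarray  # I x I, [0, 1]
    q: float
    significant: np.ndarray  # I x I boolean mask
    dof_used: np.ndarray  # per-target degrees of freedom
    w_diag: np.ndarray  # I x I sandwich diagonal (variance factors)

    def network(self, gene_labels: list[str]) -> ConnectivityMatrix:
        return ConnectivityMatrix(self.significant.astype(np.int8), list(gene_labels))


def detect_edges(
    model: MVARModel, epsilon: float = DEFAULT_EPSILON
) -> ConnectivityMatrix:
    """Threshold the coefficient matrix: edge (i, j) iff |beta_ij| > epsilon.

    All I^2 entries, including the diagonal, are candidate edges.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    adjacency = (np.abs(model.beta_hat) > epsilon).astype(np.int8)
    return ConnectivityMatrix(adjacency, list(model.gene_labels))


def coefficient_pvalues(
    model: MVARModel, design: RegressionDesign, q: float = 0.05
) -> SignificanceResult:
    """Approximate two-sided p-values for every penalized coefficient.

    Per target gene j: with d_j nonzero coefficients and residual variance
    sigma2_j, the variance factor w_k of coefficient k is the k-th diagonal
    element of (Z'Z + lam_j W^-)^-1 Z'Z (Z'Z + lam_j W^-)^-1, with
    W = diag(|beta_hat[:, j]|) and lam_j the tuned penalty on the raw
    (unnormalized) least-squares scale.  Zero coefficients get p = 1.
    The BH rejection mask over all I^2 p-values at level q is attached.
    """
    if model.beta_hat.shape[1] != design.n_genes:
        raise ValueError("model and design dimensions disagree")
    Z = design.Z
    n = design.n_samples
    G = Z.T @ Z
    I = design.n_genes
    pvalues = np.ones((I, I))
    w_diag = np.zeros((I, I))
    dof_used = np.zeros(I)

    for j in range(I):
        beta_j = model.beta_hat[:, j]
        nonzero = beta_j != 0
        if not nonzero.any():
            dof_used[j] = 0
            continue
        d = int(model.dof[j])  # nonzero-coefficient count for lasso/enet
        dof_used[j] = d
        if d <= 0:
            raise ValueError(
                f"degenerate degrees of freedom ({d}) for target "
                f"{j} with nonempty support"
            )
        # generalized inverse of W = diag(|beta|): reciprocal on the support
        w_pinv = np.zeros(I)
        w_pinv[nonzero] = 1.0 / np.abs(beta_j[nonzero])
        # lasso/enet penalties live on the 1/(2n) path scale, so the raw
        # RSS-scale weight is n * lambda; ridge lambda is already raw
        scale = 1.0 if model.penalty == "ridge" else n
        lam_raw = scale * float(model.lambda_[j])
        A = G + lam_raw * np.diag(w_pinv)
        try:
            A_inv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            import warnings

            warnings.warn(
                "singular (Z'Z + lam W^-); using pseudo-inverse", stacklevel=2
            )
            A_inv = np.linalg.pinv(A)
        sandwich = A_inv @ G @ A_inv
        wk = np.clip(np.diag(sandwich), 0.0, None)
        w_diag[:, j] = wk
        se = np.sqrt(model.resid_sigma2[j] * wk[nonzero])
        tstat = np.zeros(int(nonzero.sum()))
        ok = se > 0
        tstat[ok] = np.abs(beta_j[nonzero][ok]) / se[ok]
        tstat[~ok] = np.inf
        pvalues[nonzero, j] = 2.0 * stats.t.sf(tstat, df=d)

    significant = fdr_select(pvalues, q)
    return SignificanceResult(
        pvalues=pvalues, q=q, significant=significant, dof_used=dof_used, w_diag=w_diag
    )


def fdr_select(pvalues: np.ndarray, q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up over all entries of a p-value array.

    Sorted p-values P_(1) <= ... <= P_(n) are compared with k*q/n; all
    hypotheses up to the largest k with P_(k) <= k*q/n are rejected.
    Returns a boolean mask of the rejection set, same shape as the input.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    if ((pvalues < 0) | (pvalues > 1)).any() or np.isnan(pvalues).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvalues.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(pvalues.shape)


def write_edge_table(
    model: MVARModel,
    path: str | Path,
    epsilon: float = DEFAULT_EPSILON,
    significance: SignificanceResult | None = None,
) -> pd.DataFrame:
    """Write a long-format edge table: regulator, target, beta, [p, significant].

    Rows are the entries passing the magnitude cutoff; the table is also
    returned.
    """
    detected = detect_edges(model, epsilon)
    rows, cols = np.nonzero(detected.adjacency)
    labels = model.gene_labels
    table = pd.DataFrame(
        {
            "regulator": [labels[i] for i in rows],
            "target": [labels[j] for j in cols],
            "beta": model.beta_hat[rows, cols],
        }
    )
    if significance is not None:
        table["p"] = significance.pvalues[rows, cols]
        table["significant"] = significance.significant[rows, cols]
    table.to_csv(path, index=False)
    return table
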