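"""Synthetic gene-expression time series from a first-order vector
autoregression on a known regulatory structure.

Given a ground-truth topology, regulatory coefficients beta_ij are drawn with
magnitude uniform on [0.8, 1] (signs balanced) on the edges and exactly zero
elsewhere.  Expression trajectories follow

    y(t) = y(t-1) beta + eps(t),    eps(t) ~ N(0, Sigma)

with the initial expression vector uniform on [10, 15] and innovation
covariance Sigma = I by default.  An additive Gaussian perturbation of
standard deviation (sigma + delta) at every entry models measurement-level
noise injection at a controlled signal-to-noise ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .topology import ConnectivityMatrix

__all__ = [
    "ExpressionMatrix",
    "CoefficientMatrix",
    "NoiseSpec",
    "sample_coefficients",
    "simulate_timeseries",
    "perturb",
    "delta_for_snr",
    "read_expression_tsv",
    "write_expression_tsv",
]


@dataclass
class ExpressionMatrix:
    """Real-valued expressions of I genes over T equally spaced time points.

    ``values[i, t]`` is the expression of gene *i* at time index *t*.
    """

    values: np.ndarray
    gene_labels: list[str] = field(default=None)  # type: ignore[assignment]
    time_labels: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D (genes x time), got {values.ndim}-D")
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        self.values = values
        n_genes, n_time = values.shape
        if self.gene_labels is None:
            from .topology import default_gene_labels

            self.gene_labels = default_gene_labels(n_genes)
        else:
            self.gene_labels = list(self.gene_labels)
        if self.time_labels is None:
            self.time_labels = list(range(n_time))
        else:
            self.time_labels = list(self.time_labels)
        if len(self.gene_labels) != n_genes:
            raise ValueError("gene_labels length must match number of rows")
        if len(self.time_labels) != n_time:
            raise ValueError("time_labels length must match number of columns")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_labels, columns=self.time_labels
        )


@dataclass
class CoefficientMatrix:
    """Ground-truth autoregressive coefficients tied to their support.

    ``beta[i, j]`` is the lag-1 effect of regulator *i* on target *j*; it is
    nonzero exactly where the support topology has an edge.
    """

    beta: np.ndarray
    support: ConnectivityMatrix

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if beta.shape != self.support.adjacency.shape:
            raise ValueError("beta shape must match support adjacency")
        if ((beta != 0) != (self.support.adjacency == 1)).any():
            raise ValueError("beta must be nonzero exactly on the support edges")
        self.beta = beta


@dataclass(frozen=True)
class NoiseSpec:
    """Innovation and perturbation noise levels.

    innovation_cov
        Covariance of the i.i.d. Gaussian innovations driving the dynamics;
        a scalar means that multiple of the identity (default 1.0 -> Sigma=I).
    perturb_sigma, perturb_delta
        Residual standard deviation sigma of the unperturbed data and the
        perturbation constant delta; injected noise has sd (sigma + delta).
    """

    innovation_cov: float | np.ndarray = 1.0
    perturb_sigma: float = 0.0
    perturb_delta: float = 0.0

    def covariance(self, n_genes: int) -> np.ndarray:
        cov = self.innovation_cov
        if np.isscalar(cov):
            if cov < 0:
                raise ValueError("scalar innovation covariance must be >= 0")
            return float(cov) * np.eye(n_genes)
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (n_genes, n_genes):
            raise ValueError(f"innovation covariance must be {n_genes}x{n_genes}")
        if not np.allclose(cov, cov.T):
            raise ValueError("innovation covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-10 * max(1.0, eigvals.max()):
            raise ValueError("innovation covariance must be positive semi-definite")
        return cov


def sample_coefficients(
    support: ConnectivityMatrix,
    low: float = 0.8,
    high: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> CoefficientMatrix:
    """Draw autoregressive coefficients on the support edges.

    Magnitudes are uniform on [low, high]; signs are assigned so the numbers
    of positive and negative coefficients differ by at most one (a random
    half of a shuffled edge order is flipped negative).  Non-edges are
    exactly zero.
    """
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    rng = np.random.default_rng(seed)
    n_edges = support.n_edges
    beta = np.zeros(support.adjacency.shape)
    if n_edges == 0:
        return CoefficientMatrix(beta, support)
    magnitudes = rng.uniform(low, high, size=n_edges)
    signs = np.ones(n_edges)
    signs[: n_edges // 2] = -1.0
    rng.shuffle(signs)
    beta[support.adjacency == 1] = magnitudes * signs
    return CoefficientMatrix(beta, support)


def simulate_timeseries(
    coeffs: CoefficientMatrix,
    n_timepoints: int,
    init_low: float = 10.0,
    init_high: float = 15.0,
    noise: NoiseSpec | None = None,
    seed: int | np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Simulate an expression time series from the lag-1 autoregression.

    The t=0 expression vector is uniform on [init_low, init_high]; each later
    time point is y(t) = y(t-1) beta + eps(t) with Gaussian innovations of
    the given covariance (identity by default).
    """
    if n_timepoints < 2:
        raise ValueError(f"n_timepoints must be >= 2, got {n_timepoints}")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    n_genes = coeffs.beta.shape[0]
    cov = noise.covariance(n_genes)

    traj = np.empty((n_timepoints, n_genes))
    traj[0] = rng.uniform(init_low, init_high, size=n_genes)
    if np.allclose(cov, 0.0):
        innovations = np.zeros((n_timepoints - 1, n_genes))
    elif np.allclose(cov, cov[0, 0] * np.eye(n_genes)):
        innovations = rng.normal(
            0.0, math.sqrt(cov[0, 0]), size=(n_timepoints - 1, n_genes)
        )
    else:
        innovations = rng.multivariate_normal(
            np.zeros(n_genes), cov, size=n_timepoints - 1, method="cholesky"
        )
    for t in range(1, n_timepoints):
        traj[t] = traj[t - 1] @ coeffs.beta + innovations[t - 1]

    return ExpressionMatrix(traj.T, list(coeffs.support.gene_labels))


def perturb(
    data: ExpressionMatrix,
    sigma: float,
    delta: float,
    seed: int | np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Add i.i.d. Gaussian noise of standard deviation (sigma + delta) to
    every entry; labels and shape are preserved."""
    sd = sigma + delta
    if sd < 0:
        raise ValueError(f"sigma + delta must be >= 0, got {sd}")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sd, size=data.values.shape) if sd > 0 else 0.0
    return ExpressionMatrix(
        data.values + noise, list(data.gene_labels), list(data.time_labels)
    )


def delta_for_snr(target_snr: float, signal_variance: float, sigma: float) -> float:
    """Perturbation constant delta achieving a target signal-to-noise ratio.

    SNR is defined as signal_variance / (sigma + delta)**2, so
    delta = sqrt(signal_variance / target_snr) - sigma.  Higher SNR means a
    milder perturbation.
    """
    if target_snr <= 0:
        raise ValueError(f"target_snr must be > 0, got {target_snr}")
    if signal_variance <= 0:
        raise ValueError(f"signal_variance must be > 0, got {signal_variance}")
    return math.sqrt(signal_variance / target_snr) - sigma


def snr_of(signal_variance: float, sigma: float, delta: float) -> float:
    """Signal-to-noise ratio of a perturbation with sd (sigma + delta)."""
    sd = sigma + delta
    if sd <= 0:
        return math.inf
    return signal_variance / sd**2


# ---------------------------------------------------------------------------
# TSV round-trip: genes as rows, header row = time labels


def write_expression_tsv(data: ExpressionMatrix, path: str | Path) -> None:
    df = data.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.to_numpy(), list(df.index), list(df.columns))
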