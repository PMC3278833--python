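"""Stability and accuracy scoring for collections of inferred networks.

Replicate or perturbed datasets yield an ensemble of B binary networks over
the same gene panel.  Structural reproducibility is quantified by

* pairwise stability  rho(a, b) = 1 - d_H(a, b) / (|a| + |b|), where d_H is
  the Hamming distance between the connectivity matrices and |.| the edge
  count (rho = 1 for two empty networks);
* overall stability  rho_bar, the mean of rho over all unordered pairs;
* edge stability  e_ij, the fraction of ensemble members containing edge
  (i, j); edges with e_ij above a threshold (default 0.5, strict) form the
  stable consensus network.

Against a known ground truth, accuracy is scored over all I^2 directed
candidate entries (diagonal included) with precision, recall and F-measure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .topology import ConnectivityMatrix

__all__ = [
    "NetworkEnsemble",
    "StabilityReport",
    "AccuracyReport",
    "pairwise_stability",
    "overall_stability",
    "edge_stability",
    "stable_network",
    "accuracy",
]


@dataclass
class NetworkEnsemble:
    """Ordered collection of B networks over identical gene panels."""

    members: list[ConnectivityMatrix]
    provenance: list[dict] | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must contain at least one network")
        labels = self.members[0].gene_labels
        for m in self.members[1:]:
            if m.gene_labels != labels:
                raise ValueError("all ensemble members must share gene labels")
        if self.provenance is not None and len(self.provenance) != len(self.members):
            raise ValueError("provenance length must match number of members")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def gene_labels(self) -> list[str]:
        return self.members[0].gene_labels

    def stack(self) -> np.ndarray:
        """B x I x I array of the member adjacencies."""
        return np.stack([m.adjacency for m in self.members])


@dataclass
class StabilityReport:
    """Overall, pairwise and per-edge stability of an ensemble."""

    overall: float
    pairwise: np.ndarray  # B x B symmetric, unit diagonal
    edge_stability: np.ndarray  # I x I in [0, 1]
    gene_labels: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "overall_stability": self.overall,
            "n_networks": int(self.pairwise.shape[0]),
            "pairwise": self.pairwise.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def edge_stability_frame(self) -> pd.DataFrame:
        """Long-format per-edge stability: regulator, target, stability."""
        rows, cols = np.nonzero(self.edge_stability > 0)
        return pd.DataFrame(
            {
                "regulator": [self.gene_labels[i] for i in rows],
                "target": [self.gene_labels[j] for j in cols],
                "stability": self.edge_stability[rows, cols],
            }
        )


@dataclass(frozen=True)
class AccuracyReport:
    """Confusion counts and derived metrics over all directed entries."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2.0 * p * r / (p + r) if p + r else 0.0


def _check_same_shape(a: ConnectivityMatrix, b: ConnectivityMatrix) -> None:
    if a.adjacency.shape != b.adjacency.shape:
        raise ValueError(
            f"dimension mismatch: {a.adjacency.shape} vs {b.adjacency.shape}"
        )
    if a.gene_labels != b.gene_labels:
        raise ValueError("gene label order differs between networks")


def pairwise_stability(
    a: ConnectivityMatrix, b: ConnectivityMatrix, normalization: str = "edges"
) -> float:
    """Hamming-based similarity rho = 1 - d_H / (|a| + |b|), in [0, 1].

    d_H counts entries where the two binary matrices differ; the denominator
    is the total number of edges in the two networks.  Two empty networks
    are maximally stable (rho = 1).  ``normalization="entries"`` divides by
    the full I^2 entry count instead (strict Hamming similarity); with
    sparse networks this saturates near 1 and is kept only for comparison.
    """
    _check_same_shape(a, b)
    d_h = int((a.adjacency != b.adjacency).sum())
    if normalization == "entries":
        return 1.0 - d_h / a.adjacency.size
    if normalization != "edges":
        raise ValueError(f"unknown normalization {normalization!r}")
    total_edges = a.n_edges + b.n_edges
    if total_edges == 0:
        return 1.0
    # d_H <= |a| + |b| for binary matrices, so clamping is a formality
    return float(np.clip(1.0 - d_h / total_edges, 0.0, 1.0))


def overall_stability(
    ensemble: NetworkEnsemble, normalization: str = "edges"
) -> StabilityReport:
    """Mean pairwise stability over all B(B-1)/2 unordered pairs."""
    if ensemble.size < 2:
        raise ValueError("overall stability needs at least 2 networks")
    if normalization not in ("edges", "entries"):
        raise ValueError(f"unknown normalization {normalization!r}")
    stack = ensemble.stack().astype(np.int64)
    B = stack.shape[0]
    flat = stack.reshape(B, -1)
    edges = flat.sum(axis=1)
    # pairwise Hamming distances via |a| + |b| - 2 a.b  (binary matrices)
    inner = flat @ flat.T
    d_h = edges[:, None] + edges[None, :] - 2 * inner
    if normalization == "entries":
        denom = np.full_like(d_h, flat.shape[1])
    else:
        denom = edges[:, None] + edges[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = 1.0 - d_h / denom
    rho[denom == 0] = 1.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, 0.0, 1.0)
    upper = rho[np.triu_indices(B, k=1)]
    return StabilityReport(
        overall=float(upper.mean()),
        pairwise=rho,
        edge_stability=edge_stability(ensemble),
        gene_labels=ensemble.gene_labels,
    )


def edge_stability(ensemble: NetworkEnsemble) -> np.ndarray:
    """Occurrence frequency e_ij of each edge across the ensemble."""
    return ensemble.stack().mean(axis=0)


def stable_network(
    ensemble: NetworkEnsemble, threshold: float = 0.5
) -> ConnectivityMatrix:
    """Consensus network of edges with stability strictly above the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    freq = edge_stability(ensemble)
    return ConnectivityMatrix(
        (freq > threshold).astype(np.int8), list(ensemble.gene_labels)
    )


def accuracy(
    predicted: ConnectivityMatrix, truth: ConnectivityMatrix
) -> AccuracyReport:
    """Directed-edge confusion counts over all I^2 entries (diagonal included)."""
    _check_same_shape(predicted, truth)
    pred = predicted.adjacency.astype(bool)
    true = truth.adjacency.astype(bool)
    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    fn = int((~pred & true).sum())
    tn = int((~pred & ~true).sum())
    return AccuracyReport(tp=tp, fp=fp, fn=fn, tn=tn)
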