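"""Directed scale-free network topologies grown by preferential attachment.

Ground-truth regulatory structures are generated with a directed
Barabási–Albert process: nodes are added one at a time and each new node
attaches to an existing node *i* with probability proportional to
``d_i**gamma + b``, where ``d_i`` is the current in-degree of node *i*,
``gamma`` is the power of preferential attachment and ``b`` the
attractiveness of a node with no incoming edges.  The new node's edges point
from the new node to the chosen existing nodes, so hubs accumulate
*in*-degree and the generated graph is acyclic (every edge goes from a
later-added regulator to an earlier-added target).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "AttachmentParams",
    "generate_scale_free",
    "read_edge_list",
    "write_edge_list",
    "write_sif",
    "read_adjacency_csv",
    "write_adjacency_csv",
]


def default_gene_labels(n_genes: int) -> list[str]:
    """Zero-padded generic gene identifiers ``g001 .. gNNN``."""
    width = max(3, len(str(n_genes)))
    return [f"g{i + 1:0{width}d}" for i in range(n_genes)]


@dataclass
class ConnectivityMatrix:
    """Binary directed network structure over a fixed gene panel.

    ``adjacency[i, j] == 1`` means gene *i* (row, regulator) has a directed
    lag-1 regulatory edge onto gene *j* (column, target).  Self-edges are
    permitted as candidates for inferred networks but never produced by the
    generator.
    """

    adjacency: np.ndarray
    gene_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {adj.shape}")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be exactly 0 or 1")
        self.adjacency = adj.astype(np.int8)
        if self.gene_labels is None:
            self.gene_labels = default_gene_labels(adj.shape[0])
        else:
            self.gene_labels = list(self.gene_labels)
        if len(self.gene_labels) != adj.shape[0]:
            raise ValueError("gene_labels length must equal matrix dimension")
        if len(set(self.gene_labels)) != len(self.gene_labels):
            raise ValueError("gene_labels must be unique")

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def edge_list(self) -> list[tuple[str, str]]:
        """Directed edges as (regulator, target) label pairs, row-major order."""
        rows, cols = np.nonzero(self.adjacency)
        labels = self.gene_labels
        return [(labels[i], labels[j]) for i, j in zip(rows, cols)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConnectivityMatrix):
            return NotImplemented
        return (
            self.gene_labels == other.gene_labels
            and np.array_equal(self.adjacency, other.adjacency)
        )


@dataclass(frozen=True)
class AttachmentParams:
    """Parameters of the preferential-attachment probability d_i**gamma + b.

    gamma
        Power of preferential attachment (> 0).  The study default is 1.2.
    b
        Attractiveness of a node with no incoming edges (>= 0).  Any b > 0
        keeps zero-in-degree nodes reachable; the conventional choice is 1.
    edges_per_node
        Number of edges each newly added node brings (default 1, so an
        I-gene network has exactly I - 1 edges).
    """

    gamma: float = 1.2
    b: float = 1.0
    edges_per_node: int = 1

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.b < 0:
            raise ValueError(f"b must be >= 0, got {self.b}")
        if self.edges_per_node < 1:
            raise ValueError(f"edges_per_node must be >= 1, got {self.edges_per_node}")


def attachment_probabilities(
    in_degree: np.ndarray, params: AttachmentParams
) -> np.ndarray:
    """Normalized attachment probabilities p_i over the existing nodes.

    p_i is proportional to in_degree_i**gamma + b.  With b > 0 every node
    has strictly positive probability; as gamma -> 0 the probabilities over
    nodes with at least one incoming edge become uniform.
    """
    weights = np.asarray(in_degree, dtype=float) ** params.gamma + params.b
    if not (weights > 0).all():
        # only possible when b == 0 and some node has in-degree 0
        weights = np.where(weights > 0, weights, 0.0)
        if weights.sum() == 0:
            weights[:] = 1.0  # degenerate all-zero start: uniform
    return weights / weights.sum()


def generate_scale_free(
    n_genes: int,
    params: AttachmentParams | None = None,
    seed: int | np.random.Generator | None = None,
    gene_labels: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Grow a directed scale-free topology by preferential attachment.

    Starts from a single isolated node; each subsequent node attaches
    ``edges_per_node`` distinct existing nodes, chosen with probability
    proportional to ``in_degree**gamma + b``, and contributes one directed
    edge per attachment from itself to the chosen node.  No self-edges, no
    duplicate edges; with ``edges_per_node=1`` the result is a tree with
    exactly ``n_genes - 1`` edges.

    Parameters
    ----------
    n_genes
        Number of nodes (genes) in the final network, >= 1.
    params
        Attachment parameters; defaults to gamma=1.2, b=1, one edge per node.
    seed
        Integer seed or Generator; the same seed yields the same adjacency.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    params = params or AttachmentParams()
    m = params.edges_per_node
    if n_genes > 1 and m >= n_genes:
        raise ValueError(
            f"edges_per_node={m} requires at least {m} existing nodes "
            f"before any attachment; increase n_genes"
        )
    # growth starts with max(1, m) seed nodes so every new node can attach
    n_initial = max(1, m)
    rng = np.random.default_rng(seed)
    adjacency = np.zeros((n_genes, n_genes), dtype=np.int8)
    in_degree = np.zeros(n_genes, dtype=np.int64)

    for new in range(n_initial, n_genes):
        probs = attachment_probabilities(in_degree[:new], params)
        targets = rng.choice(new, size=m, replace=False, p=probs)
        for tgt in np.atleast_1d(targets):
            adjacency[new, tgt] = 1
            in_degree[tgt] += 1

    return ConnectivityMatrix(adjacency, list(gene_labels) if gene_labels else None)


def realized_degree_exponent(network: ConnectivityMatrix, d_min: int = 1) -> float:
    """Maximum-likelihood power-law exponent of the realized in-degree
    distribution (discrete Hill estimator over in-degrees >= d_min).

    This is the degree exponent of the grown graph, a different quantity
    from the attachment power gamma used to grow it.
    """
    deg = network.adjacency.sum(axis=0)
    deg = deg[deg >= d_min]
    if deg.size < 2:
        return float("nan")
    return 1.0 + deg.size / np.sum(np.log(deg / (d_min - 0.5)))


# ---------------------------------------------------------------------------
# file formats: 2-column TSV edge list, SIF, labelled adjacency CSV


def write_edge_list(network: ConnectivityMatrix, path: str | Path) -> None:
    """Write directed edges as 2-column TSV (regulator, target) with header."""
    df = pd.DataFrame(network.edge_list(), columns=["regulator", "target"])
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(
    path: str | Path, gene_labels: Sequence[str] | None = None
) -> ConnectivityMatrix:
    """Read a 2-column TSV edge list into a ConnectivityMatrix.

    The gene panel is the union of mentioned identifiers in first-seen order
    unless an explicit ordered panel is supplied.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("edge list must have at least 2 columns")
    regs, tgts = df.iloc[:, 0], df.iloc[:, 1]
    if gene_labels is None:
        gene_labels = list(dict.fromkeys(pd.concat([regs, tgts])))
    index = {g: k for k, g in enumerate(gene_labels)}
    adjacency = np.zeros((len(gene_labels), len(gene_labels)), dtype=np.int8)
    for r, t in zip(regs, tgts):
        adjacency[index[r], index[t]] = 1
    return ConnectivityMatrix(adjacency, list(gene_labels))


def write_sif(
    network: ConnectivityMatrix, path: str | Path, relation: str = "regulates"
) -> None:
    """Write the network in SIF dialect: regulator <TAB> relation <TAB> target."""
    with open(path, "w") as fh:
        for reg, tgt in network.edge_list():
            fh.write(f"{reg}\t{relation}\t{tgt}\n")


def write_adjacency_csv(network: ConnectivityMatrix, path: str | Path) -> None:
    """Write the binary adjacency as CSV with gene labels on rows and columns."""
    pd.DataFrame(
        network.adjacency, index=network.gene_labels, columns=network.gene_labels
    ).to_csv(path)


def read_adjacency_csv(path: str | Path) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("adjacency CSV must have identical row and column labels")
    return ConnectivityMatrix(df.to_numpy(), list(df.index))
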