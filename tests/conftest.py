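"""Shared fixtures: a small ground-truth network with simulated series."""

import numpy as np
import pytest

from grnstab import (
    build_design,
    generate_scale_free,
    sample_coefficients,
    simulate_timeseries,
)


@pytest.fixture(scope="session")
def ten_gene_truth():
    """A fixed 10-gene scale-free topology with sampled coefficients."""
    topo = generate_scale_free(10, seed=np.random.SeedSequence([11, 1, 10]))
    coeffs = sample_coefficients(topo, seed=np.random.SeedSequence([11, 2, 10]))
    return topo, coeffs


@pytest.fixture(scope="session")
def ten_gene_series(ten_gene_truth):
    """One noisy 50-time-point series simulated on the fixed truth."""
    _, coeffs = ten_gene_truth
    return simulate_timeseries(coeffs, 50, seed=np.random.SeedSequence([11, 3]))


@pytest.fixture(scope="session")
def ten_gene_design(ten_gene_series):
    return build_design(ten_gene_series)


@pytest.fixture(scope="session")
def ring_truth():
    """A persistent (cyclic) 10-gene truth for noise-free identifiability.

    The acyclic generated topologies are nilpotent, so their noise-free
    trajectories lose rank after the graph depth; a directed ring with
    |beta| = 0.9 keeps the design informative at zero innovation noise.
    """
    from grnstab import CoefficientMatrix, ConnectivityMatrix

    n = 10
    adj = np.zeros((n, n), dtype=int)
    beta = np.zeros((n, n))
    for i in range(n):
        adj[i, (i + 1) % n] = 1
        beta[i, (i + 1) % n] = 0.9 * (1 if i % 2 else -1)
    support = ConnectivityMatrix(adj)
    return support, CoefficientMatrix(beta, support)
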