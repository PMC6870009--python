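"""Graph-theoretic summaries of weighted NMI brain networks.

Three node-averaged measures are used downstream as classifier features:

* characteristic path length ``L`` — mean weighted shortest-path distance
  over ordered node pairs, with edge length 1/weight;
* average clustering coefficient ``C`` — computed on a binary graph
  obtained by proportional thresholding (keeping the strongest fraction of
  edges), since the triangle-count definition uses binary adjacency;
* global efficiency ``E_global`` — mean reciprocal shortest-path distance,
  with disconnected pairs contributing 0.

``L`` and ``E_global`` are computed on the full weighted graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "NetworkMetrics",
    "characteristic_path_length",
    "average_clustering",
    "global_efficiency",
    "binarize_proportional",
    "metrics_for_subject",
    "FEATURE_ORDER",
]

CONDITION_KEYS = ("S1", "S2", "S1-S2")
#: feature naming used in the 24-feature staging table
FEATURE_ORDER = (
    "S1_CLU", "S2_CLU", "S1_S2_CLU",
    "S1_CHA", "S2_CHA", "S1_S2_CHA",
    "S1_EFF", "S2_EFF", "S1_S2_EFF",
)


@dataclass
class NetworkMetrics:
    """L, C and E_global for one subject-condition network."""

    L: float
    C: float
    E_global: float
    condition: str = ""
    density: float = 0.2


def _as_weight_matrix(W) -> np.ndarray:
    values = np.asarray(getattr(W, "values", W), dtype=np.float64)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if (values < 0).any():
        raise ValueError("weights must be nonnegative")
    W = values.copy()
    np.fill_diagonal(W, 0.0)
    return W


def _shortest_lengths(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths with edge length 1/weight."""
    n = W.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / W, 0.0)
    graph = csr_matrix(lengths)
    dist = shortest_path(graph, method="D", directed=False)
    return dist


def characteristic_path_length(W) -> float:
    """Mean shortest-path length over ordered pairs of distinct nodes.

    Disconnected pairs are excluded from the mean (with a warning); a graph
    with no connected pair at all is an error.
    """
    W = _as_weight_matrix(W)
    dist = _shortest_lengths(W)
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    if not finite.any():
        raise ValueError("graph is fully disconnected; path length undefined")
    if finite.sum() < off.sum():
        warnings.warn(
            "graph is disconnected; unreachable pairs excluded from L", stacklevel=2
        )
    return float(dist[finite].mean())


def global_efficiency(W) -> float:
    """Mean reciprocal shortest-path length; disconnected pairs count 0."""
    W = _as_weight_matrix(W)
    n = W.shape[0]
    if n < 2:
        return 0.0
    dist = _shortest_lengths(W)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def binarize_proportional(W, density: float) -> np.ndarray:
    """Keep the strongest ``density * C(n,2)`` edges; return 0/1 adjacency.

    Ties at the threshold break by stable (row-major upper-triangle) edge
    index order.  Zero-weight entries never become edges.
    """
    W = _as_weight_matrix(W)
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    weights = W[iu, ju]
    k = int(round(density * weights.size))
    order = np.argsort(-weights, kind="stable")
    keep = order[:k]
    keep = keep[weights[keep] > 0]
    A = np.zeros_like(W)
    A[iu[keep], ju[keep]] = 1.0
    A[ju[keep], iu[keep]] = 1.0
    return A


def average_clustering(W, density: float = 0.2) -> float:
    """Mean node clustering coefficient on the proportionally thresholded graph.

    ``C_i = E_i / (k_i (k_i - 1))`` with ``E_i`` the ordered-pair triangle
    count around node ``i``; nodes with degree < 2 contribute 0.
    """
    A = binarize_proportional(W, density)
    k = A.sum(axis=1)
    # E_i counts ordered neighbour pairs (j, h) that are themselves linked:
    # diag(A^3)[i] = sum_{j,h} a_ij a_jh a_hi
    triangles = np.einsum("ij,jh,hi->i", A, A, A)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_i = np.where(denom > 0, triangles / denom, 0.0)
    return float(c_i.mean())


def network_metrics(W, density: float = 0.2, condition: str = "") -> NetworkMetrics:
    return NetworkMetrics(
        L=characteristic_path_length(W),
        C=average_clustering(W, density),
        E_global=global_efficiency(W),
        condition=condition,
        density=density,
    )


def metrics_for_subject(matrices: dict, density: float = 0.2) -> dict[str, float]:
    """Nine scalar network features (CLU/CHA/EFF x S1/S2/S1-S2) per subject.

    ``matrices`` maps condition name ("S1", "S2", "S1-S2") to a weight
    matrix or :class:`~gatenet.connectivity.ConnectivityMatrix`.
    """
    missing = [c for c in CONDITION_KEYS if c not in matrices]
    if missing:
        raise ValueError(f"missing condition matrices: {missing}")
    out: dict[str, float] = {}
    for cond, tag in zip(CONDITION_KEYS, ("S1", "S2", "S1_S2")):
        m = network_metrics(matrices[cond], density=density, condition=cond)
        out[f"{tag}_CLU"] = m.C
        out[f"{tag}_CHA"] = m.L
        out[f"{tag}_EFF"] = m.E_global
    return {name: out[name] for name in FEATURE_ORDER}
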