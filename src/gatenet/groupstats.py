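"""Group comparisons: edge-wise permutation tests and rank statistics.

Edge-wise comparison of two groups of NMI networks uses the difference of
group means per edge as the statistic, with a null built by shuffling group
labels over the pooled subjects.  The two-sided permutation p-value is

    p = (1 + #{ |null| >= |observed| }) / (1 + n_perm),

reported per edge at a fixed level (no cross-edge correction, matching the
per-edge p < 0.05 reporting convention).  Scalar measures are compared with
the Kruskal-Wallis test and Bonferroni-adjusted pairwise rank tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EdgeTestResult",
    "edge_permutation_test",
    "degree_summary",
    "kruskal_wallis",
    "bonferroni_posthoc",
]


@dataclass
class EdgeTestResult:
    """Edge-wise permutation comparison of two groups of networks."""

    group_pair: tuple[str, str]
    edges: np.ndarray          # n_edges x 2 node indices (upper triangle)
    p_values: np.ndarray
    observed_diff: np.ndarray  # mean(A) - mean(B) per edge
    alpha: float
    n_perm: int
    seed: int | None
    exact: bool = False
    significant_edges: list[tuple[int, int, int]] = field(default_factory=list)
    # each entry: (node_i, node_j, sign) with sign +1 higher in A, -1 lower

    @property
    def n_significant(self) -> int:
        return len(self.significant_edges)


def _stack_edge_vectors(nets) -> tuple[np.ndarray, np.ndarray]:
    """Subjects x edges matrix of upper-triangle entries, plus edge index."""
    mats = [np.asarray(getattr(m, "values", m), dtype=np.float64) for m in nets]
    n = mats[0].shape[0]
    if any(m.shape != (n, n) for m in mats):
        raise ValueError("all matrices must share one atlas / node count")
    iu, ju = np.triu_indices(n, k=1)
    X = np.stack([m[iu, ju] for m in mats])
    return X, np.column_stack([iu, ju])


def edge_permutation_test(
    nets_a,
    nets_b,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
    group_pair: tuple[str, str] = ("A", "B"),
    exact_limit: int = 20000,
) -> EdgeTestResult:
    """Permutation test of mean NMI difference at every edge.

    Uses exact enumeration of all label assignments when their number is at
    most ``exact_limit``; otherwise ``n_perm`` random label shuffles.
    """
    Xa, edges = _stack_edge_vectors(nets_a)
    Xb, _ = _stack_edge_vectors(nets_b)
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError("groups use different atlases")
    na, nb = Xa.shape[0], Xb.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 subjects per group")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values", stacklevel=2)

    pooled = np.vstack([Xa, Xb])
    n_tot = na + nb
    obs = Xa.mean(axis=0) - Xb.mean(axis=0)

    n_exact = comb(n_tot, na)
    exact = n_exact <= exact_limit
    if exact:
        assignments = np.array(list(combinations(range(n_tot), na)))
        n_null = assignments.shape[0]
        sel = np.zeros((n_null, n_tot), dtype=np.float64)
        rows = np.repeat(np.arange(n_null), na)
        sel[rows, assignments.ravel()] = 1.0
        n_used = n_null
    else:
        rng = np.random.default_rng(seed)
        sel = np.zeros((n_perm, n_tot), dtype=np.float64)
        for r in range(n_perm):
            sel[r, rng.permutation(n_tot)[:na]] = 1.0
        n_used = n_perm

    # null statistic = mean over permuted group A - mean over complement
    sums = sel @ pooled
    total = pooled.sum(axis=0)
    null = sums / na - (total[None, :] - sums) / nb

    exceed = (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)
    if exact:
        p = exceed / n_used  # the identity assignment is among them
    else:
        p = (1.0 + exceed) / (1.0 + n_used)

    sig_mask = p < alpha
    significant = [
        (int(edges[e, 0]), int(edges[e, 1]), int(np.sign(obs[e])) or 1)
        for e in np.flatnonzero(sig_mask)
    ]
    return EdgeTestResult(
        group_pair=group_pair,
        edges=edges,
        p_values=p,
        observed_diff=obs,
        alpha=alpha,
        n_perm=n_used,
        seed=seed,
        exact=exact,
        significant_edges=significant,
    )


def degree_summary(result: EdgeTestResult, atlas: pd.DataFrame) -> pd.DataFrame:
    """Degrees of nodes incident to significant edges, sorted descending.

    Ties keep atlas order.  The degree column sums to twice the number of
    significant edges.
    """
    n_nodes = len(atlas)
    degree = np.zeros(n_nodes, dtype=int)
    for i, j, _sign in result.significant_edges:
        degree[i] += 1
        degree[j] += 1
    rows = np.flatnonzero(degree > 0)
    table = pd.DataFrame(
        {
            "region": atlas["name"].to_numpy()[rows],
            "hemisphere": atlas["hemisphere"].to_numpy()[rows],
            "degree": degree[rows],
        }
    )
    return table.sort_values("degree", ascending=False, kind="stable").reset_index(
        drop=True
    )


def kruskal_wallis(groups: list) -> tuple[float, float, int]:
    """Kruskal-Wallis H (tie-corrected), p-value and degrees of freedom."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    if sum(g.size for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0, df
    h, p = stats.kruskal(*groups)
    return float(h), float(p), df


def bonferroni_posthoc(groups: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise two-sided rank (Mann-Whitney) tests, Bonferroni adjusted.

    ``groups`` maps group name to a value sequence.  Adjusted p-values are
    ``min(1, n_pairs * raw)``.
    """
    names = list(groups)
    if len(names) < 3:
        raise ValueError("post hoc comparison expects >= 3 groups")
    pairs = list(combinations(names, 2))
    rows = []
    for a, b in pairs:
        xa = np.asarray(groups[a], dtype=np.float64)
        xb = np.asarray(groups[b], dtype=np.float64)
        if np.ptp(np.concatenate([xa, xb])) == 0:
            raw = 1.0
        else:
            raw = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        adj = min(1.0, len(pairs) * raw)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "p_raw": raw,
                "p_adjusted": adj,
                "significant": adj < alpha,
            }
        )
    return pd.DataFrame(rows)
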