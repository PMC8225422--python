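"""Community detection per fixed-topology window and co-membership tracking.

Communities are found on each window's 0/1 coupling matrix by greedy
agglomerative modularity optimization (CNM style): repeatedly merge the
pair of communities with the largest modularity gain until no merge is
positive.  Merges are only ever proposed between communities joined by at
least one edge, so disconnected components are never merged, and ties are
broken by the lexicographically smallest community-index pair, making the
result deterministic.  Community structure depends only on the topology,
never on the membrane dynamics.

Across windows, the co-membership probability P_ij is the fraction of
windows in which i and j share a community; pairs with P_ij at or above
the threshold (default 70%) define the stable communities, taken as
connected components of the thresholded P-graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .sync import SyncSeries, subset_sync_series

__all__ = [
    "Partition",
    "CoMembership",
    "modularity",
    "detect_communities",
    "window_partitions",
    "community_count_series",
    "co_membership",
    "community_sync_report",
]

_DQ_TOL = 1e-12


@dataclass
class Partition:
    """Community labels for one fixed-topology window."""

    labels: np.ndarray
    q: float
    t_start: float = float("nan")
    t_end: float = float("nan")

    @property
    def n_communities(self) -> int:
        return int(np.unique(self.labels).size)

    def sizes(self) -> tuple[int, ...]:
        return tuple(sorted(np.bincount(self.labels).tolist(), reverse=True))


@dataclass
class CoMembership:
    """Pairwise co-membership probabilities and the stable groups."""

    p: np.ndarray
    threshold: float = 0.70
    stable_groups: list[np.ndarray] = field(default_factory=list)


def _validate_adjacency(adjacency) -> np.ndarray:
    adj = np.asarray(adjacency)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    return adj.astype(bool)


def modularity(adjacency, labels) -> float:
    """Newman modularity Q = sum_c [l_c/m - (d_c/2m)^2] of a partition."""
    adj = _validate_adjacency(adjacency)
    labels = np.asarray(labels, dtype=int)
    m = adj.sum() / 2
    if m == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    deg = adj.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        l_c = adj[np.ix_(idx, idx)].sum() / 2
        d_c = deg[idx].sum()
        q += l_c / m - (d_c / (2 * m)) ** 2
    return float(q)


def detect_communities(adjacency, seed: int = 0, window=(float("nan"), float("nan"))) -> Partition:
    """Greedy modularity-optimizing partition of a 0/1 graph.

    Deterministic: the ``seed`` is accepted for interface uniformity but the
    algorithm itself has no randomness -- equal modularity gains are broken
    by the lowest community-index pair.  An edgeless graph yields all
    singletons (with Q reported as 0, the convention for the undefined
    case).
    """
    adj = _validate_adjacency(adjacency)
    n = adj.shape[0]
    m = int(adj.sum()) // 2
    if m == 0:
        return Partition(labels=np.arange(n), q=0.0, t_start=window[0], t_end=window[1])

    # community state: node sets, inter-community edge counts, degree sums
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    deg = adj.sum(axis=1).astype(float)
    a = {i: float(deg[i]) for i in range(n)}
    links: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    rows, cols = np.nonzero(np.triu(adj, 1))
    for i, j in zip(rows.tolist(), cols.tolist()):
        links[i][j] = 1.0
        links[j][i] = 1.0

    while True:
        best = None  # (dq, i, j)
        for i in sorted(links):
            for j in sorted(links[i]):
                if j <= i:
                    continue
                dq = links[i][j] / m - a[i] * a[j] / (2.0 * m * m)
                if best is None or dq > best[0] + _DQ_TOL:
                    best = (dq, i, j)
        if best is None or best[0] <= _DQ_TOL:
            break
        _, i, j = best
        members[i].extend(members.pop(j))
        a[i] += a.pop(j)
        for k, w in links.pop(j).items():
            if k == i:
                continue
            links[k].pop(j, None)
            links[k][i] = links[k].get(i, 0.0) + w
            links[i][k] = links[i].get(k, 0.0) + w
        links[i].pop(j, None)

    labels = np.empty(n, dtype=int)
    for new_id, cid in enumerate(sorted(members, key=lambda c: min(members[c]))):
        labels[members[cid]] = new_id
    return Partition(labels=labels, q=modularity(adj, labels), t_start=window[0], t_end=window[1])


def window_partitions(trace, seed: int = 0) -> list[Partition]:
    """Community partition of every topology snapshot of a run."""
    return [
        detect_communities(s.coupling, seed=seed, window=(s.t_start, s.t_end))
        for s in trace.snapshots
    ]


def community_count_series(trace, seed: int = 0) -> pd.DataFrame:
    """Per-window community count and size multiset."""
    parts = trace if isinstance(trace, list) else window_partitions(trace, seed=seed)
    return pd.DataFrame(
        {
            "t_start": [p.t_start for p in parts],
            "t_end": [p.t_end for p in parts],
            "n_communities": [p.n_communities for p in parts],
            "sizes": [p.sizes() for p in parts],
        }
    )


def co_membership(partitions: list[Partition], threshold: float = 0.70) -> CoMembership:
    """Fraction of windows sharing a label, and the >= threshold stable groups."""
    if not partitions:
        raise ValueError("need at least one partition")
    n = partitions[0].labels.size
    p = np.zeros((n, n))
    for part in partitions:
        p += part.labels[:, None] == part.labels[None, :]
    p /= len(partitions)
    above = csr_matrix(p >= threshold)
    n_comp, comp = connected_components(above, directed=False)
    groups = [np.flatnonzero(comp == c) for c in range(n_comp)]
    groups.sort(key=lambda g: (-g.size, g[0]))
    return CoMembership(p=p, threshold=threshold, stable_groups=groups)


def community_sync_report(trace, groups) -> list[SyncSeries]:
    """Synchronization series of each stable group (empty groups skipped)."""
    out = []
    for g in groups:
        g = np.asarray(g, dtype=int)
        if g.size == 0:
            warnings.warn("skipping empty community group", stacklevel=2)
            continue
        out.append(subset_sync_series(trace, g))
    return out
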