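"""Average-linkage hierarchical clustering of frames with a distance-cutoff stop.

The cluster count at a fixed RMSD cutoff (1.2 Å by convention) is the
ensemble-flexibility metric: a flexible loop scatters its frames over many
clusters, a rigid one collapses onto few.  Linkage is unweighted average
(UPGMA — the arithmetic mean over all cross-pairs of the raw distance matrix),
and agglomeration stops *before* the first merge whose linkage distance would
exceed the cutoff, so every pair of final clusters has average inter-cluster
distance strictly greater than the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flexibility import RmsdMatrix


@dataclass(frozen=True)
class ClusterResult:
    """A flat partition of frames with representatives and the cutoff used.

    Labels are 0-based, ordered by decreasing cluster size (ties broken by the
    lowest member frame index).
    """

    labels: np.ndarray
    n_clusters: int
    representatives: tuple[int, ...]
    cutoff: float
    linkage: str = "average"

    def __post_init__(self) -> None:
        if self.n_clusters != len(np.unique(self.labels)):
            raise ValueError("n_clusters inconsistent with labels")
        for c, rep in enumerate(self.representatives):
            if self.labels[rep] != c:
                raise ValueError(f"representative {rep} is not a member of cluster {c}")

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def _canonical_labels(groups: list[list[int]], n: int) -> tuple[np.ndarray, int]:
    """Relabel groups by decreasing size, ties by lowest member frame."""
    order = sorted(range(len(groups)), key=lambda g: (-len(groups[g]), min(groups[g])))
    labels = np.empty(n, dtype=int)
    for new_id, g in enumerate(order):
        for f in groups[g]:
            labels[f] = new_id
    return labels, len(groups)


def average_linkage_cluster(matrix: RmsdMatrix | np.ndarray, cutoff: float) -> ClusterResult:
    """UPGMA agglomeration of frames, stopped at the distance cutoff.

    Starting from singletons, repeatedly merge the pair of clusters with the
    smallest average pairwise inter-cluster distance; stop when that smallest
    average exceeds ``cutoff``.  Merge ties are broken by the lexicographically
    lowest cluster-index pair, making the procedure fully deterministic.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    D = matrix.values if isinstance(matrix, RmsdMatrix) else np.asarray(matrix, dtype=float)
    F = D.shape[0]
    if F == 1:
        return ClusterResult(
            labels=np.zeros(1, dtype=int), n_clusters=1,
            representatives=(0,), cutoff=cutoff,
        )

    # Lance-Williams UPGMA: d(k, i∪j) = (n_i d(k,i) + n_j d(k,j)) / (n_i + n_j)
    # keeps every entry equal to the exact cross-pair mean of the raw matrix.
    dist = D.astype(float).copy()
    np.fill_diagonal(dist, np.inf)
    sizes = np.ones(F, dtype=int)
    members: list[list[int] | None] = [[i] for i in range(F)]
    active = np.ones(F, dtype=bool)

    while active.sum() > 1:
        sub = np.where(active)[0]
        block = dist[np.ix_(sub, sub)]
        flat = np.argmin(block)
        bi, bj = divmod(flat, block.shape[1])
        # argmin on ties returns the first in row-major order = lowest (i, j)
        i, j = sub[bi], sub[bj]
        if i > j:
            i, j = j, i
        if dist[i, j] > cutoff:
            break
        ni, nj = sizes[i], sizes[j]
        new_row = (ni * dist[i] + nj * dist[j]) / (ni + nj)
        dist[i, :] = new_row
        dist[:, i] = new_row
        dist[i, i] = np.inf
        dist[j, :] = np.inf
        dist[:, j] = np.inf
        sizes[i] = ni + nj
        members[i] = members[i] + members[j]  # type: ignore[operator]
        members[j] = None
        active[j] = False

    groups = [m for m in members if m is not None]
    labels, n_clusters = _canonical_labels(groups, F)
    reps = _representatives_from_labels(D, labels, n_clusters)
    return ClusterResult(
        labels=labels, n_clusters=n_clusters, representatives=reps, cutoff=cutoff,
    )


def representatives(matrix: RmsdMatrix | np.ndarray, result: ClusterResult) -> tuple[int, ...]:
    """Per-cluster representative: the member with minimal average distance to
    the other members (ties → lowest frame index; singletons → themselves)."""
    D = matrix.values if isinstance(matrix, RmsdMatrix) else np.asarray(matrix, dtype=float)
    return _representatives_from_labels(D, result.labels, result.n_clusters)


def _representatives_from_labels(D: np.ndarray, labels: np.ndarray, n_clusters: int) -> tuple[int, ...]:
    reps = []
    for c in range(n_clusters):
        mem = np.flatnonzero(labels == c)
        if len(mem) == 1:
            reps.append(int(mem[0]))
            continue
        sub = D[np.ix_(mem, mem)]
        avg = sub.sum(axis=1) / (len(mem) - 1)
        reps.append(int(mem[int(np.argmin(avg))]))  # argmin takes first on ties
    return tuple(reps)


def cluster_count_sweep(
    matrix: RmsdMatrix | np.ndarray, cutoffs: list[float] | np.ndarray
) -> pd.DataFrame:
    """Cluster counts over a grid of cutoffs — the rigidification-robustness curve."""
    cutoffs = list(cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly increasing")
    rows = [
        {"cutoff": c, "n_clusters": average_linkage_cluster(matrix, c).n_clusters}
        for c in cutoffs
    ]
    return pd.DataFrame(rows)
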