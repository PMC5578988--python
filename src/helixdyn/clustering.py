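"""GROMOS conformational clustering on a pairwise-RMSD matrix.

The greedy neighbour-count scheme: the frame with the most neighbours within
the cutoff becomes a cluster centre, it and its neighbours are removed, and
the procedure repeats until every frame is assigned.  The centre of the first
(largest) cluster is the trajectory's most representative structure (the
centroid).  Ties on neighbour count break to the lowest frame index, and the
neighbour criterion is inclusive (≤ cutoff), so the partition is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory
from .geometry import kabsch_superpose

__all__ = ["ClusterResult", "Cluster", "pairwise_rmsd_matrix", "gromos_cluster"]

MAX_FRAMES_DENSE = 12000  # guard: dense O(n^2) matrix memory


@dataclass(frozen=True)
class Cluster:
    center: int                  # frame index of the cluster centre
    members: tuple[int, ...]     # includes the centre


@dataclass
class ClusterResult:
    clusters: list[Cluster]      # ordered by decreasing size
    cutoff: float

    @property
    def centroid(self) -> int:
        """Frame index of the most representative structure."""
        return self.clusters[0].center

    @property
    def labels(self) -> dict[int, int]:
        return {m: ci for ci, cl in enumerate(self.clusters) for m in cl.members}


def pairwise_rmsd_matrix(
    traj: Trajectory, selection: np.ndarray | None = None
) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs over the analyzed frames.

    Entry (i, j) is the RMSD after optimal superposition of analyzed frame j
    onto analyzed frame i over the selection (default: CA atoms).
    """
    if traj.n_analyzed < 2:
        raise ValueError("need at least 2 analyzed frames")
    if traj.n_analyzed > MAX_FRAMES_DENSE:
        raise ValueError(
            f"{traj.n_analyzed} frames exceeds the dense-matrix guard "
            f"({MAX_FRAMES_DENSE}); subsample the trajectory"
        )
    if selection is None:
        selection = np.asarray(
            [i for i, a in enumerate(traj.atoms) if a.name == "CA"], int)
    selection = np.asarray(selection, int)
    if selection.size == 0:
        raise ValueError("empty selection")
    idx = traj.analyzed_indices
    pts = traj.coords[idx][:, selection, :]
    m = pts.shape[0]
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = kabsch_superpose(pts[j], pts[i])[2]
    return out


def gromos_cluster(matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Greedy neighbour-count clustering of a pairwise-distance matrix."""
    matrix = np.asarray(matrix, float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-6):
        raise ValueError("matrix must be symmetric")
    if np.any(matrix < 0):
        raise ValueError("matrix entries must be non-negative")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = matrix.shape[0]
    neighbours = matrix <= cutoff
    np.fill_diagonal(neighbours, True)
    remaining = np.ones(n, bool)
    clusters: list[Cluster] = []
    while remaining.any():
        counts = (neighbours & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(neighbours[center] & remaining)[0]
        clusters.append(Cluster(center=center, members=tuple(int(m) for m in members)))
        remaining[members] = False
    clusters.sort(key=lambda c: (-len(c.members), c.center))
    return ClusterResult(clusters=clusters, cutoff=float(cutoff))
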