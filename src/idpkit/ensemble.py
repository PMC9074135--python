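"""Pairwise-RMSD DBSCAN clustering and Ramachandran-region analysis.

Clustering follows the classic density-based algorithm on a precomputed
pairwise best-fit backbone-RMSD matrix: a frame is a core point when at
least ``min_points`` frames (itself included) lie within ``eps`` Å of it;
clusters grow by density reachability, border frames join the first cluster
that reaches them in scan order, and everything else is noise (label −1).
The defaults (ε = 0.8 Å backbone RMSD, MinPoints = 5) match the clustering
protocol used for the room-temperature ensembles this package analyses.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .structure_io import Trajectory
from .geometry import kabsch_superpose, _resolve_selection

__all__ = [
    "pairwise_rmsd",
    "dbscan",
    "cluster_representative",
    "ClusterResult",
    "ramachandran",
    "RamaHistogram",
    "RAMA_CENTRES",
    "NOISE",
]

NOISE = -1


def pairwise_rmsd(traj: Trajectory, selection="backbone") -> np.ndarray:
    """Condensed pairwise best-fit RMSD matrix over frames (Å).

    Every frame pair is superposed independently (Kabsch) on the selection
    before the deviation is measured; the result is a condensed
    upper-triangle vector compatible with ``scipy.spatial.distance``.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    idx = _resolve_selection(traj.topology, selection)
    X = traj.coords()[:, idx]
    n = X.shape[0]
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            out[k] = kabsch_superpose(X[j], X[i]).rmsd
            k += 1
    return out


@dataclass
class ClusterResult:
    labels: np.ndarray              # per-frame cluster id, NOISE = −1
    populations: dict               # cluster id → member count
    fractions: dict                 # cluster id → population / n_frames
    medoids: dict                   # cluster id → frame index

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    @property
    def n_noise(self) -> int:
        return int((self.labels == NOISE).sum())


def _square(matrix: np.ndarray) -> np.ndarray:
    M = np.asarray(matrix, dtype=float)
    if M.ndim == 1:
        M = squareform(M)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("need a square or condensed distance matrix")
    return M


def dbscan(matrix: np.ndarray, eps: float = 0.8, min_points: int = 5) -> ClusterResult:
    """Density-based clustering of a distance matrix (square or condensed)."""
    D = _square(matrix)
    n = D.shape[0]
    neighbours = [np.flatnonzero(D[i] <= eps) for i in range(n)]  # includes self
    core = np.array([len(nb) >= min_points for nb in neighbours])
    labels = np.full(n, NOISE, dtype=int)
    cid = 0
    for i in range(n):
        if labels[i] != NOISE or not core[i]:
            continue
        labels[i] = cid
        queue = deque(neighbours[i])
        while queue:
            j = queue.popleft()
            if labels[j] == NOISE:
                labels[j] = cid
                if core[j]:
                    queue.extend(k for k in neighbours[j] if labels[k] == NOISE)
        cid += 1
    populations = {c: int((labels == c).sum()) for c in range(cid)}
    fractions = {c: populations[c] / n for c in populations}
    result = ClusterResult(labels=labels, populations=populations,
                           fractions=fractions, medoids={})
    result.medoids = cluster_representative(result, D)
    return result


def cluster_representative(result: ClusterResult, matrix: np.ndarray) -> dict:
    """Medoid frame of each cluster: member minimizing summed intra-cluster
    distance; ties broken by the lowest frame index."""
    D = _square(matrix)
    medoids = {}
    for c in result.populations:
        members = np.flatnonzero(result.labels == c)
        sums = D[np.ix_(members, members)].sum(axis=1)
        medoids[c] = int(members[np.argmin(sums)])   # argmin takes first on ties
    return medoids


# ---------------------------------------------------------------------------
# Ramachandran analysis

# Named basin centres (φ, ψ) in degrees.  γ′ sits in the bridge region.
RAMA_CENTRES = {
    "alphaR": (-60.0, -40.0),
    "ppii": (-75.0, 150.0),
    "beta": (-150.0, 160.0),
    "gamma_prime": (-80.0, 80.0),
    "alphaL": (60.0, 40.0),
}
_RAMA_RADIUS = 30.0     # Chebyshev radius for region membership, deg


@dataclass
class RamaHistogram:
    counts: np.ndarray          # (n_bins, n_bins), φ rows, ψ columns
    phi_edges: np.ndarray
    psi_edges: np.ndarray
    region_fractions: dict      # named region → fraction of pairs
    n_pairs: int


def _wrap_diff(a: np.ndarray, b: float) -> np.ndarray:
    d = np.abs(a - b) % 360.0
    return np.minimum(d, 360.0 - d)


def ramachandran(dihedral_table: pd.DataFrame, bin_width: float = 5.0) -> RamaHistogram:
    """Histogram a φ/ψ table and assign named conformational regions.

    Regions are assigned by the nearest named centre within a 30° Chebyshev
    radius (angular wrap-around respected): right-handed α (−60, −40),
    polyproline II (−75, 150), β (−150, 160), γ′ (−80, 80), left-handed α
    (+60, +40); pairs outside every basin count as ``other``.
    """
    tab = dihedral_table.dropna(subset=["phi", "psi"])
    if tab.empty:
        raise ValueError("no complete phi/psi pairs")
    phi = tab["phi"].to_numpy()
    psi = tab["psi"].to_numpy()
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    counts, pe, se = np.histogram2d(phi, psi, bins=(edges, edges))
    n = len(phi)
    fractions = {}
    assigned = np.zeros(n, dtype=bool)
    cheb = {}
    for name, (pc, sc) in RAMA_CENTRES.items():
        cheb[name] = np.maximum(_wrap_diff(phi, pc), _wrap_diff(psi, sc))
    names = list(RAMA_CENTRES)
    stack = np.stack([cheb[nm] for nm in names])
    nearest = np.argmin(stack, axis=0)
    within = stack.min(axis=0) <= _RAMA_RADIUS
    for i, nm in enumerate(names):
        fractions[nm] = float(((nearest == i) & within).mean())
    fractions["other"] = float((~within).mean())
    return RamaHistogram(counts=counts, phi_edges=pe, psi_edges=se,
                         region_fractions=fractions, n_pairs=n)
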