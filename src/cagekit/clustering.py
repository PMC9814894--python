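"""Conformational clustering of trajectory frames by best-fit RMSD.

Frames are compared through least-squares-superposed (Kabsch) RMSD over
a configurable atom selection -- by convention all carbon atoms of the
host or complex, resolved by element symbol -- and agglomerated with
average linkage.  Merging stops when the smallest average inter-cluster
RMSD exceeds epsilon (default 1.0 Angstrom); because average linkage is
monotone this is equivalent to cutting the dendrogram at that height,
and the agglomeration itself is delegated to scipy's hierarchical
clustering.  Clusters are reported by descending population with the
largest cluster as id 0; the representative of a cluster is its member
frame with the smallest total RMSD to co-members, and the average
conformation is the coordinate mean after superposing every member onto
the representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import Trajectory
from .geometry import kabsch_rotation


@dataclass
class ClusterParams:
    """Average-linkage parameters: stop threshold and atom selection."""

    linkage: str = "average"
    epsilon: float = 1.0
    selection: np.ndarray | None = None  # default: all carbons

    def __post_init__(self) -> None:
        if self.linkage != "average":
            raise ValueError(f"unsupported linkage {self.linkage!r}: only "
                             "'average' is implemented")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def pairwise_rmsd(traj: Trajectory, selection=None,
                  block: int = 64) -> np.ndarray:
    """Symmetric (F, F) matrix of pairwise best-fit RMSD, Angstrom.

    Vectorized Kabsch: per pair only the 3x3 cross-covariance is needed,
    so covariances are built in blocks and their singular values batched.
    """
    sel = (traj.select_element("C") if selection is None
           else np.asarray(selection, int))
    if len(sel) == 0:
        raise ValueError("empty selection")
    x = traj.coords[:, sel, :].astype(float)
    x = x - x.mean(axis=1, keepdims=True)
    f, n, _ = x.shape
    g = np.einsum("fnd,fnd->f", x, x)  # squared norms
    out = np.zeros((f, f))
    for i0 in range(0, f, block):
        i1 = min(i0 + block, f)
        # H[a, b] = x[a]^T x[b] for a in block, all b
        h = np.einsum("and,bne->abde", x[i0:i1], x)
        s = np.linalg.svd(h, compute_uv=False)
        det = np.linalg.det(h)
        s[..., -1] = np.where(det < 0, -s[..., -1], s[..., -1])
        msd = (g[i0:i1, None] + g[None, :] - 2.0 * s.sum(axis=-1)) / n
        out[i0:i1] = np.sqrt(np.clip(msd, 0.0, None))
    np.fill_diagonal(out, 0.0)
    return 0.5 * (out + out.T)  # enforce exact symmetry


@dataclass
class ClusterResult:
    """Assignment, populations (descending) and per-cluster structures."""

    assignment: np.ndarray  # frame -> cluster id, largest cluster id 0
    populations: np.ndarray  # fraction per cluster, descending
    representatives: list[int]  # member frame index per cluster
    average_coords: list[np.ndarray]  # (N, 3) mean structure per cluster
    epsilon: float = 1.0

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def cluster(traj: Trajectory, params: ClusterParams | None = None,
            distances: np.ndarray | None = None) -> ClusterResult:
    """Average-linkage clustering of trajectory frames with an epsilon stop.

    A precomputed RMSD matrix can be passed to avoid recomputation.
    Cluster ids are assigned by descending population (ties broken by the
    smallest member frame index), so the largest cluster is always id 0.
    """
    params = params or ClusterParams()
    f = traj.n_frames
    if f < 1:
        raise ValueError("need at least one frame")
    if distances is None:
        distances = pairwise_rmsd(traj, params.selection)
    if f == 1:
        raw = np.zeros(1, dtype=int)
    else:
        z = linkage(squareform(distances, checks=False), method="average")
        raw = fcluster(z, t=params.epsilon, criterion="distance") - 1

    # relabel by descending population, ties by first-occurring frame
    ids, counts = np.unique(raw, return_counts=True)
    first_frame = {i: int(np.flatnonzero(raw == i)[0]) for i in ids}
    order = sorted(ids, key=lambda i: (-counts[list(ids).index(i)],
                                       first_frame[i]))
    relabel = {old: new for new, old in enumerate(order)}
    assignment = np.array([relabel[i] for i in raw], dtype=int)

    populations = np.array([np.sum(assignment == c) / f
                            for c in range(len(ids))])

    sel = (traj.select_element("C") if params.selection is None
           else np.asarray(params.selection, int))
    representatives: list[int] = []
    averages: list[np.ndarray] = []
    for c in range(len(ids)):
        members = np.flatnonzero(assignment == c)
        sub = distances[np.ix_(members, members)]
        rep = int(members[np.argmin(sub.sum(axis=1))])
        representatives.append(rep)
        ref = traj.coords[rep][sel]
        acc = np.zeros_like(traj.coords[rep])
        for m in members:
            # rigid motion fitted on the selection, applied to all atoms
            r, t_ref, t_mob = kabsch_rotation(ref, traj.coords[m][sel])
            acc += (traj.coords[m] - t_mob) @ r.T + t_ref
        averages.append(acc / len(members))

    return ClusterResult(assignment=assignment, populations=populations,
                         representatives=representatives,
                         average_coords=averages, epsilon=params.epsilon)


def preprocess(traj: Trajectory, center_selection=None,
               image: bool = False) -> Trajectory:
    """Center frames at the origin and optionally wrap molecules.

    Centering subtracts the mass-weighted centroid of ``center_selection``
    (default: all atoms) per frame.  Imaging requires per-frame box
    metadata and translates each molecule (grouped by residue id) by
    whole box lengths so its centroid lands in the primary cell centered
    at the origin.
    """
    if image and traj.box is None:
        raise ValueError("imaging requested but the trajectory has no box")
    sel = (np.arange(traj.n_atoms) if center_selection is None
           else np.asarray(center_selection, int))
    masses = traj.masses
    w = masses[sel] / masses[sel].sum()
    coords = traj.coords.copy()
    centroid = np.einsum("s,fsd->fd", w, coords[:, sel, :])
    coords -= centroid[:, None, :]

    if image:
        resids = traj.resids
        for rid in np.unique(resids):
            atoms = np.flatnonzero(resids == rid)
            mw = masses[atoms] / masses[atoms].sum()
            com = np.einsum("s,fsd->fd", mw, coords[:, atoms, :])  # (F, 3)
            shift = -np.round(com / traj.box) * traj.box
            coords[:, atoms, :] += shift[:, None, :]

    return traj.with_coords(coords)


def brute_force_average_linkage(distances: np.ndarray,
                                epsilon: float) -> np.ndarray:
    """Reference average-linkage agglomeration by direct enumeration.

    Exhaustively recomputes every inter-cluster average distance at each
    step and merges the closest pair until the minimum exceeds epsilon.
    O(F^4); intended as an independent oracle for small frame counts.
    """
    f = len(distances)
    clusters: list[list[int]] = [[i] for i in range(f)]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([distances[i, j] for i in clusters[a]
                             for j in clusters[b]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        if best[0] > epsilon:
            break
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(f, dtype=int)
    for k, members in enumerate(clusters):
        labels[members] = k
    return labels
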