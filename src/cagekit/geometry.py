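"""Rigid-body geometry primitives: least-squares superposition, RMSD,
gyration tensors and torsions.

All routines take plain (N, 3) coordinate arrays in Angstroms.  The
superposition is the standard Kabsch algorithm (SVD of the covariance
with a determinant correction so only proper rotations are returned).
"""

from __future__ import annotations

import numpy as np


def kabsch_rotation(ref: np.ndarray, mob: np.ndarray,
                    weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation superposing *mob* onto *ref*.

    Returns ``(R, t_ref, t_mob)`` where ``(mob - t_mob) @ R.T + t_ref``
    is the superposed copy; ``t_ref`` / ``t_mob`` are the (weighted)
    centroids.
    """
    ref = np.asarray(ref, float)
    mob = np.asarray(mob, float)
    if ref.shape != mob.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {mob.shape}")
    if weights is None:
        w = np.ones(len(ref))
    else:
        w = np.asarray(weights, float)
    w = w / w.sum()
    t_ref = w @ ref
    t_mob = w @ mob
    a = (ref - t_ref) * w[:, None]
    b = mob - t_mob
    h = b.T @ a  # 3x3 covariance
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    return r, t_ref, t_mob


def superpose(ref: np.ndarray, mob: np.ndarray,
              weights: np.ndarray | None = None) -> np.ndarray:
    """Rigidly superpose *mob* onto *ref*; returns moved coordinates."""
    r, t_ref, t_mob = kabsch_rotation(ref, mob, weights)
    return (mob - t_mob) @ r.T + t_ref


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Raw (unfitted) root-mean-square coordinate deviation."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_rmsd_coords(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets over rigid motions."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    n = len(a)
    ga = np.sum(ac * ac)
    gb = np.sum(bc * bc)
    h = ac.T @ bc
    s = np.linalg.svd(h, compute_uv=False)
    # det correction: flip the smallest singular value for improper fits
    if np.linalg.det(h) < 0:
        s = s.copy()
        s[-1] = -s[-1]
    msd = max((ga + gb - 2.0 * s.sum()) / n, 0.0)
    return float(np.sqrt(msd))


def gyration_tensor(coords: np.ndarray,
                    weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted second-moment (gyration) tensor, Angstrom^2.

    ``S = sum_i w_i (r_i - rbar)(r_i - rbar)^T / sum_i w_i`` with ``rbar``
    the weighted centroid.
    """
    x = np.asarray(coords, float)
    if weights is None:
        w = np.ones(len(x))
    else:
        w = np.asarray(weights, float)
    w = w / w.sum()
    c = x - w @ x
    return (c * w[:, None]).T @ c


def gyration_eigenvalues(coords: np.ndarray,
                         weights: np.ndarray | None = None) -> np.ndarray:
    """Eigenvalues of the gyration tensor, descending (lam1 >= lam2 >= lam3)."""
    s = gyration_tensor(coords, weights)
    lam = np.linalg.eigvalsh(s)[::-1]
    return np.clip(lam, 0.0, None)


def relative_shape_anisotropy(lam: np.ndarray) -> float:
    """kappa^2 in [0, 1] from gyration-tensor eigenvalues.

    0 for perfectly isotropic point sets, 1 for collinear ones.  A fully
    collapsed set (all eigenvalues zero) is isotropic by convention.
    """
    lam = np.asarray(lam, float)
    tr = lam.sum()
    if tr <= 1e-12:  # collapsed to a point: isotropic by convention
        return 0.0
    return float(1.5 * np.sum(lam**2) / tr**2 - 0.5)


def asphericity(lam: np.ndarray) -> float:
    """b = lam1 - (lam2 + lam3)/2, Angstrom^2."""
    lam = np.asarray(lam, float)
    return float(lam[0] - 0.5 * (lam[1] + lam[2]))


def principal_axis(coords: np.ndarray,
                   weights: np.ndarray | None = None) -> np.ndarray:
    """Unit eigenvector of the gyration tensor with the largest eigenvalue."""
    s = gyration_tensor(coords, weights)
    evals, evecs = np.linalg.eigh(s)
    v = evecs[:, -1]
    return v / np.linalg.norm(v)


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle of four points, degrees in (-180, 180].

    Follows the IUPAC convention: looking down the p1->p2 bond, the angle
    is positive when the far bond is rotated clockwise from the near bond.
    Raises ``ValueError`` when three consecutive points are collinear.
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("dihedral undefined: three consecutive points collinear")
    m = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m @ n2
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)
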