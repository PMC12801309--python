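"""Small rigid-body geometry toolbox shared by all analysis modules.

All lengths are in nm, all angles in degrees unless a function says otherwise.
Rotation matrices act on column vectors; triads store frame axes as columns.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rotation_about",
    "kabsch",
    "superpose_rmsd",
    "dihedral",
    "fit_plane",
    "signed_angle",
]


def rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix about an arbitrary axis (Rodrigues formula)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    u = axis / n
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    K = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(u, u)


def kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Optimal (weighted) rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd, degenerate)`` such that
    ``rotation @ x + translation`` maps mobile points onto the reference in the
    least-squares sense.  The rotation is always proper (det +1).  For
    (near-)collinear point sets the rotation is ill-determined; those are
    flagged ``degenerate`` and fitted by translation only.
    """
    A = np.asarray(mobile, dtype=float)
    B = np.asarray(reference, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"coordinate shape mismatch: {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    ca = (w[:, None] * A).sum(axis=0)
    cb = (w[:, None] * B).sum(axis=0)
    A0 = A - ca
    B0 = B - cb

    H = (w[:, None] * A0).T @ B0
    U, S, Vt = np.linalg.svd(H)
    # collinear sets have (at most) one significant singular value
    degenerate = bool(S[0] > 0 and S[1] / S[0] < 1e-8) or S[0] == 0
    if degenerate:
        R = np.eye(3)
    else:
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cb - R @ ca
    diff = (R @ A.T).T + t - B
    rmsd = float(np.sqrt((w * (diff**2).sum(axis=1)).sum()))
    return R, t, rmsd, degenerate


def superpose_rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch superposition; returns (rotation, translation, minimum RMSD in nm)."""
    R, t, rmsd, _ = kabsch(mobile, reference, weights)
    return R, t, rmsd


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign, range (-180, 180]."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = np.degrees(np.arctan2(y, x))
    return float(ang) if ang != -180.0 else 180.0


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through points: (centroid, unit normal, out-of-plane RMS).

    The normal is the singular vector of the smallest singular value; its sign
    is arbitrary and must be fixed by the caller when continuity matters.
    Raises for point sets that do not define a plane (collinear).
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[0] < 3:
        raise ValueError("plane fit needs at least 3 points")
    c = P.mean(axis=0)
    _, S, Vt = np.linalg.svd(P - c)
    if S[1] / max(S[0], 1e-300) < 1e-8:
        raise ValueError("points are collinear; no plane defined")
    normal = Vt[2]
    rms = float(S[2] / np.sqrt(P.shape[0]))
    return c, normal, rms


def signed_angle(v1: np.ndarray, v2: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle (degrees) from v1 to v2 about ``axis``, right-hand rule."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    u = np.asarray(v1, float) - (np.asarray(v1, float) @ a) * a
    v = np.asarray(v2, float) - (np.asarray(v2, float) @ a) * a
    x = u @ v
    y = np.cross(u, v) @ a
    return float(np.degrees(np.arctan2(y, x)))
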