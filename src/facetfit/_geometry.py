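"""Small rotation / lattice geometry helpers shared across modules.

All rotations are proper (det +1). Axis-angle vectors are in radians; the
rotation angle is the vector norm and the axis its direction.
"""
from __future__ import annotations

import numpy as np


def rotation_matrix(rotvec: np.ndarray) -> np.ndarray:
    """Rodrigues formula for a single axis-angle vector (3,) -> (3, 3).

    Smooth at the identity: uses the series-safe sinc-style form.
    """
    return rotation_matrices(np.asarray(rotvec, dtype=float)[None, :])[0]


def rotation_matrices(rotvecs: np.ndarray) -> np.ndarray:
    """Vectorized Rodrigues formula, (B, 3) -> (B, 3, 3).

    Implemented with ``sin(t)/t`` and ``(1-cos(t))/t^2`` factors evaluated
    through numerically safe small-angle expansions so the map stays smooth
    (and finite-difference friendly) through the identity.
    """
    r = np.asarray(rotvecs, dtype=float)
    t2 = np.einsum("bi,bi->b", r, r)
    t = np.sqrt(t2)
    small = t < 1e-6
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(small, 1.0 - t2 / 6.0, np.sin(t) / np.where(small, 1.0, t))
        b = np.where(small, 0.5 - t2 / 24.0, (1.0 - np.cos(t)) / np.where(small, 1.0, t2))
    zeros = np.zeros_like(t)
    kx, ky, kz = r[:, 0], r[:, 1], r[:, 2]
    K = np.stack(
        [
            np.stack([zeros, -kz, ky], axis=-1),
            np.stack([kz, zeros, -kx], axis=-1),
            np.stack([-ky, kx, zeros], axis=-1),
        ],
        axis=-2,
    )
    eye = np.broadcast_to(np.eye(3), K.shape)
    return eye + a[:, None, None] * K + b[:, None, None] * (K @ K)


def rotvec_from_matrix(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rotation_matrix` (principal branch, angle in [0, pi])."""
    R = np.asarray(R, dtype=float)
    cos = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.arccos(cos)
    if angle < 1e-12:
        return np.zeros(3)
    if np.pi - angle < 1e-6:
        # near-pi: axis from the symmetric part
        A = (R + np.eye(3)) / 2.0
        axis = np.sqrt(np.clip(np.diag(A), 0.0, None))
        # fix signs using off-diagonals
        i = int(np.argmax(axis))
        axis = A[i] / max(axis[i], 1e-12)
        axis = axis / np.linalg.norm(axis)
        return axis * angle
    axis = (
        np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        / (2.0 * np.sin(angle))
    )
    return axis * angle


def geodesic_angle(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Geodesic distance on SO(3): arccos((tr(Ra Rb^T) - 1)/2)."""
    cos = np.clip((np.trace(Ra @ Rb.T) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.arccos(cos))


def random_rotvec(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation on SO(3) via the normalized-quaternion method."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    if w < 0:
        w, x, y, z = -w, -x, -y, -z
    angle = 2.0 * np.arccos(np.clip(w, -1.0, 1.0))
    s = np.sqrt(max(1.0 - w * w, 0.0))
    if s < 1e-12:
        return np.zeros(3)
    return np.array([x, y, z]) / s * angle


def direct_lattice_vectors(unit_cell) -> np.ndarray:
    """Row-stacked direct lattice vectors for (a, b, c, alpha, beta, gamma).

    Lengths in the cell's units, angles in degrees.  Conventional
    orientation: ``a`` along x, ``b`` in the xy plane.
    """
    a, b, c, al, be, ga = [float(x) for x in unit_cell]
    if min(a, b, c) <= 0:
        raise ValueError("unit cell lengths must be positive")
    if not all(0.0 < x < 180.0 for x in (al, be, ga)):
        raise ValueError("unit cell angles must be in (0, 180) degrees")
    al, be, ga = np.radians([al, be, ga])

    def _cos(x):  # exact zeros for right angles (cos(pi/2) != 0 in floats)
        c = np.cos(x)
        return 0.0 if abs(c) < 1e-15 else c

    va = np.array([a, 0.0, 0.0])
    vb = np.array([b * _cos(ga), b * np.sin(ga), 0.0])
    cx = _cos(be)
    cy = (_cos(al) - _cos(be) * _cos(ga)) / np.sin(ga)
    cz2 = 1.0 - cx * cx - cy * cy
    if cz2 <= 1e-12:
        raise ValueError("degenerate unit cell: angles do not define a 3D lattice")
    vc = c * np.array([cx, cy, np.sqrt(cz2)])
    return np.stack([va, vb, vc])


def reciprocal_lattice_vectors(unit_cell) -> np.ndarray:
    """Row-stacked reciprocal basis (without the 2*pi factor)."""
    A = direct_lattice_vectors(unit_cell)
    return np.linalg.inv(A).T
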