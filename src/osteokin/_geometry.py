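"""Low-level rotation and homogeneous-transform helpers.

Internal module: everything here works in radians and 4x4 homogeneous
matrices in the column-vector convention (``world = T @ [local, 1]``).
"""
from __future__ import annotations

import numpy as np

GIMBAL_COS_TOL = 1e-6


def rot_x(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation about an arbitrary unit axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero rotation axis")
    x, y, z = axis / n
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def compose_zyx(rz: float, ry: float, rx: float) -> np.ndarray:
    """Rotation matrix for the z-then-y-then-x intrinsic Euler sequence."""
    return rot_z(rz) @ rot_y(ry) @ rot_x(rx)


def decompose_zyx(R: np.ndarray) -> tuple[float, float, float, bool]:
    """Extract (rz, ry, rx) radians from ``R = Rz @ Ry @ Rx``.

    Returns a fourth element flagging gimbal proximity (|cos ry| < 1e-6);
    in that case rx is set to 0 by convention and rz absorbs the sum.
    """
    sy = -float(R[2, 0])
    sy = min(1.0, max(-1.0, sy))
    ry = np.arcsin(sy)
    if abs(np.cos(ry)) < GIMBAL_COS_TOL:
        # ry = +/-90 deg: only rz +/- rx is observable.  Convention: rx = 0.
        rz = float(np.arctan2(-R[0, 1], R[1, 1]))
        return rz, float(ry), 0.0, True
    rz = float(np.arctan2(R[1, 0], R[0, 0]))
    rx = float(np.arctan2(R[2, 1], R[2, 2]))
    return rz, float(ry), float(rx), False


def hom(R: np.ndarray | None = None, t: np.ndarray | None = None) -> np.ndarray:
    """Build a 4x4 homogeneous transform from a rotation block and translation."""
    T = np.eye(4)
    if R is not None:
        T[:3, :3] = R
    if t is not None:
        T[:3, 3] = np.asarray(t, dtype=float)
    return T


def inv_hom(T: np.ndarray) -> np.ndarray:
    """Closed-form inverse of a rigid homogeneous transform."""
    R = T[:3, :3]
    out = np.eye(4)
    out[:3, :3] = R.T
    out[:3, 3] = -R.T @ T[:3, 3]
    return out


def apply_hom(T: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 4x4 transform to an (..., 3) array of points."""
    points = np.asarray(points, dtype=float)
    return points @ T[:3, :3].T + T[:3, 3]


def is_rotation(R: np.ndarray, tol: float = 1e-9) -> bool:
    return (
        np.allclose(R.T @ R, np.eye(3), atol=tol)
        and abs(np.linalg.det(R) - 1.0) < tol
    )


def orthonormal_frame(x: np.ndarray, z_hint: np.ndarray) -> np.ndarray:
    """Right-handed 3x3 frame with first column along ``x``.

    The third column is ``z_hint`` projected orthogonal to x; the second
    column completes the right-handed triad (y = z cross x).
    """
    x = np.asarray(x, dtype=float)
    x = x / np.linalg.norm(x)
    z = np.asarray(z_hint, dtype=float)
    z = z - (z @ x) * x
    nz = np.linalg.norm(z)
    if nz < 1e-12:
        raise ValueError("z_hint parallel to x")
    z = z / nz
    y = np.cross(z, x)
    return np.column_stack([x, y, z])
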