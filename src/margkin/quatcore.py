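"""Quaternion and rotation algebra for singularity-free orientation handling.

Conventions
-----------
* Hamilton quaternions, right-handed, **scalar-first** ``(w, x, y, z)``.
* A quaternion ``q`` represents the rotation of the sensor (or segment)
  frame into the global frame: ``v_global = R(q) @ v_sensor``; the columns
  of ``R(q)`` are the sensor axes expressed in the global frame.
* Composition is by the Hamilton product ``⊗``; ``hamilton(a, b)`` applies
  ``b`` first, then ``a`` (matching matrix composition ``R(a) @ R(b)``).
* Internally angles are radians; every reporting boundary is degrees.

All functions accept either a single quaternion of shape ``(4,)`` or a
batch of shape ``(n, 4)`` and broadcast accordingly.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "identity_quat",
    "normalize",
    "canonicalize",
    "hamilton",
    "conjugate",
    "rotate_vector",
    "quat_to_dcm",
    "dcm_to_quat",
    "quat_from_axis_angle",
    "quat_to_euler",
    "euler_to_quat",
    "quat_angle",
    "GimbalLockWarning",
]

_EULER_AXES = {"X": 0, "Y": 1, "Z": 2}


class GimbalLockWarning(UserWarning):
    """Raised when an Euler decomposition approaches its singular configuration."""


def _as_quat(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError(f"quaternion must have 4 components, got shape {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ValueError("quaternion has non-finite components")
    return q


def identity_quat() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def normalize(q) -> np.ndarray:
    q = _as_quat(q)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize a near-zero quaternion")
    return q / n


def canonicalize(q) -> np.ndarray:
    """Return the sign-canonical representative (w >= 0) of the same rotation."""
    q = normalize(q)
    sign = np.where(q[..., :1] < 0.0, -1.0, 1.0)
    return q * sign


def hamilton(a, b) -> np.ndarray:
    """Hamilton product a ⊗ b (apply b, then a). Non-commutative."""
    a = _as_quat(a)
    b = _as_quat(b)
    aw, ax, ay, az = (a[..., i] for i in range(4))
    bw, bx, by, bz = (b[..., i] for i in range(4))
    out = np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )
    return normalize(out)


def conjugate(q) -> np.ndarray:
    q = _as_quat(q)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def rotate_vector(q, v) -> np.ndarray:
    """Rotate vector(s) v from the sensor frame into the global frame."""
    q = _as_quat(q)
    v = np.asarray(v, dtype=float)
    w = q[..., 0:1]
    u = q[..., 1:4]
    # Rodrigues form of q v q*; cheaper than building the DCM.
    t = 2.0 * np.cross(u, v)
    return v + w * t + np.cross(u, t)


def quat_to_dcm(q) -> np.ndarray:
    """Direction cosine matrix with columns = sensor axes in the global frame."""
    q = normalize(q)
    w, x, y, z = (q[..., i] for i in range(4))
    R = np.empty(q.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1 - 2 * (y * y + z * z)
    R[..., 0, 1] = 2 * (x * y - w * z)
    R[..., 0, 2] = 2 * (x * z + w * y)
    R[..., 1, 0] = 2 * (x * y + w * z)
    R[..., 1, 1] = 1 - 2 * (x * x + z * z)
    R[..., 1, 2] = 2 * (y * z - w * x)
    R[..., 2, 0] = 2 * (x * z - w * y)
    R[..., 2, 1] = 2 * (y * z + w * x)
    R[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def dcm_to_quat(R, tol: float = 1e-6) -> np.ndarray:
    """Inverse of :func:`quat_to_dcm`; returns the canonical (w >= 0) quaternion.

    Rejects matrices that are not proper rotations to within ``tol``.
    """
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise ValueError("rotation matrix must be 3x3")
    err = np.abs(np.swapaxes(R, -1, -2) @ R - np.eye(3)).max()
    if err > tol:
        raise ValueError(f"matrix is not orthonormal (deviation {err:.2e} > {tol:.0e})")
    if np.any(np.linalg.det(R) < 0):
        raise ValueError("matrix has negative determinant (improper rotation)")

    single = R.ndim == 2
    R = np.atleast_3d(R) if single else R
    if single:
        R = R.reshape(1, 3, 3)
    # Shepperd's method: pick the numerically largest of the four pivots.
    q = np.empty(R.shape[:-2] + (4,))
    tr = np.trace(R, axis1=-2, axis2=-1)
    for idx in np.ndindex(R.shape[:-2]):
        m = R[idx]
        t = tr[idx]
        if t > 0:
            s = np.sqrt(t + 1.0) * 2
            q[idx] = [0.25 * s, (m[2, 1] - m[1, 2]) / s, (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
        elif m[0, 0] >= m[1, 1] and m[0, 0] >= m[2, 2]:
            s = np.sqrt(1.0 + m[0, 0] - m[1, 1] - m[2, 2]) * 2
            q[idx] = [(m[2, 1] - m[1, 2]) / s, 0.25 * s, (m[0, 1] + m[1, 0]) / s, (m[0, 2] + m[2, 0]) / s]
        elif m[1, 1] >= m[2, 2]:
            s = np.sqrt(1.0 + m[1, 1] - m[0, 0] - m[2, 2]) * 2
            q[idx] = [(m[0, 2] - m[2, 0]) / s, (m[0, 1] + m[1, 0]) / s, 0.25 * s, (m[1, 2] + m[2, 1]) / s]
        else:
            s = np.sqrt(1.0 + m[2, 2] - m[0, 0] - m[1, 1]) * 2
            q[idx] = [(m[1, 0] - m[0, 1]) / s, (m[0, 2] + m[2, 0]) / s, (m[1, 2] + m[2, 1]) / s, 0.25 * s]
    q = canonicalize(q)
    return q[0] if single else q


def quat_from_axis_angle(axis, angle_rad) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle_rad`` about ``axis``.

    ``angle_rad`` may be a scalar or an array; the axis is shared.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = 0.5 * np.asarray(angle_rad, dtype=float)
    w = np.cos(half)[..., None]
    xyz = np.sin(half)[..., None] * axis
    return np.concatenate([w, xyz], axis=-1)


def quat_angle(q) -> np.ndarray:
    """Rotation angle (radians, in [0, pi]) encoded by q."""
    q = canonicalize(q)
    w = np.clip(q[..., 0], -1.0, 1.0)
    return 2.0 * np.arccos(w)


def quat_to_euler(q, sequence: str = "YXZ", degrees: bool = True, lock_tol: float = 1e-6):
    """Intrinsic Euler decomposition of q.

    ``sequence`` names three intrinsic axes, e.g. ``"YXZ"`` (the default used
    at the joint-angle reporting boundary: sagittal flexion/extension first,
    so flexion is single-axis-exact over the full ±180° range).  Emits a
    :class:`GimbalLockWarning` when the middle angle sits within ``lock_tol``
    of its singularity.
    """
    seq = sequence.upper()
    if len(seq) != 3 or any(c not in _EULER_AXES for c in seq) or seq[0] == seq[1] or seq[1] == seq[2]:
        raise ValueError(f"unsupported Euler sequence {sequence!r}")
    from scipy.spatial.transform import Rotation

    q = normalize(q)
    xyzw = np.stack([q[..., 1], q[..., 2], q[..., 3], q[..., 0]], axis=-1)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ang = Rotation.from_quat(xyzw).as_euler(seq, degrees=degrees)
    mid = np.atleast_2d(ang)[..., 1]
    mid_rad = np.deg2rad(mid) if degrees else mid
    if seq[0] == seq[2]:  # proper Euler: singular at mid = 0 or pi
        near_lock = np.minimum(np.abs(mid_rad), np.abs(np.pi - np.abs(mid_rad))) < lock_tol
    else:  # Tait-Bryan: singular at mid = ±pi/2
        near_lock = np.abs(np.abs(mid_rad) - np.pi / 2) < lock_tol
    if caught or np.any(near_lock):
        warnings.warn("Euler decomposition near gimbal lock; angles degenerate", GimbalLockWarning, stacklevel=2)
    return ang


def euler_to_quat(angles, sequence: str = "YXZ", degrees: bool = True) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_euler(sequence.upper(), angles, degrees=degrees)
    xyzw = rot.as_quat()
    q = np.stack([xyzw[..., 3], xyzw[..., 0], xyzw[..., 1], xyzw[..., 2]], axis=-1)
    return canonicalize(q)
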