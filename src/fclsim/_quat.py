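"""Minimal batched quaternion kernels for the stepper hot path.

Quaternions use scipy's (x, y, z, w) component order so arrays are
interchangeable with scipy.spatial.transform.Rotation, which remains the
reference implementation for non-performance-critical code paths.
"""

from __future__ import annotations

import numpy as np


def multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 * q2 (rotation q2 followed by q1), batched."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    x1, y1, z1, w1 = q1[..., 0], q1[..., 1], q1[..., 2], q1[..., 3]
    x2, y2, z2, w2 = q2[..., 0], q2[..., 1], q2[..., 2], q2[..., 3]
    return np.stack(
        [
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        ],
        axis=-1,
    )


def from_euler_xyz(angles: np.ndarray) -> np.ndarray:
    """Quaternion of extrinsic x-y-z rotations (R = Rz Ry Rx), batched.

    Matches scipy ``Rotation.from_euler('xyz', angles)``.
    """
    angles = np.asarray(angles, dtype=float)
    half = 0.5 * angles
    s = np.sin(half)
    c = np.cos(half)
    shape = angles.shape[:-1] + (4,)
    qx = np.zeros(shape)
    qx[..., 0] = s[..., 0]
    qx[..., 3] = c[..., 0]
    qy = np.zeros(shape)
    qy[..., 1] = s[..., 1]
    qy[..., 3] = c[..., 1]
    qz = np.zeros(shape)
    qz[..., 2] = s[..., 2]
    qz[..., 3] = c[..., 2]
    return multiply(qz, multiply(qy, qx))


def normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def apply(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors ``v`` by quaternions ``q`` (broadcasting batches)."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    qv = q[..., :3]
    qw = q[..., 3:]
    t = 2.0 * np.cross(qv, v)
    return v + qw * t + np.cross(qv, t)


def to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices, shape (..., 3, 3), for unit quaternions."""
    q = np.asarray(q, dtype=float)
    x, y, z, w = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - z * w)
    m[..., 0, 2] = 2 * (x * z + y * w)
    m[..., 1, 0] = 2 * (x * y + z * w)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - x * w)
    m[..., 2, 0] = 2 * (x * z - y * w)
    m[..., 2, 1] = 2 * (y * z + x * w)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m
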