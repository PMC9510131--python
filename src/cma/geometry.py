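"""Rigid-body geometry primitives: transforms, superposition, rotations.

All coordinates are in Ångström, all angles in degrees unless noted.
Rotation matrices are proper (det = +1); superposition uses the
Kabsch/SVD least-squares solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError

__all__ = [
    "RigidTransform",
    "kabsch",
    "rotation_about_axis",
    "rotation_angle",
    "rotation_axis",
    "screw_axis_point",
    "rmsd",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R @ x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tra = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)
        if abs(np.linalg.det(rot) - 1.0) > 1e-6:
            raise UsageError(
                f"rotation matrix is not proper (det={np.linalg.det(rot):.6f})"
            )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single 3-vector)."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )


def kabsch(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the transform minimising ``sum ||R m_i + t - t_i||^2`` over
    the matched (N, 3) coordinate sets.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise UsageError("kabsch requires two matched (N, 3) coordinate sets")
    if len(mobile) < 3:
        raise UsageError("kabsch requires at least 3 matched points")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, ct - rot @ cm)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unfitted) root-mean-square deviation of matched points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rotation_about_axis(
    direction: np.ndarray, point: np.ndarray, angle_deg: float
) -> RigidTransform:
    """Rotation by ``angle_deg`` about the line through ``point`` along
    ``direction`` (Rodrigues construction)."""
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise UsageError("axis direction must be non-zero")
    d = d / norm
    p = np.asarray(point, dtype=float).reshape(3)
    theta = np.deg2rad(angle_deg)
    k = np.array(
        [[0.0, -d[2], d[1]], [d[2], 0.0, -d[0]], [-d[1], d[0], 0.0]]
    )
    rot = np.eye(3) + np.sin(theta) * k + (1.0 - np.cos(theta)) * (k @ k)
    return RigidTransform(rot, p - rot @ p)


def rotation_angle(rotation: np.ndarray) -> float:
    """Rotation angle of a proper rotation matrix, in degrees in [0, 180]."""
    tr = float(np.trace(np.asarray(rotation, dtype=float)))
    return float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))


def rotation_axis(rotation: np.ndarray) -> np.ndarray:
    """Unit fixed-vector (eigenvector for eigenvalue +1) of a rotation.

    The sign convention makes the component of largest magnitude positive;
    for 180-degree rotations the axis sign is inherently arbitrary.
    """
    rot = np.asarray(rotation, dtype=float)
    w, v = np.linalg.eig(rot)
    idx = int(np.argmin(np.abs(w - 1.0)))
    axis = np.real(v[:, idx])
    axis = axis / np.linalg.norm(axis)
    pivot = int(np.argmax(np.abs(axis)))
    if axis[pivot] < 0:
        axis = -axis
    return axis


def screw_axis_point(transform: RigidTransform) -> np.ndarray:
    """A point on the screw axis of a rigid transform.

    Solves ``(I - R) p = t_perp`` in the plane perpendicular to the axis,
    where ``t_perp`` is the translation with its axis-parallel component
    removed; returns the solution of minimum norm.
    """
    axis = rotation_axis(transform.rotation)
    t = transform.translation
    t_perp = t - np.dot(t, axis) * axis
    a = np.eye(3) - transform.rotation
    p, *_ = np.linalg.lstsq(a, t_perp, rcond=None)
    # remove any axial component so the point is well-defined
    return p - np.dot(p, axis) * axis
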