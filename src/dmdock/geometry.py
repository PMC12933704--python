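"""Rigid-body geometry helpers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion y = R @ x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           allow_reflection: bool = False) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the transform and the post-fit RMSD.  By default the rotation is
    constrained to be proper (det = +1) so chirality is preserved.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("kabsch requires matching (n, 3) coordinate arrays")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    a = mobile - mu_m
    b = reference - mu_r
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if allow_reflection:
        d = 1.0
    s = np.diag([1.0, 1.0, d])
    rot = vt.T @ s @ u.T
    t = mu_r - rot @ mu_m
    fitted = a @ rot.T + mu_r
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return RigidTransform(rot, t), rmsd


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without superposition."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("coordinate arrays must have identical shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis by ``angle`` rad."""
    axis = np.asarray(axis, dtype=np.float64)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero rotation axis")
    x, y, z = axis / n
    c, s = np.cos(angle), np.sin(angle)
    cc = 1.0 - c
    return np.array([
        [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
        [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
        [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
    ])
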