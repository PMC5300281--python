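"""Rigid-body transforms as validated 4x4 homogeneous matrices.

A rigid transform maps world-space points x (mm) to R @ x + t where R is a
proper rotation (orthonormal, det = +1).  These are the registration matrices
moving one scan's anatomy into another scan's space, and the residual matrices
obtained by composing a closed cycle of registrations.
"""

from __future__ import annotations

import numpy as np

__all__ = ["RigidTransform", "InvalidTransformError"]

_ORTHO_TOL = 1e-6


class InvalidTransformError(ValueError):
    """Raised when a matrix fails rigid-transform validation."""


class RigidTransform:
    """A 4x4 homogeneous rigid-body transform (rotation + translation).

    Parameters
    ----------
    matrix : (4, 4) array_like
        Homogeneous matrix with an orthonormal rotation block (RᵀR = I and
        det R = +1 within 1e-6) and last row (0, 0, 0, 1).
    """

    __slots__ = ("matrix",)

    def __init__(self, matrix):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise InvalidTransformError(f"expected a 4x4 matrix, got shape {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=_ORTHO_TOL):
            raise InvalidTransformError(f"last row must be (0, 0, 0, 1), got {m[3]}")
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=_ORTHO_TOL):
            raise InvalidTransformError("rotation block is not orthonormal within 1e-6")
        if not np.isclose(np.linalg.det(r), 1.0, atol=_ORTHO_TOL):
            raise InvalidTransformError(
                f"rotation block has det {np.linalg.det(r):.8f}, expected +1 "
                "(reflections are not rigid-body transforms)"
            )
        out = np.eye(4)
        out[:3, :3] = r
        out[:3, 3] = m[:3, 3]
        self.matrix = out
        self.matrix.flags.writeable = False

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rodrigues construction from a rotation axis, angle (degrees) and translation (mm)."""
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise InvalidTransformError("rotation axis must be non-zero")
        k = axis / n
        th = np.deg2rad(angle_deg)
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        r = np.eye(3) + np.sin(th) * kx + (1.0 - np.cos(th)) * (kx @ kx)
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @classmethod
    def from_translation(cls, translation) -> "RigidTransform":
        m = np.eye(4)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    # -- accessors ---------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        """The 3x3 rotation block."""
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        """The translation vector in mm."""
        return self.matrix[:3, 3]

    # -- algebra -----------------------------------------------------------
    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        if not isinstance(other, RigidTransform):
            return NotImplemented
        return RigidTransform(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = self.rotation.T
        m[:3, 3] = -self.rotation.T @ self.translation
        return RigidTransform(m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array of world-mm points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RigidTransform(t={self.translation}, R=\n{self.rotation})"
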