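"""Rigid-body transforms as 4x4 homogeneous matrices.

All transforms in this package map millimetre coordinates between frames,
most importantly from the CT frame into the 3D world frame of the biplanar
radiography system (the direction in which per-bone registration results
are expressed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform", "pose_to_transform", "transform_to_pose"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body transform (rotation + translation, no scaling).

    Parameters
    ----------
    matrix:
        4x4 homogeneous matrix. The rotation block must be orthonormal with
        determinant +1 (to 1e-9) and the last row (0, 0, 0, 1).
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"rigid transform must be 4x4, got {m.shape}")
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-7):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation block has negative determinant (reflection)")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=_ORTHO_TOL):
            raise ValueError("last row must be (0, 0, 0, 1)")
        # re-orthonormalization guard: project onto SO(3) so accumulated
        # round-off never leaks out of the type
        u, _, vt = np.linalg.svd(r)
        r_clean = u @ vt
        if np.linalg.det(r_clean) < 0:
            u[:, -1] *= -1
            r_clean = u @ vt
        clean = np.eye(4)
        clean[:3, :3] = r_clean
        clean[:3, 3] = m[:3, 3]
        object.__setattr__(self, "matrix", clean)
        self.matrix.setflags(write=False)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray, translation) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array or a single 3-vector of points (mm)."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.rotation.T + self.translation
        return out[0] if single else out

    def apply_vector(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        v = np.asarray(vectors, dtype=float)
        single = v.ndim == 1
        v = np.atleast_2d(v)
        out = v @ self.rotation.T
        return out[0] if single else out

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform.from_rotation_translation(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self @ other (apply ``other`` first)."""
        return RigidTransform(self.matrix @ other.matrix)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    # --- serialization -------------------------------------------------
    def to_text(self) -> str:
        rows = [" ".join(f"{v:.12g}" for v in row) for row in self.matrix]
        return "\n".join(rows) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RigidTransform":
        vals = [float(tok) for tok in text.split()]
        if len(vals) != 16:
            raise ValueError("expected 16 whitespace-delimited numbers")
        return cls(np.array(vals).reshape(4, 4))


def pose_to_transform(params, center=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Build a rigid transform from a 6-vector of pose parameters.

    ``params = (rx, ry, rz, tx, ty, tz)`` with rotations in degrees and
    translations in mm. The rotation is the intrinsic x-y-z Euler rotation
    applied about ``center`` (typically the bone's annotated midpoint, so
    rotational and translational parameters stay decoupled), followed by the
    translation: ``p -> R (p - c) + c + t``.
    """
    params = np.asarray(params, dtype=float)
    if params.shape != (6,) or not np.all(np.isfinite(params)):
        raise ValueError("pose parameters must be a finite 6-vector")
    c = np.asarray(center, dtype=float)
    r = Rotation.from_euler("XYZ", params[:3], degrees=True).as_matrix()
    t = params[3:] + c - r @ c
    return RigidTransform.from_rotation_translation(r, t)


def transform_to_pose(transform: RigidTransform, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Inverse of :func:`pose_to_transform` (same center and conventions)."""
    c = np.asarray(center, dtype=float)
    r = transform.rotation
    angles = Rotation.from_matrix(r).as_euler("XYZ", degrees=True)
    t = transform.translation - c + r @ c
    return np.concatenate([angles, t])
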