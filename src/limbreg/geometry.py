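"""Biplanar fan-beam (EOS-style) imaging geometry.

The EOS scanner acquires frontal and lateral standing radiographs with two
synchronized, mutually perpendicular fan beams that sweep vertically. Each
image row is therefore an independent 1D perspective projection in the
horizontal plane, while the vertical image axis maps to world height with no
magnification. The vendor rescales the horizontal axis so that the virtual
detector sits at the machine isocenter (magnification 1 at the isocenter).

World frame (right-handed): x to the patient's left, y posterior, z superior.
By convention the frontal line source lies at y = -f_f and the lateral line
source at x = -f_l; both move along z during the sweep. For a point
P = (Px, Py, Pz):

    frontal:  h_mm = f_f * Px / (f_f + Py),   v = (z0 - Pz) / lambda_z
    lateral:  h_mm = f_l * Py / (f_l + Px),   v = (z0 - Pz) / lambda_z

where h_mm is the horizontal offset on the isocenter detector and z0 the
initial emitter height. Stereo triangulation inverts the two horizontal
constraints as a 2x2 linear system and recovers the height as

    P_z = z0 - lambda_z * (v_f + v_l) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "EOSGeometry",
    "PixelCoord",
    "project_point",
    "project_points",
    "triangulate_point",
    "geometry_from_parameters",
]

Plane = Literal["frontal", "lateral"]

#: Calibration constants of the reference clinical device (from its DICOM
#: tags): source-to-isocenter distances, initial emitter height and the
#: vertical pixel pitch.
DEFAULT_CALIBRATION = {
    "f_frontal": 918.0,
    "f_lateral": 918.0,
    "z0": 477.5,
    "pitch_z": 0.179363,
}


@dataclass(frozen=True)
class PixelCoord:
    """A (sub)pixel location in one radiograph.

    ``h`` is the horizontal pixel position (column), ``v`` the vertical pixel
    position (row). Coordinates may lie outside the stored image bounds; the
    projection model is defined everywhere off the source lines.
    """

    plane: Plane
    h: float
    v: float

    def __post_init__(self) -> None:
        if self.plane not in ("frontal", "lateral"):
            raise ValueError(f"plane must be 'frontal' or 'lateral', got {self.plane!r}")
        if not (np.isfinite(self.h) and np.isfinite(self.v)):
            raise ValueError("pixel coordinates must be finite")


@dataclass(frozen=True)
class EOSGeometry:
    """Calibration of the biplanar fan-beam system (all lengths in mm).

    Attributes
    ----------
    f_frontal, f_lateral:
        Source-to-isocenter distances of the frontal and lateral emitters.
    z0:
        Initial emitter height (world z at image row 0).
    pitch_z:
        Vertical pixel pitch, mm/pixel (identical in both planes: the
        vertical axis is the synchronized scan axis).
    pitch_h_frontal, pitch_h_lateral:
        Horizontal pixel pitch at the isocenter-rescaled detector.
    n_rows, n_cols_frontal, n_cols_lateral:
        Image dimensions in pixels (rows are shared by construction).
    principal_frontal, principal_lateral:
        Column index where the central ray (through the isocenter axis)
        lands, per plane.
    """

    f_frontal: float = DEFAULT_CALIBRATION["f_frontal"]
    f_lateral: float = DEFAULT_CALIBRATION["f_lateral"]
    z0: float = DEFAULT_CALIBRATION["z0"]
    pitch_z: float = DEFAULT_CALIBRATION["pitch_z"]
    pitch_h_frontal: float | None = None
    pitch_h_lateral: float | None = None
    n_rows: int = 2000
    n_cols_frontal: int = 1000
    n_cols_lateral: int = 1000
    principal_frontal: float | None = None
    principal_lateral: float | None = None

    def __post_init__(self) -> None:
        # square pixels by default: only the vertical pitch is part of the
        # minimal calibration set
        if self.pitch_h_frontal is None:
            object.__setattr__(self, "pitch_h_frontal", self.pitch_z)
        if self.pitch_h_lateral is None:
            object.__setattr__(self, "pitch_h_lateral", self.pitch_z)
        # principal pixel defaults to the image-center column
        if self.principal_frontal is None:
            object.__setattr__(self, "principal_frontal", (self.n_cols_frontal - 1) / 2.0)
        if self.principal_lateral is None:
            object.__setattr__(self, "principal_lateral", (self.n_cols_lateral - 1) / 2.0)
        for name in ("f_frontal", "f_lateral", "z0", "pitch_z",
                     "pitch_h_frontal", "pitch_h_lateral"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v}")
        for name in ("n_rows", "n_cols_frontal", "n_cols_lateral"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")

    # -- per-plane accessors --------------------------------------------
    def source_distance(self, plane: Plane) -> float:
        return self.f_frontal if plane == "frontal" else self.f_lateral

    def pitch_h(self, plane: Plane) -> float:
        return self.pitch_h_frontal if plane == "frontal" else self.pitch_h_lateral

    def principal(self, plane: Plane) -> float:
        return self.principal_frontal if plane == "frontal" else self.principal_lateral

    def n_cols(self, plane: Plane) -> int:
        return self.n_cols_frontal if plane == "frontal" else self.n_cols_lateral

    def image_shape(self, plane: Plane) -> tuple[int, int]:
        return (self.n_rows, self.n_cols(plane))

    def source_position(self, plane: Plane, z: float | np.ndarray) -> np.ndarray:
        """Emitter position at sweep height ``z`` (line source sampled at z)."""
        z = np.asarray(z, dtype=float)
        if plane == "frontal":
            return np.stack(np.broadcast_arrays(np.zeros_like(z), -self.f_frontal + 0 * z, z), axis=-1)
        return np.stack(np.broadcast_arrays(-self.f_lateral + 0 * z, np.zeros_like(z), z), axis=-1)

    def row_height(self, v: float | np.ndarray) -> np.ndarray:
        """World z of the emitter/detector for image row ``v``."""
        return self.z0 - self.pitch_z * np.asarray(v, dtype=float)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EOSGeometry":
        with open(path) as fh:
            return geometry_from_parameters(yaml.safe_load(fh))


def project_points(points: np.ndarray, geom: EOSGeometry, plane: Plane) -> np.ndarray:
    """Project (N, 3) world points to (N, 2) pixel coordinates (h, v)."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    f = geom.source_distance(plane)
    if plane == "frontal":
        num, den = f * p[:, 0], f + p[:, 1]
    else:
        num, den = f * p[:, 1], f + p[:, 0]
    if np.any(np.abs(den) < 1e-9):
        raise ValueError("point at source plane: perspective denominator vanishes")
    h_mm = num / den
    h = geom.principal(plane) + h_mm / geom.pitch_h(plane)
    v = (geom.z0 - p[:, 2]) / geom.pitch_z
    return np.column_stack([h, v])


def project_point(point, geom: EOSGeometry, plane: Plane) -> PixelCoord:
    """Project a single 3D world point to frontal or lateral pixel space.

    The vertical coordinate is affine in world height with no magnification,
    ``v = (z0 - Pz) / pitch_z``; the horizontal coordinate is the fan-beam
    perspective ratio rescaled to the isocenter detector.
    """
    h, v = project_points(np.asarray(point, dtype=float)[None, :], geom, plane)[0]
    return PixelCoord(plane=plane, h=float(h), v=float(v))


def triangulate_point(frontal: PixelCoord, lateral: PixelCoord,
                      geom: EOSGeometry) -> np.ndarray:
    """Reconstruct a 3D world point from its frontal and lateral projections.

    (Px, Py) solve the 2x2 system given by the two horizontal perspective
    constraints (right-hand side entries are the products f*h in mm); the
    height is the exact average ``P_z = z0 - pitch_z * (v_f + v_l) / 2``.

    Raises
    ------
    ValueError
        If the two horizontal rays are (near-)parallel.
    """
    if frontal.plane != "frontal" or lateral.plane != "lateral":
        raise ValueError("arguments must be a frontal and a lateral PixelCoord")
    hf_mm = (frontal.h - geom.principal_frontal) * geom.pitch_h_frontal
    hl_mm = (lateral.h - geom.principal_lateral) * geom.pitch_h_lateral
    ff, fl = geom.f_frontal, geom.f_lateral
    # frontal constraint: ff*Px - hf*Py = ff*hf ; lateral: -hl*Px + fl*Py = fl*hl
    a = np.array([[ff, -hf_mm], [-hl_mm, fl]])
    b = np.array([ff * hf_mm, fl * hl_mm])
    det = ff * fl - hf_mm * hl_mm
    if abs(det) < 1e-9 * ff * fl:
        raise ValueError("rays parallel/ill-conditioned: cannot triangulate")
    px, py = np.linalg.solve(a, b)
    pz = geom.z0 - geom.pitch_z * (frontal.v + lateral.v) / 2.0
    return np.array([px, py, pz])


# mapping from the DICOM-style tag names found in EOS image headers to
# EOSGeometry fields (values are taken as mm / pixels)
DICOM_TAG_MAP = {
    "DistanceSourceToIsocenterFrontal": "f_frontal",
    "DistanceSourceToIsocenterLateral": "f_lateral",
    "InitialEmitterHeight": "z0",
    "PixelSpacingVertical": "pitch_z",
    "PixelSpacingHorizontalFrontal": "pitch_h_frontal",
    "PixelSpacingHorizontalLateral": "pitch_h_lateral",
    "RowsFrontal": "n_rows",
    "ColumnsFrontal": "n_cols_frontal",
    "ColumnsLateral": "n_cols_lateral",
    "PrincipalPixelFrontal": "principal_frontal",
    "PrincipalPixelLateral": "principal_lateral",
}


def geometry_from_parameters(params: dict | None = None) -> EOSGeometry:
    """Build a validated :class:`EOSGeometry` from a flat key-value set.

    Keys may be EOSGeometry field names or the DICOM-style tag names in
    :data:`DICOM_TAG_MAP`. Missing fields fall back to the reference device
    calibration (918 mm source distances, z0 = 477.5 mm, vertical pitch
    0.179363 mm) and the documented defaults (square pixels, principal pixel
    at the image-center column).
    """
    kwargs: dict = {}
    for key, value in (params or {}).items():
        field = DICOM_TAG_MAP.get(key, key)
        if field not in EOSGeometry.__dataclass_fields__:
            raise ValueError(f"unknown calibration key: {key!r}")
        if value is not None:
            kwargs[field] = value
    try:
        return EOSGeometry(**kwargs)
    except ValueError as exc:
        raise ValueError(f"invalid calibration: {exc}") from exc
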