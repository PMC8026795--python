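"""CT volumes and digitally reconstructed radiographs (DRRs).

A DRR is a synthetic radiograph computed by integrating X-ray attenuation
along the rays of the imaging geometry through a CT volume placed at a trial
pose. Because the similarity metric used for registration (localized NCC) is
invariant to monotone local intensity rescaling, the renderer stops at the
monochromatic line integral and applies no detector/exponential conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import EOSGeometry, Plane
from .transforms import RigidTransform

__all__ = [
    "CTVolume",
    "AttenuationVolume",
    "RadiographPair",
    "hu_to_attenuation",
    "render_drr",
]

#: linear attenuation coefficient of water, 1/mm (typical diagnostic energy)
MU_WATER = 0.02


@dataclass
class CTVolume:
    """A 3D scalar grid in Hounsfield units on an axis-aligned lattice.

    ``data`` is indexed ``[ix, iy, iz]``; voxel centers sit at
    ``origin + index * spacing`` in the volume's own (CT) frame, mm.
    Oblique direction cosines are not supported; resample obliquely
    acquired series before use.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 strictly positive values (mm)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) corner of the voxel-center bounding box, mm."""
        return self.origin.copy(), self.origin + (np.array(self.shape) - 1) * self.spacing

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_nifti(cls, path) -> "CTVolume":
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine
        lin = aff[:3, :3]
        # accept axis-aligned (possibly flipped/permuted) orientations only
        perm = np.argmax(np.abs(lin), axis=0)
        if sorted(perm.tolist()) != [0, 1, 2]:
            raise ValueError("oblique NIfTI orientation not supported; resample first")
        data = np.asarray(img.dataobj, dtype=np.float32)
        spacing = np.abs(lin[perm, range(3)])
        return cls(data=data, spacing=spacing, origin=aff[:3, 3])

    def to_nifti(self, path) -> None:
        import nibabel as nib

        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), aff), str(path))

    @classmethod
    def from_file(cls, path) -> "CTVolume":
        """Load NIfTI (.nii/.nii.gz), MHD/MHA, or a DICOM series directory."""
        import os

        p = str(path)
        if os.path.isdir(p):
            return cls._from_sitk_dicom(p)
        if p.endswith((".nii", ".nii.gz")):
            return cls.from_nifti(p)
        if p.endswith((".mhd", ".mha")):
            return cls._from_sitk_image(p)
        raise ValueError(f"unrecognized volume format: {p}")

    @classmethod
    def _from_sitk_image(cls, path) -> "CTVolume":
        import SimpleITK as sitk

        return cls._from_sitk(sitk.ReadImage(str(path)))

    @classmethod
    def _from_sitk_dicom(cls, directory) -> "CTVolume":
        import SimpleITK as sitk

        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(str(directory))
        if not files:
            raise ValueError(f"no DICOM series found in {directory}")
        reader.SetFileNames(files)
        return cls._from_sitk(reader.Execute())

    @classmethod
    def _from_sitk(cls, img) -> "CTVolume":
        import SimpleITK as sitk

        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        return cls(
            data=np.ascontiguousarray(arr.transpose(2, 1, 0)),
            spacing=np.asarray(img.GetSpacing(), dtype=float),
            origin=np.asarray(img.GetOrigin(), dtype=float),
        )


class AttenuationVolume(CTVolume):
    """Linear attenuation (1/mm) on the same lattice as its source CT."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.data < 0):
            raise ValueError("attenuation values must be non-negative")


@dataclass
class RadiographPair:
    """Frontal + lateral 2D images tied to one imaging geometry."""

    frontal: np.ndarray
    lateral: np.ndarray
    geometry: EOSGeometry

    def __post_init__(self) -> None:
        for plane, img in (("frontal", self.frontal), ("lateral", self.lateral)):
            img = np.asarray(img, dtype=float)
            if img.shape != self.geometry.image_shape(plane):
                raise ValueError(
                    f"{plane} image shape {img.shape} does not match geometry "
                    f"{self.geometry.image_shape(plane)}"
                )
        self.frontal = np.asarray(self.frontal, dtype=float)
        self.lateral = np.asarray(self.lateral, dtype=float)

    def image(self, plane: Plane) -> np.ndarray:
        return self.frontal if plane == "frontal" else self.lateral


def hu_to_attenuation(volume: CTVolume, mu_water: float = MU_WATER) -> AttenuationVolume:
    """Map Hounsfield units to linear attenuation, mu = (HU + 1000)/1000 * mu_water.

    Values below -1000 HU clip to zero attenuation; the lattice is unchanged.
    """
    mu = np.maximum(0.0, (np.asarray(volume.data, dtype=np.float32) + 1000.0) / 1000.0) * mu_water
    return AttenuationVolume(data=mu, spacing=volume.spacing.copy(), origin=volume.origin.copy())


def _ray_bundle(geom: EOSGeometry, plane: Plane, rows: np.ndarray, cols: np.ndarray):
    """Ray origins/directions (world frame) for a grid of pixel coordinates."""
    vv, hh = np.meshgrid(rows, cols, indexing="ij")
    z_row = geom.row_height(vv).ravel()
    h_mm = (hh.ravel() - geom.principal(plane)) * geom.pitch_h(plane)
    f = geom.source_distance(plane)
    n = z_row.size
    origins = np.empty((n, 3))
    dirs = np.empty((n, 3))
    if plane == "frontal":
        origins[:, 0], origins[:, 1] = 0.0, -f
        dirs[:, 0], dirs[:, 1] = h_mm, f
    else:
        origins[:, 0], origins[:, 1] = -f, 0.0
        dirs[:, 0], dirs[:, 1] = f, h_mm
    origins[:, 2] = z_row
    dirs[:, 2] = 0.0
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return origins, dirs


def render_drr(
    volume: AttenuationVolume,
    pose: RigidTransform,
    geom: EOSGeometry,
    plane: Plane,
    step: float | None = None,
    roi: tuple[int, int, int, int] | None = None,
    _chunk: int = 4096,
) -> np.ndarray:
    """Render one DRR plane of ``volume`` placed at ``pose`` (CT -> world).

    Each pixel holds the trapezoid-rule line integral of attenuation along
    the ray from the row's emitter position through the pixel's isocenter
    detector position, sampled with trilinear interpolation every ``step``
    mm (default: half the smallest voxel spacing). Samples outside the
    volume contribute zero; rays are clipped to the volume bounding box
    before sampling.

    Parameters
    ----------
    roi:
        Optional half-open pixel rectangle ``(r0, c0, r1, c1)``; only these
        pixels are rendered and the returned image has shape
        ``(r1 - r0, c1 - c0)``. Without it the full image is rendered.
    """
    if not isinstance(pose, RigidTransform):
        raise TypeError("pose must be a RigidTransform (non-rigid poses are not supported)")
    if step is None:
        step = float(volume.spacing.min()) / 2.0
    if step <= 0:
        raise ValueError("step must be > 0")
    if roi is None:
        r0, c0 = 0, 0
        r1, c1 = geom.image_shape(plane)
    else:
        r0, c0, r1, c1 = roi
    rows = np.arange(r0, r1, dtype=float)
    cols = np.arange(c0, c1, dtype=float)
    origins, dirs = _ray_bundle(geom, plane, rows, cols)

    inv = pose.inverse()
    o = origins @ inv.rotation.T + inv.translation  # rays in the CT frame
    d = dirs @ inv.rotation.T

    lo, hi = volume.world_bounds()
    out = np.zeros(o.shape[0])
    for start in range(0, o.shape[0], _chunk):
        sl = slice(start, start + _chunk)
        out[sl] = _integrate_rays(volume, o[sl], d[sl], lo, hi, step)
    return out.reshape(len(rows), len(cols))


def _integrate_rays(volume, origins, dirs, lo, hi, step):
    # slab clipping against the voxel-center AABB
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_d = 1.0 / dirs
        t_lo = (lo[None, :] - origins) * inv_d
        t_hi = (hi[None, :] - origins) * inv_d
    t0 = np.nanmax(np.minimum(t_lo, t_hi), axis=1)
    t1 = np.nanmin(np.maximum(t_lo, t_hi), axis=1)
    t0 = np.maximum(t0, 0.0)
    span = t1 - t0
    hit = span > 0
    if not np.any(hit):
        return np.zeros(origins.shape[0])
    span_h = span[hit]
    n_samp = int(np.ceil(span_h.max() / step)) + 1
    n_samp = max(n_samp, 2)
    frac = np.linspace(0.0, 1.0, n_samp)
    ts = t0[hit, None] + span_h[:, None] * frac[None, :]
    pts = origins[hit, None, :] + ts[:, :, None] * dirs[hit, None, :]
    idx = (pts - volume.origin) / volume.spacing
    vals = ndimage.map_coordinates(
        volume.data,
        idx.reshape(-1, 3).T,
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    ).reshape(ts.shape)
    dt = span_h / (n_samp - 1)
    integral = (vals.sum(axis=1) - 0.5 * (vals[:, 0] + vals[:, -1])) * dt
    result = np.zeros(origins.shape[0])
    result[hit] = integral
    return result
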