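"""Intensity-based 2D-3D rigid registration of one bone to a biplanar pair.

The pose of the CT (6 degrees of freedom: 3 Euler angles + 3 translations) is
optimized so that DRRs rendered from the CT match the frontal and lateral
radiographs inside user-drawn rectangular masks. The similarity is a
variance-weighted localized normalized cross correlation (LNCC) summed over
the two planes; optimization uses a bound-constrained derivative-free method.

The output is a 4x4 rigid transform mapping CT coordinates into the world
frame of the radiography system — the transform that, applied to the CT-derived
bone models, carries them into the standing (weight-bearing) pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .drr import AttenuationVolume, RadiographPair, render_drr
from .geometry import EOSGeometry, PixelCoord, Plane, triangulate_point
from .transforms import RigidTransform, pose_to_transform

__all__ = [
    "ArrowAnnotation",
    "ROIMask",
    "RegistrationConfig",
    "RegistrationResult",
    "initialize_pose",
    "lncc_similarity",
    "registration_cost",
    "register_bone",
]


@dataclass(frozen=True)
class ROIMask:
    """Axis-aligned pixel rectangle (half-open: rows r0..r1-1, cols c0..c1-1)."""

    r0: int
    c0: int
    r1: int
    c1: int

    def __post_init__(self) -> None:
        if self.r1 <= self.r0 or self.c1 <= self.c0:
            raise ValueError("ROI rectangle must be nonempty")

    def clipped(self, shape: tuple[int, int]) -> "ROIMask":
        r0, c0 = max(self.r0, 0), max(self.c0, 0)
        r1, c1 = min(self.r1, shape[0]), min(self.c1, shape[1])
        if r1 <= r0 or c1 <= c0:
            raise ValueError("ROI does not intersect the image")
        return ROIMask(r0, c0, r1, c1)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.r0, self.c0, self.r1, self.c1)


@dataclass
class ArrowAnnotation:
    """The three corresponding arrows used to initialize a registration.

    The same pair of anatomical landmarks (e.g. distal tibia to tibial
    plateau center) is annotated as an arrow in the frontal radiograph, the
    lateral radiograph, and the CT volume.
    """

    frontal_start: PixelCoord
    frontal_end: PixelCoord
    lateral_start: PixelCoord
    lateral_end: PixelCoord
    ct_start: np.ndarray
    ct_end: np.ndarray

    def __post_init__(self) -> None:
        self.ct_start = np.asarray(self.ct_start, dtype=float)
        self.ct_end = np.asarray(self.ct_end, dtype=float)
        for name, a, b in (
            ("frontal", (self.frontal_start.h, self.frontal_start.v),
             (self.frontal_end.h, self.frontal_end.v)),
            ("lateral", (self.lateral_start.h, self.lateral_start.v),
             (self.lateral_end.h, self.lateral_end.v)),
            ("ct", self.ct_start, self.ct_end),
        ):
            if np.allclose(a, b):
                raise ValueError(f"{name} arrow has zero length")

    @classmethod
    def from_dict(cls, d: dict) -> "ArrowAnnotation":
        fr, la, ct = d["frontal"], d["lateral"], d["ct"]
        return cls(
            frontal_start=PixelCoord("frontal", *fr[0]),
            frontal_end=PixelCoord("frontal", *fr[1]),
            lateral_start=PixelCoord("lateral", *la[0]),
            lateral_end=PixelCoord("lateral", *la[1]),
            ct_start=np.asarray(ct[0], dtype=float),
            ct_end=np.asarray(ct[1], dtype=float),
        )


@dataclass
class RegistrationConfig:
    """Settings of the pose optimization.

    ``bounds_translation`` (mm) and ``bounds_rotation`` (degrees) are
    symmetric box bounds around the initialization; patch_size is the LNCC
    neighborhood (odd, >= 3).
    """

    patch_size: int = 9
    bounds_translation: float = 30.0
    bounds_rotation: float = 30.0
    xtol: float = 0.01
    ftol: float = 1e-6
    max_evaluations: int = 2000
    drr_step: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd and >= 3")
        if not (np.isfinite(self.bounds_translation) and np.isfinite(self.bounds_rotation)):
            raise ValueError("bounds must be finite")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    params: np.ndarray
    cost: float
    n_evaluations: int
    converged: bool
    message: str
    center: np.ndarray


def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix carrying unit vector a onto unit vector b about a x b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    c = float(np.dot(a, b))
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about a fixed axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    axis = axis / s
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def initialize_pose(arrow: ArrowAnnotation, geom: EOSGeometry) -> RigidTransform:
    """Initial CT -> world pose from the three corresponding arrow annotations.

    The 2D arrow endpoints are triangulated to 3D; the returned transform is
    the minimal rotation (about the cross-product axis) taking the CT arrow
    direction onto the triangulated arrow direction, combined with the
    translation taking the CT arrow midpoint onto the triangulated midpoint.
    Roll about the arrow axis is unobservable from the arrows and left at
    zero; the intensity optimization resolves it.
    """
    start_3d = triangulate_point(arrow.frontal_start, arrow.lateral_start, geom)
    end_3d = triangulate_point(arrow.frontal_end, arrow.lateral_end, geom)
    world_dir = end_3d - start_3d
    ct_dir = arrow.ct_end - arrow.ct_start
    if np.linalg.norm(world_dir) < 1e-9 or np.linalg.norm(ct_dir) < 1e-9:
        raise ValueError("arrow endpoints coincide")
    r = _minimal_rotation(ct_dir, world_dir)
    ct_mid = (arrow.ct_start + arrow.ct_end) / 2.0
    world_mid = (start_3d + end_3d) / 2.0
    t = world_mid - r @ ct_mid
    return RigidTransform.from_rotation_translation(r, t)


def _patch_stats(img: np.ndarray, patch_size: int):
    """Local mean/variance over patch_size x patch_size neighborhoods."""
    size = (patch_size, patch_size)
    mean = ndimage.uniform_filter(img, size, mode="constant")
    sq = ndimage.uniform_filter(img * img, size, mode="constant")
    return mean, np.maximum(sq - mean * mean, 0.0)


def lncc_similarity(
    image_a: np.ndarray,
    image_b: np.ndarray,
    mask: ROIMask | None = None,
    patch_size: int = 9,
) -> float:
    """Variance-weighted localized normalized cross correlation.

    For every pixel inside ``mask`` whose full neighborhood lies inside the
    image, the NCC of the patch_size x patch_size neighborhoods of ``image_a``
    and ``image_b`` is computed; the score is the mean of these patch NCCs
    weighted by the local variance of ``image_b`` (the fixed radiograph), so
    structured regions dominate and flat background contributes nothing.
    Zero-variance patches get weight zero; the score lies in [-1, 1].
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have identical shapes")
    if patch_size % 2 == 0 or patch_size < 3:
        raise ValueError("patch_size must be odd and >= 3")
    k = patch_size // 2
    if mask is None:
        mask = ROIMask(0, 0, a.shape[0], a.shape[1])
    mask = mask.clipped(a.shape)
    # restrict to pixels whose patches fit fully inside the image: no edge
    # convention enters the score
    r0 = max(mask.r0, k)
    c0 = max(mask.c0, k)
    r1 = min(mask.r1, a.shape[0] - k)
    c1 = min(mask.c1, a.shape[1] - k)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("mask empty after intersection with the patch-valid region")

    mean_a, var_a = _patch_stats(a, patch_size)
    mean_b, var_b = _patch_stats(b, patch_size)
    mean_ab = ndimage.uniform_filter(a * b, (patch_size, patch_size), mode="constant")
    cov = mean_ab - mean_a * mean_b

    sl = (slice(r0, r1), slice(c0, c1))
    va, vb, cv = var_a[sl], var_b[sl], cov[sl]
    scale = max(float(va.max(initial=0.0)), float(vb.max(initial=0.0)), 1.0)
    eps = 1e-12 * scale
    ok = (va > eps) & (vb > eps)
    ncc = np.zeros_like(cv)
    ncc[ok] = cv[ok] / np.sqrt(va[ok] * vb[ok])
    np.clip(ncc, -1.0, 1.0, out=ncc)
    weight = np.where(vb > eps, vb, 0.0)
    wsum = weight.sum()
    if wsum <= 0:
        return 0.0
    return float((weight * ncc).sum() / wsum)


def _masked_drr_similarity(
    volume: AttenuationVolume,
    pose: RigidTransform,
    radiographs: RadiographPair,
    mask: ROIMask,
    plane: Plane,
    cfg: RegistrationConfig,
) -> float:
    """LNCC between the DRR and the radiograph inside one plane's mask.

    Only the mask rectangle (expanded by the patch half-width for
    neighborhood context) is rendered.
    """
    geom = radiographs.geometry
    k = cfg.patch_size // 2
    mask = mask.clipped(geom.image_shape(plane))
    shape = geom.image_shape(plane)
    er0, ec0 = max(mask.r0 - k, 0), max(mask.c0 - k, 0)
    er1, ec1 = min(mask.r1 + k, shape[0]), min(mask.c1 + k, shape[1])
    drr = render_drr(volume, pose, geom, plane, step=cfg.drr_step, roi=(er0, ec0, er1, ec1))
    fixed = radiographs.image(plane)[er0:er1, ec0:ec1]
    inner = ROIMask(mask.r0 - er0, mask.c0 - ec0, mask.r1 - er0, mask.c1 - ec0)
    return lncc_similarity(drr, fixed, inner, cfg.patch_size)


def registration_cost(
    pose_params: np.ndarray,
    volume: AttenuationVolume,
    radiographs: RadiographPair,
    masks: tuple[ROIMask, ROIMask],
    cfg: RegistrationConfig,
    center: np.ndarray = (0.0, 0.0, 0.0),
    base_pose: RigidTransform | None = None,
) -> float:
    """Negated sum of the two masked LNCC scores at the given pose parameters.

    ``pose_params`` parameterize a correction about ``center`` applied on top
    of ``base_pose`` (identity if omitted); minimum possible value is -2.0
    (both planes in perfect correlation).
    """
    delta = pose_to_transform(pose_params, center)
    pose = delta @ base_pose if base_pose is not None else delta
    total = 0.0
    for plane, mask in zip(("frontal", "lateral"), masks):
        total += _masked_drr_similarity(volume, pose, radiographs, mask, plane, cfg)
    return -total


def register_bone(
    volume: AttenuationVolume,
    radiographs: RadiographPair,
    arrow: ArrowAnnotation | None,
    masks: tuple[ROIMask, ROIMask],
    cfg: RegistrationConfig | None = None,
    initial_pose: RigidTransform | None = None,
) -> RegistrationResult:
    """Register one bone's CT to the biplanar pair.

    The pose is initialized from the arrow annotations (or from
    ``initial_pose`` when given — the manual-restart workflow re-invokes with
    an adjusted pose), then refined by bound-constrained derivative-free
    optimization of the summed LNCC within ``cfg`` bounds. Deterministic for
    identical inputs.
    """
    if cfg is None:
        cfg = RegistrationConfig()
    if initial_pose is None:
        if arrow is None:
            raise ValueError("either an arrow annotation or an initial pose is required")
        initial_pose = initialize_pose(arrow, radiographs.geometry)
    # rotation center: the annotated bone midpoint mapped into the world frame
    if arrow is not None:
        ct_mid = (arrow.ct_start + arrow.ct_end) / 2.0
    else:
        lo, hi = volume.world_bounds()
        ct_mid = (lo + hi) / 2.0
    center = initial_pose.apply(ct_mid)

    n_eval = 0

    def objective(p: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        return registration_cost(p, volume, radiographs, masks, cfg, center, initial_pose)

    br, bt = cfg.bounds_rotation, cfg.bounds_translation
    bounds = [(-br, br)] * 3 + [(-bt, bt)] * 3
    res = optimize.minimize(
        objective,
        x0=np.zeros(6),
        method="Powell",
        bounds=bounds,
        options={
            "xtol": cfg.xtol,
            "ftol": cfg.ftol,
            "maxfev": cfg.max_evaluations,
        },
    )
    params = np.asarray(res.x, dtype=float)
    at_bound = bool(np.any(np.abs(np.abs(params) - np.array([br] * 3 + [bt] * 3)) < 1e-9))
    message = res.message + (" [bound saturated]" if at_bound else "")
    transform = pose_to_transform(params, center) @ initial_pose
    return RegistrationResult(
        transform=transform,
        params=params,
        cost=float(res.fun),
        n_evaluations=n_eval,
        converged=bool(res.success) and not at_bound,
        message=message,
        center=center,
    )
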