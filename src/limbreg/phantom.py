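"""Parametric digital leg phantom and simulated biplanar acquisitions.

The phantom plays the role of a physical validation phantom (a plastic full
leg rigidly mounted in the scanner, each bone carrying six 3 mm radiopaque
spherical fiducials): it provides a CT volume, per-segment surface meshes,
fiducial markers, measurement landmarks and analytically known alignment
angles, plus simulated frontal/lateral radiographs at a known rigid pose per
bone. Everything the clinical pipeline consumes can therefore be generated
with known ground truth.

Geometry is deliberately schematic (spheres, capsules, cylinders): the femur
is a head sphere + shaft capsule + two condyle spheres, the tibia a plateau
disk + shaft cylinder with a flat distal face, plus fibula, patella and talus.
The frontal-plane deformity is constructed exactly: the knee is displaced
laterally until the hip-knee-ankle deviation equals the requested MA, and the
plateau plane is tilted by the requested JLCA in the lateral-opening sense.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq
from skimage import measure as _skmeasure

from .drr import CTVolume, RadiographPair, hu_to_attenuation, render_drr
from .geometry import EOSGeometry, project_points
from .measurements import BoneMesh
from .transforms import RigidTransform

__all__ = ["PhantomSpec", "PhantomTruth", "build_phantom", "simulate_eos_pair", "phantom_geometry"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the digital leg phantom (lengths in mm, angles degrees).

    Defaults describe a desk-scale leg (350 mm hip-to-ankle) voxelized at
    1.5 mm — coarser than clinical CT (0.5-1 mm slices) but fine enough for
    sub-voxel surface meshes thanks to anti-aliased voxelization. ``target_ma``
    is varus-positive, ``target_jlca`` lateral-opening-positive.
    """

    spacing: float = 1.5
    leg_length: float = 350.0
    side: str = "right"
    target_ma: float = 5.0
    target_jlca: float = 3.0
    shaft_radius_femur: float = 11.0
    shaft_radius_tibia: float = 9.0
    head_radius: float = 15.0
    condyle_radius: float = 14.0
    condyle_separation: float = 36.0
    plateau_radius: float = 22.0
    markers_per_bone: int = 6
    marker_diameter: float = 3.0
    hu_bone: float = 1200.0
    hu_marker: float = 3000.0
    hu_soft: float = 40.0
    hu_air: float = -1000.0
    soft_margin: float = 5.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.marker_diameter < 2 * self.spacing:
            raise ValueError(
                "marker diameter must be at least two voxels for detectability"
            )
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.condyle_separation <= 2 * self.spacing:
            raise ValueError("condyle spheres overlap completely")


@dataclass
class PhantomTruth:
    """Everything known exactly about a built phantom."""

    spec: PhantomSpec
    volume: CTVolume                      # composite CT, phantom (CT) frame
    segment_volumes: dict                 # group label -> CTVolume (additive)
    meshes: dict                          # segment label -> BoneMesh
    marker_labels: list
    marker_centers: np.ndarray            # (N, 3), CT frame
    landmarks: dict                       # measurement landmark picks, CT frame
    arrows_ct: dict                       # bone -> (start, end) CT points
    ma: float                             # constructed ground-truth MA, degrees
    jlca: float                           # constructed ground-truth JLCA, degrees
    joint_centers: dict                   # hjc/kjc/ajc used in the construction


# ---------------------------------------------------------------------------
# signed-distance primitives (vectorized over broadcastable X, Y, Z grids)
# ---------------------------------------------------------------------------

def _sd_sphere(x, y, z, c, r):
    return np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) - r


def _sd_capsule(x, y, z, a, b, r):
    ab = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    len2 = ab @ ab
    px, py, pz = x - a[0], y - a[1], z - a[2]
    t = np.clip((px * ab[0] + py * ab[1] + pz * ab[2]) / len2, 0.0, 1.0)
    dx = px - t * ab[0]
    dy = py - t * ab[1]
    dz = pz - t * ab[2]
    return np.sqrt(dx * dx + dy * dy + dz * dz) - r


def _sd_cylinder(x, y, z, base, axis, length, r):
    """Finite cylinder with flat caps; ``axis`` must be unit length."""
    px, py, pz = x - base[0], y - base[1], z - base[2]
    t = px * axis[0] + py * axis[1] + pz * axis[2]
    dx = px - t * axis[0]
    dy = py - t * axis[1]
    dz = pz - t * axis[2]
    radial = np.sqrt(dx * dx + dy * dy + dz * dz) - r
    axial = np.maximum(-t, t - length)
    # exact outside both; max() elsewhere — fine for iso-surfacing
    outside = np.sqrt(np.maximum(radial, 0.0) ** 2 + np.maximum(axial, 0.0) ** 2)
    inside = np.minimum(np.maximum(radial, axial), 0.0)
    return outside + inside


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def _solve_knee_offset(target_ma: float, l_prox: float, l_dist: float,
                       lat_sign: float) -> float:
    """Frontal knee offset producing the requested hip-knee-ankle deviation.

    A varus (positive) MA corresponds to a laterally displaced knee; the
    magnitude solves atan(|x|/L1) + atan(|x|/L2) = |MA|.
    """
    mag = abs(target_ma)
    if mag < 1e-12:
        return 0.0

    def dev(xm):
        return np.degrees(np.arctan(xm / l_prox) + np.arctan(xm / l_dist)) - mag

    xm = brentq(dev, 0.0, min(l_prox, l_dist) * 0.9)
    return lat_sign * np.sign(target_ma) * xm


def _frame_layout(spec: PhantomSpec) -> dict:
    """All analytic geometry of the phantom, CT frame (x left, y post, z sup)."""
    z_ankle = 60.0
    z_hip = z_ankle + spec.leg_length
    z_knee = z_ankle + 0.486 * spec.leg_length  # plateau height
    lat = 1.0 if spec.side == "left" else -1.0
    xk = _solve_knee_offset(spec.target_ma, z_hip - z_knee, z_knee - z_ankle, lat)

    hjc = np.array([0.0, 0.0, z_hip])
    ajc = np.array([0.0, 0.0, z_ankle])
    kjc = np.array([xk, 0.0, z_knee])

    tau = np.radians(spec.target_jlca)
    plateau_normal = _unit([lat * np.sin(tau), 0.0, np.cos(tau)])
    # in-plane frontal trace (zero y-component), and the orthogonal in-plane dir
    trace = _unit([plateau_normal[2], 0.0, -plateau_normal[0]])
    inplane2 = np.cross(plateau_normal, trace)

    condyle_z = z_knee + 4.0
    c_med = kjc + np.array([+spec.condyle_separation / 2, 0, condyle_z - z_knee])
    c_lat = kjc + np.array([-spec.condyle_separation / 2, 0, condyle_z - z_knee])

    tibia_axis = _unit(kjc - np.array([0, 0, 8.0]) - ajc)  # distal->proximal
    return {
        "z_ankle": z_ankle, "z_hip": z_hip, "z_knee": z_knee,
        "lat": lat, "xk": xk,
        "hjc": hjc, "ajc": ajc, "kjc": kjc,
        "plateau_normal": plateau_normal, "trace": trace, "inplane2": inplane2,
        "condyles": (c_med, c_lat),
        "tibia_axis": tibia_axis,
    }


def _segment_sdfs(spec: PhantomSpec, lay: dict) -> dict:
    """Per-segment callables sdf(X, Y, Z) -> signed distance (mm)."""
    hjc, ajc, kjc = lay["hjc"], lay["ajc"], lay["kjc"]
    n, lat = lay["plateau_normal"], lay["lat"]
    c_med, c_lat = lay["condyles"]
    t_axis = lay["tibia_axis"]
    plateau_thick = 8.0
    p0 = kjc  # plateau top-face center
    tibia_base = ajc
    tibia_len = np.linalg.norm((p0 - plateau_thick * n) - ajc)

    def femur(x, y, z):
        shaft = _sd_capsule(x, y, z, hjc, kjc + [0, 0, spec.condyle_radius], spec.shaft_radius_femur)
        head = _sd_sphere(x, y, z, hjc, spec.head_radius)
        cm = _sd_sphere(x, y, z, c_med, spec.condyle_radius)
        cl = _sd_sphere(x, y, z, c_lat, spec.condyle_radius)
        return np.minimum(np.minimum(shaft, head), np.minimum(cm, cl))

    def tibia(x, y, z):
        # plateau disk: cylinder along the plateau normal, top face through p0
        plate = _sd_cylinder(x, y, z, p0 - plateau_thick * n, n, plateau_thick,
                             spec.plateau_radius)
        shaft = _sd_cylinder(x, y, z, tibia_base, t_axis, tibia_len,
                             spec.shaft_radius_tibia)
        return np.minimum(plate, shaft)

    # fibula head stays below the joint line, clear of the femoral condyles
    fib_base = ajc + np.array([lat * 26.0, 0.0, 20.0])
    fib_top = kjc + np.array([lat * 26.0, 0.0, -26.0])

    def fibula(x, y, z):
        return _sd_capsule(x, y, z, fib_base, fib_top, 4.5)

    pat_center = kjc + np.array([0.0, -36.0, 10.0])

    def patella(x, y, z):
        return _sd_cylinder(x, y, z, pat_center, (0.0, 1.0, 0.0), 8.0, 11.0)

    talus_top = ajc - 2.0 * t_axis

    def talus(x, y, z):
        return _sd_cylinder(x, y, z, talus_top - 16.0 * t_axis, t_axis, 16.0, 18.0)

    return {"femur": femur, "tibia": tibia, "fibula": fibula,
            "patella": patella, "talus": talus}


def _marker_positions(spec: PhantomSpec, lay: dict) -> tuple[list, np.ndarray]:
    """Fiducial centers on the bone shaft surfaces, deterministic layout."""
    labels, centers = [], []
    hjc, ajc, kjc = lay["hjc"], lay["ajc"], lay["kjc"]
    shaft_specs = {
        "fem": (hjc, kjc + [0, 0, spec.condyle_radius], spec.shaft_radius_femur),
        "tib": (ajc, kjc - [0, 0, 8.0], spec.shaft_radius_tibia),
    }
    for bone, (a, b, r) in shaft_specs.items():
        axis = _unit(np.asarray(b) - np.asarray(a))
        ref = _unit(np.cross(axis, [0.0, 0.0, 1.0])
                    if abs(axis[2]) < 0.9 else np.cross(axis, [1.0, 0.0, 0.0]))
        ref2 = np.cross(axis, ref)
        for i in range(spec.markers_per_bone):
            frac = 0.22 + 0.56 * i / max(spec.markers_per_bone - 1, 1)
            azim = i * 2.399963  # golden angle: spreads markers round the shaft
            radial = np.cos(azim) * ref + np.sin(azim) * ref2
            center = np.asarray(a) + frac * (np.asarray(b) - np.asarray(a)) + r * radial
            labels.append(f"{bone}{i + 1}")
            centers.append(center)
    return labels, np.asarray(centers)


def _occupancy(sdf_values: np.ndarray, spacing: float) -> np.ndarray:
    """Anti-aliased occupancy: linear ramp across one voxel at the surface."""
    return np.clip(0.5 - sdf_values / spacing, 0.0, 1.0)


def build_phantom(spec: PhantomSpec | None = None) -> PhantomTruth:
    """Voxelize the phantom and extract meshes, markers and landmarks.

    The CT volume is composed with anti-aliased (partial-volume) voxelization
    so that marching cubes recovers each surface with sub-voxel accuracy;
    segment meshes are extracted from the analytic signed-distance fields at
    the zero level, which coincides with the mid-ramp HU iso-level of the
    volume. Deterministic for a given spec.
    """
    spec = spec or PhantomSpec()
    lay = _frame_layout(spec)
    sdfs = _segment_sdfs(spec, lay)
    marker_labels, marker_centers = _marker_positions(spec, lay)

    # grid extents: bounding spheres of every solid, plus soft-tissue margin
    pad = spec.soft_margin + 4.0
    c_med, c_lat = lay["condyles"]
    covers = [
        (lay["hjc"], spec.head_radius),
        (lay["kjc"], spec.plateau_radius + 3.0),
        (c_med, spec.condyle_radius),
        (c_lat, spec.condyle_radius),
        (lay["ajc"], 22.0),  # talus + distal tibia
        (lay["ajc"] + [lay["lat"] * 26.0, 0.0, 20.0], 6.0),   # fibula ends
        (lay["kjc"] + [lay["lat"] * 26.0, 0.0, -26.0], 6.0),
        (lay["kjc"] + [0.0, -36.0, 10.0], 13.0),              # patella
    ]
    centers = np.array([c for c, _ in covers])
    radii = np.array([r for _, r in covers])
    lo = (centers - radii[:, None]).min(axis=0) - pad
    hi = (centers + radii[:, None]).max(axis=0) + pad
    sp = spec.spacing
    shape = np.ceil((hi - lo) / sp).astype(int) + 1
    xs = lo[0] + sp * np.arange(shape[0])
    ys = lo[1] + sp * np.arange(shape[1])
    zs = lo[2] + sp * np.arange(shape[2])
    gx = xs[:, None, None]
    gy = ys[None, :, None]
    gz = zs[None, None, :]

    groups = {"femur_group": ["femur", "patella"],
              "tibia_group": ["tibia", "fibula", "talus"]}
    marker_owner = {"fem": "femur_group", "tib": "tibia_group"}

    seg_sdf_grids = {name: f(gx, gy, gz).astype(np.float32) for name, f in sdfs.items()}

    segment_volumes = {}
    for group, members in groups.items():
        # compose tissue classes in priority order (soft, then bone, then
        # markers), each as the union (min-SDF) over the group's segments,
        # so one bone's soft sheath never overwrites another's cortex
        bone_sd = np.minimum.reduce([seg_sdf_grids[name] for name in members])
        hu = np.full(shape, spec.hu_air, dtype=np.float32)
        for level_sd, level_hu in ((bone_sd - spec.soft_margin, spec.hu_soft),
                                   (bone_sd, spec.hu_bone)):
            alpha = _occupancy(level_sd, sp)
            hu += alpha * (level_hu - hu)
        for label, center in zip(marker_labels, marker_centers):
            if marker_owner[label[:3]] != group:
                continue
            sd = _sd_sphere(gx, gy, gz, center, spec.marker_diameter / 2).astype(np.float32)
            alpha = _occupancy(sd, sp)
            hu += alpha * (spec.hu_marker - hu)
        segment_volumes[group] = CTVolume(data=hu, spacing=[sp] * 3, origin=lo)

    # composite: attenuation-additive combination of the disjoint groups
    comp = np.full(shape, spec.hu_air, dtype=np.float32)
    for vol in segment_volumes.values():
        comp = comp + (vol.data - spec.hu_air)
    volume = CTVolume(data=comp, spacing=[sp] * 3, origin=lo)

    meshes = {}
    for name, sd in seg_sdf_grids.items():
        verts, faces, _, _ = _skmeasure.marching_cubes(sd, level=0.0, spacing=(sp, sp, sp))
        verts = verts + lo
        tri = verts[faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        meshes[name] = BoneMesh(verts, faces[areas > 1e-10], label=name)

    landmarks = _landmarks(spec, lay)
    arrows_ct = {
        "femur": (np.array([lay["xk"], 0.0, lay["z_knee"] + 4.0]), lay["hjc"].copy()),
        "tibia": (lay["ajc"].copy(), lay["kjc"].copy()),
    }
    return PhantomTruth(
        spec=spec,
        volume=volume,
        segment_volumes=segment_volumes,
        meshes=meshes,
        marker_labels=marker_labels,
        marker_centers=marker_centers,
        landmarks=landmarks,
        arrows_ct=arrows_ct,
        ma=spec.target_ma,
        jlca=spec.target_jlca,
        joint_centers={"hjc": lay["hjc"], "kjc": lay["kjc"], "ajc": lay["ajc"]},
    )


def _landmarks(spec: PhantomSpec, lay: dict) -> dict:
    """Exact landmark picks a user would make, derived from the construction."""
    n, trace, inplane2 = lay["plateau_normal"], lay["trace"], lay["inplane2"]
    kjc, hjc = lay["kjc"], lay["hjc"]
    # femoral head points: spiral over the upper hemisphere of the head sphere
    idx = np.arange(24)
    phi = np.arccos(1 - idx / 24.0)  # polar angle within the upper hemisphere
    theta = idx * 2.399963
    head_pts = hjc + spec.head_radius * np.column_stack([
        np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)
    ])
    eminences = np.array([kjc + 6.0 * trace, kjc - 6.0 * trace])
    rhomb = []
    for r_frac, k in ((0.65, 0), (0.65, 1), (0.65, 2), (0.65, 3),
                      (0.35, 0), (0.35, 1), (0.35, 2), (0.35, 3)):
        ang = np.pi / 4 + k * np.pi / 2
        rhomb.append(kjc + r_frac * spec.plateau_radius *
                     (np.cos(ang) * trace + np.sin(ang) * inplane2))
    pat_face_center = kjc + np.array([0.0, -36.0, 10.0])  # anterior face, y = -36
    ring = np.array([[np.cos(a), 0.0, np.sin(a)] for a in np.linspace(0, 2 * np.pi, 5)[:-1]])
    patella_pts = pat_face_center + 7.0 * ring
    epicondyles = np.array([
        kjc + [+spec.condyle_separation / 2 + 2.0, 0.0, 6.0],
        kjc + [-spec.condyle_separation / 2 - 2.0, 0.0, 6.0],
    ])
    return {
        "femoral_head_points": head_pts,
        "eminences": eminences,
        "plateau_points": np.asarray(rhomb),
        "patella_points": patella_pts,
        "epicondyles": epicondyles,
    }


# ---------------------------------------------------------------------------
# simulated acquisition
# ---------------------------------------------------------------------------

def phantom_geometry(spec: PhantomSpec | None = None) -> EOSGeometry:
    """A fan-beam geometry sized for the phantom.

    Source distances are those of the reference device (918 mm); the pixel
    pitch is coarsened to 2 mm vertically / 1 mm horizontally so full images
    stay small.
    """
    spec = spec or PhantomSpec()
    return EOSGeometry(
        z0=max(500.0, spec.leg_length + 150.0),
        pitch_z=2.0,
        pitch_h_frontal=1.0,
        pitch_h_lateral=1.0,
        n_rows=int(np.ceil(max(500.0, spec.leg_length + 150.0) / 2.0)),
        n_cols_frontal=160,
        n_cols_lateral=160,
    )


def _project_bbox_mask(points: np.ndarray, geom: EOSGeometry, plane: str,
                       margin: int = 5) -> tuple[int, int, int, int]:
    hv = project_points(points, geom, plane)
    shape = geom.image_shape(plane)
    r0 = int(np.floor(hv[:, 1].min())) - margin
    r1 = int(np.ceil(hv[:, 1].max())) + margin + 1
    c0 = int(np.floor(hv[:, 0].min())) - margin
    c1 = int(np.ceil(hv[:, 0].max())) + margin + 1
    return (max(r0, 0), max(c0, 0), min(r1, shape[0]), min(c1, shape[1]))


def simulate_eos_pair(
    truth: PhantomTruth,
    pose_femur: RigidTransform,
    pose_tibia: RigidTransform,
    geom: EOSGeometry | None = None,
    noise_sigma: float | None = None,
    seed: int | None = None,
    step: float | None = None,
) -> tuple[RadiographPair, dict]:
    """Render the posed phantom into a frontal/lateral radiograph pair.

    The femur group (femur + patella) and tibia group (tibia, fibula, talus)
    are posed independently and composited additively — a schematic stand-in
    for a posture change that ignores soft-tissue deformation. Returns the
    image pair plus the exact 2D annotations a user would supply: per-plane
    marker projections, arrow annotations and rectangular bone masks.
    Optional additive Gaussian noise (sigma in line-integral units) is drawn
    from the spec seed unless overridden.
    """
    geom = geom or phantom_geometry(truth.spec)
    if noise_sigma is None:
        noise_sigma = truth.spec.noise_sigma
    if seed is None:
        seed = truth.spec.seed
    poses = {"femur_group": pose_femur, "tibia_group": pose_tibia}

    images = {}
    common = np.allclose(pose_femur.matrix, pose_tibia.matrix)
    for plane in ("frontal", "lateral"):
        if common:
            mu = hu_to_attenuation(truth.volume)
            img = render_drr(mu, pose_femur, geom, plane, step=step)
        else:
            img = np.zeros(geom.image_shape(plane))
            for group, vol in truth.segment_volumes.items():
                img += render_drr(hu_to_attenuation(vol), poses[group], geom, plane, step=step)
        images[plane] = img
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        for plane in images:
            images[plane] = images[plane] + noise_sigma * rng.standard_normal(images[plane].shape)
    pair = RadiographPair(frontal=images["frontal"], lateral=images["lateral"], geometry=geom)

    bone_group = {"femur": "femur_group", "tibia": "tibia_group"}
    marker_group = {"fem": "femur_group", "tib": "tibia_group"}
    annotations: dict = {"markers": {"frontal": {}, "lateral": {}},
                         "arrows": {}, "masks": {}}
    for label, center in zip(truth.marker_labels, truth.marker_centers):
        posed = poses[marker_group[label[:3]]].apply(center)
        for plane in ("frontal", "lateral"):
            h, v = project_points(posed[None, :], geom, plane)[0]
            annotations["markers"][plane][label] = [float(h), float(v)]
    for bone, (start, end) in truth.arrows_ct.items():
        pose = poses[bone_group[bone]]
        entry = {"ct": [start.tolist(), end.tolist()]}
        for plane in ("frontal", "lateral"):
            hv = project_points(pose.apply(np.vstack([start, end])), geom, plane)
            entry[plane] = hv.tolist()
        annotations["arrows"][bone] = entry
    for bone in ("femur", "tibia"):
        pose = poses[bone_group[bone]]
        verts = pose.apply(truth.meshes[bone].vertices[::7])
        annotations["masks"][bone] = {
            plane: list(_project_bbox_mask(verts, geom, plane))
            for plane in ("frontal", "lateral")
        }
    return pair, annotations


def export_case(truth: PhantomTruth, pair: RadiographPair, annotations: dict,
                out_dir, poses: dict | None = None) -> None:
    """Write a complete self-contained case to ``out_dir``.

    Emits the CT volume (NIfTI), meshes (STL), geometry (YAML), images
    (TIFF), annotations/markers (JSON/CSV) and a truth file (JSON).
    """
    import csv
    from pathlib import Path

    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.volume.to_nifti(out / "ct.nii.gz")
    (out / "meshes").mkdir(exist_ok=True)
    for name, mesh in truth.meshes.items():
        mesh.to_stl(out / "meshes" / f"{name}.stl")
    pair.geometry.to_yaml(out / "geometry.yaml")
    tifffile.imwrite(out / "frontal.tif", pair.frontal.astype(np.float32))
    tifffile.imwrite(out / "lateral.tif", pair.lateral.astype(np.float32))
    with open(out / "annotations.json", "w") as fh:
        json.dump(annotations, fh, indent=1)
    with open(out / "landmarks.json", "w") as fh:
        json.dump({k: np.asarray(v).tolist() for k, v in truth.landmarks.items()}, fh, indent=1)
    with open(out / "markers_ct.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "x", "y", "z"])
        for label, c in zip(truth.marker_labels, truth.marker_centers):
            w.writerow([label, f"{c[0]:.6f}", f"{c[1]:.6f}", f"{c[2]:.6f}"])
    truth_info = {
        "spec": asdict(truth.spec),
        "ma": truth.ma,
        "jlca": truth.jlca,
        "joint_centers": {k: np.asarray(v).tolist() for k, v in truth.joint_centers.items()},
    }
    if poses is not None:
        truth_info["poses"] = {k: np.asarray(v.matrix).tolist() for k, v in poses.items()}
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_info, fh, indent=1)
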