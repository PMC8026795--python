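"""3D lower-limb alignment measurements: mechanical axis (MA) and joint line
convergence angle (JLCA).

Workflow: estimate the hip, knee and ankle joint centers (HJC/KJC/AJC) from
bone surface meshes and user-picked landmark points, reorient everything into
an anatomical frame (mechanical axis HJC-AJC along +y = superior, patella
facing +z = anterior), then measure frontal-plane angles.

Sign conventions: varus MA positive, laterally opened JLCA positive; the
``side`` argument ("left"/"right") orients medial/lateral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .transforms import RigidTransform

__all__ = [
    "BoneMesh",
    "JointCenters",
    "MeasurementResult",
    "fit_sphere",
    "fit_plane",
    "compute_kjc",
    "compute_ajc",
    "align_anatomical",
    "compute_ma",
    "compute_fct",
    "compute_jlca",
    "measure_alignment",
    "point_mesh_distance",
]

SEGMENT_LABELS = ("femur", "tibia", "fibula", "patella", "talus")


@dataclass
class BoneMesh:
    """A triangular surface mesh of one anatomical segment, mm."""

    vertices: np.ndarray
    faces: np.ndarray
    label: str = "bone"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3 or len(self.vertices) < 4:
            raise ValueError("mesh needs at least 4 vertices of dimension 3")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (M, 3) vertex indices")
        tri = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        if np.any(areas <= 0):
            raise ValueError("mesh contains degenerate triangles")

    def transformed(self, t: RigidTransform) -> "BoneMesh":
        return BoneMesh(t.apply(self.vertices), self.faces.copy(), self.label)

    # -- STL I/O via trimesh --------------------------------------------
    @classmethod
    def from_stl(cls, path, label: str = "bone") -> "BoneMesh":
        import trimesh

        m = trimesh.load_mesh(str(path), process=True)
        return cls(np.asarray(m.vertices), np.asarray(m.faces), label)

    def to_stl(self, path) -> None:
        import trimesh

        trimesh.Trimesh(self.vertices, self.faces, process=False).export(str(path))


@dataclass
class JointCenters:
    hjc: np.ndarray
    kjc: np.ndarray
    ajc: np.ndarray


@dataclass
class MeasurementResult:
    """Alignment angles and the geometric objects they came from."""

    ma: float                       # degrees, varus positive
    jlca: float                     # degrees, laterally opened positive
    fct_point: np.ndarray           # femoral condyle tangent, anatomical frame
    fct_direction: np.ndarray
    tct_point: np.ndarray           # tibial plateau plane
    tct_normal: np.ndarray
    joint_centers: JointCenters
    alignment: RigidTransform       # input frame -> anatomical frame
    ajc_point_count: int = 0


# ---------------------------------------------------------------------------
# primitive fits
# ---------------------------------------------------------------------------

def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere fit.

    Solves ``|p|^2 = 2 p.c + (r^2 - |c|^2)`` in the least-squares sense.
    Returns ``(center, radius, rms_residual)``; the residual is the RMS of
    radial distances minus the fitted radius.

    Raises for < 4 points or (near-)coplanar configurations, for which the
    linear system is singular.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 4:
        raise ValueError("need at least 4 points in 3D")
    a = np.column_stack([2 * p, np.ones(len(p))])
    b = (p * p).sum(axis=1)
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[-1] < 1e-8 * sv[0]:
        raise ValueError("points are coplanar/ill-conditioned for a sphere fit")
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("degenerate sphere fit (non-positive radius)")
    radius = float(np.sqrt(r2))
    rms = float(np.sqrt(np.mean((np.linalg.norm(p - center, axis=1) - radius) ** 2)))
    return center, radius, rms


def fit_plane(points: np.ndarray, orient=None) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares plane through >= 3 non-collinear points.

    Minimizes orthogonal distances (smallest principal component of the
    centered points). Returns ``(point, unit_normal, rms_residual)``; the
    normal is flipped to have positive dot product with ``orient``
    (default +y, the superior direction of the anatomical frame).
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 3:
        raise ValueError("need at least 3 points in 3D")
    centroid = p.mean(axis=0)
    q = p - centroid
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("points are collinear: plane is undetermined")
    normal = vt[2]
    if orient is None:
        orient = np.array([0.0, 1.0, 0.0])
    if np.dot(normal, orient) < 0:
        normal = -normal
    rms = float(np.sqrt(np.mean((q @ normal) ** 2)))
    return centroid, normal / np.linalg.norm(normal), rms


# ---------------------------------------------------------------------------
# joint centers
# ---------------------------------------------------------------------------

def compute_kjc(medial_eminence, lateral_eminence) -> np.ndarray:
    """Knee joint center: midpoint of the intercondylar eminences."""
    a = np.asarray(medial_eminence, dtype=float)
    b = np.asarray(lateral_eminence, dtype=float)
    if np.allclose(a, b):
        raise ValueError("eminence points coincide")
    return (a + b) / 2.0


def point_mesh_distance(points: np.ndarray, mesh: BoneMesh) -> np.ndarray:
    """Unsigned distance from each point to the surface of ``mesh``.

    Exact point-to-triangle distances, restricted to candidate triangles
    found with a KD-tree over triangle centroids (shortlist radius covers the
    largest triangle, so the result is exact).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.vertices[mesh.faces]
    centroids = tri.mean(axis=1)
    # max distance from a centroid to its triangle's farthest vertex
    slack = np.linalg.norm(tri - centroids[:, None, :], axis=2).max()
    tree = cKDTree(centroids)
    d_cent, _ = tree.query(pts)
    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        idx = tree.query_ball_point(p, d_cent[i] + slack + 1e-9)
        out[i] = _point_triangles_distance(p, tri[idx]).min()
    return out


def _point_triangles_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distance from point p to each triangle in (M, 3, 3), vectorized."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = (ab * ap).sum(1)
    d2 = (ac * ap).sum(1)
    bp = p - b
    d3 = (ab * bp).sum(1)
    d4 = (ac * bp).sum(1)
    cp = p - c
    d5 = (ab * cp).sum(1)
    d6 = (ac * cp).sum(1)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(np.abs(denom) > 0, vb / denom, 0.0)
        w = np.where(np.abs(denom) > 0, vc / denom, 0.0)
    closest = a + v[:, None] * ab + w[:, None] * ac
    # vertex regions
    closest = np.where(((d1 <= 0) & (d2 <= 0))[:, None], a, closest)
    closest = np.where(((d3 >= 0) & (d4 <= d3))[:, None], b, closest)
    closest = np.where(((d6 >= 0) & (d5 <= d6))[:, None], c, closest)
    # edge regions
    ab_t = np.clip(np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0), 0.0), 0, 1)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest = np.where(on_ab[:, None], a + ab_t[:, None] * ab, closest)
    ac_t = np.clip(np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0), 0.0), 0, 1)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest = np.where(on_ac[:, None], a + ac_t[:, None] * ac, closest)
    denom_bc = (d4 - d3) + (d5 - d6)
    bc_t = np.clip(np.where(denom_bc != 0, (d4 - d3) / np.where(denom_bc != 0, denom_bc, 1.0), 0.0), 0, 1)
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    closest = np.where(on_bc[:, None], b + bc_t[:, None] * (c - b), closest)
    return np.linalg.norm(p - closest, axis=1)


def compute_ajc(
    tibia: BoneMesh,
    fibula: BoneMesh | None,
    talus: BoneMesh,
    threshold: float = 3.0,
) -> tuple[np.ndarray, int]:
    """Ankle joint center: centroid of the distal articular surface.

    Tibial (and fibular, if provided) vertices whose closest-point distance
    to the talus surface is below ``threshold`` (mm) form the articular
    surface; the AJC is their centroid. The selected-vertex count is returned
    so the threshold can be adjusted until the whole surface is captured, the
    visual workflow used with clinical data.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    verts = [tibia.vertices] if fibula is None else [tibia.vertices, fibula.vertices]
    pts = np.vstack(verts)
    # cheap bound first: surface distance differs from nearest-vertex distance
    # by at most the largest talus edge length
    tree = cKDTree(talus.vertices)
    d_vert, _ = tree.query(pts)
    edges = talus.vertices[talus.faces[:, [0, 1, 2]]]
    max_edge = np.linalg.norm(np.diff(edges[:, [0, 1, 2, 0]], axis=1), axis=2).max()
    candidates = d_vert - max_edge < threshold
    selected_mask = np.zeros(len(pts), dtype=bool)
    if np.any(candidates):
        d_exact = point_mesh_distance(pts[candidates], talus)
        selected_mask[np.flatnonzero(candidates)[d_exact < threshold]] = True
    selected = pts[selected_mask]
    if len(selected) == 0:
        raise ValueError(f"no vertices within threshold {threshold} mm of the talus")
    return selected.mean(axis=0), int(len(selected))


# ---------------------------------------------------------------------------
# anatomical frame and angles
# ---------------------------------------------------------------------------

def align_anatomical(hjc, ajc, patella_points) -> RigidTransform:
    """Rigid transform into the anatomical measurement frame.

    The mechanical leg axis AJC -> HJC is placed along +y (superior); the
    limb is then rotated about it until the best-fit plane of the anterior
    patellar surface points faces +z (anterior). The AJC maps to the origin.
    The anterior sense is resolved anatomically: the patella lies in front of
    the leg axis, so +z points from the axis toward the patella centroid.
    """
    hjc = np.asarray(hjc, dtype=float)
    ajc = np.asarray(ajc, dtype=float)
    axis = hjc - ajc
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("HJC and AJC coincide")
    y = axis / norm
    _, normal, _ = fit_plane(patella_points, orient=None)
    centroid = np.asarray(patella_points, dtype=float).mean(axis=0)
    offset = centroid - ajc
    offset_perp = offset - (offset @ y) * y
    z_raw = normal - (normal @ y) * y
    if np.linalg.norm(z_raw) < 1e-9:
        raise ValueError("patella plane normal parallel to the mechanical axis")
    if np.dot(z_raw, offset_perp) < 0:
        z_raw = -z_raw
    z = z_raw / np.linalg.norm(z_raw)
    x = np.cross(y, z)
    r = np.vstack([x, y, z])
    return RigidTransform.from_rotation_translation(r, -r @ ajc)


def _lateral_sign(side: str) -> float:
    """Sign of the lateral direction along +x (x points to the patient's left)."""
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    # right leg: lateral is the patient's right, i.e. -x; left leg: +x
    return 1.0 if side == "left" else -1.0


def compute_ma(hjc, kjc, ajc, side: str) -> float:
    """Mechanical axis angle, degrees, in the anatomical frame.

    Frontal-plane (x-y) angle between the HJC->KJC and KJC->AJC lines,
    measured as deviation from collinearity (straight leg = 0). Positive when
    the knee deviates laterally from the hip-ankle line (varus).
    """
    h = np.asarray(hjc, dtype=float)[:2]
    k = np.asarray(kjc, dtype=float)[:2]
    a = np.asarray(ajc, dtype=float)[:2]
    u = k - h
    w = a - k
    if np.linalg.norm(u) < 1e-9 or np.linalg.norm(w) < 1e-9:
        raise ValueError("joint centers coincide after frontal projection")
    cross = u[0] * w[1] - u[1] * w[0]
    angle = np.degrees(np.arctan2(cross, u @ w))
    # derived from the lateral-deviation definition: for the right leg a
    # laterally (-x) shifted knee gives positive cross
    return float(angle if side == "right" else -angle)


def compute_fct(
    femur: BoneMesh,
    cut_fraction: float = 0.15,
    epicondyles: np.ndarray | None = None,
    proximal_hint=(0.0, 1.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Femoral condyle tangent: the line through the two most-distal condyle
    points, returned as ``(point, unit_direction)``.

    The femoral longitudinal axis is the first principal component of the
    vertices (oriented proximally by ``proximal_hint``). The distal epiphysis
    is isolated by a cut perpendicular to this axis — by default at the
    most-distal ``cut_fraction`` of femoral length, or 5 mm proximal of the
    more proximal epicondyle landmark if two are given. A 2-means split along
    deterministic seeds (the two extremal epiphysis vertices along the
    mediolateral spread) separates the condyles; per condyle the three most
    distal vertices along the axis are averaged.
    """
    from sklearn.cluster import KMeans

    v = femur.vertices
    centroid = v.mean(axis=0)
    _, _, vt = np.linalg.svd(v - centroid, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, np.asarray(proximal_hint, dtype=float)) < 0:
        axis = -axis
    coord = (v - centroid) @ axis  # along-axis coordinate, proximal positive
    if epicondyles is not None:
        epi = np.atleast_2d(np.asarray(epicondyles, dtype=float))
        if epi.shape != (2, 3):
            raise ValueError("epicondyles must be two 3D landmarks")
        cut = max(((epi - centroid) @ axis)) + 5.0
        epiphysis = v[coord <= cut]
    else:
        lo, hi = coord.min(), coord.max()
        cut = lo + cut_fraction * (hi - lo)
        epiphysis = v[coord <= cut]
    if len(epiphysis) < 6:
        raise ValueError("epiphysis cut leaves too few vertices")
    # mediolateral spread direction within the epiphysis, orthogonal to axis
    e_cent = epiphysis.mean(axis=0)
    q = epiphysis - e_cent
    q -= np.outer(q @ axis, axis)
    _, _, evt = np.linalg.svd(q, full_matrices=False)
    ml = evt[0]
    ml_coord = q @ ml
    seeds = np.vstack([epiphysis[np.argmin(ml_coord)], epiphysis[np.argmax(ml_coord)]])
    km = KMeans(n_clusters=2, init=seeds, n_init=1, max_iter=100).fit(epiphysis)
    means = []
    for lab in (0, 1):
        cluster = epiphysis[km.labels_ == lab]
        if len(cluster) < 3:
            raise ValueError("condyle cluster has fewer than 3 points")
        along = (cluster - centroid) @ axis
        distal3 = cluster[np.argsort(along)[:3]]
        means.append(distal3.mean(axis=0))
    m0, m1 = means
    direction = m1 - m0
    direction /= np.linalg.norm(direction)
    return (m0 + m1) / 2.0, direction


def compute_jlca(fct_direction, tct_normal, side: str) -> float:
    """Joint line convergence angle, degrees, in the anatomical frame.

    The FCT direction and the tibial plateau plane's frontal trace
    (``n x z``) are projected to the frontal (x-y) plane; the JLCA is the
    angle between them, positive when the joint space opens laterally.
    """
    f = np.asarray(fct_direction, dtype=float)
    n = np.asarray(tct_normal, dtype=float)
    f2 = f[:2]
    t2 = np.array([n[1], -n[0]])  # frontal trace of the plane
    if np.linalg.norm(f2) < 1e-9:
        raise ValueError("FCT is purely sagittal: frontal projection degenerates")
    if np.linalg.norm(t2) < 1e-9:
        raise ValueError("plateau plane is frontal-parallel: no trace line")
    if f2[0] < 0:
        f2 = -f2
    if t2[0] < 0:
        t2 = -t2
    phi_f = np.degrees(np.arctan2(f2[1], f2[0]))
    phi_t = np.degrees(np.arctan2(t2[1], t2[0]))
    delta = phi_f - phi_t
    # lateral opening: femoral tangent rises away from the plateau on the
    # lateral side; x is lateral for the left leg, -x for the right
    return float(delta if side == "left" else -delta)


# ---------------------------------------------------------------------------
# end-to-end measurement
# ---------------------------------------------------------------------------

def measure_alignment(
    meshes: dict[str, BoneMesh],
    landmarks: dict,
    side: str = "right",
    ajc_threshold: float = 3.0,
    epicondyle_cut_fraction: float = 0.15,
) -> MeasurementResult:
    """Measure MA and JLCA from segment meshes and landmark picks.

    ``meshes`` maps segment labels (femur, tibia, fibula, patella, talus) to
    meshes in one common frame; ``landmarks`` holds the user-picked points in
    the same frame: ``femoral_head_points``, ``eminences`` (2 points),
    ``plateau_points`` (8, rhomboid layout), ``patella_points`` and
    optionally ``epicondyles``.
    """
    hjc, _, _ = fit_sphere(np.asarray(landmarks["femoral_head_points"], dtype=float))
    em = np.asarray(landmarks["eminences"], dtype=float)
    kjc = compute_kjc(em[0], em[1])
    ajc, n_sel = compute_ajc(
        meshes["tibia"], meshes.get("fibula"), meshes["talus"], ajc_threshold
    )
    align = align_anatomical(hjc, ajc, np.asarray(landmarks["patella_points"], dtype=float))

    hjc_a, kjc_a, ajc_a = align.apply(np.vstack([hjc, kjc, ajc]))
    ma = compute_ma(hjc_a, kjc_a, ajc_a, side)

    femur_a = meshes["femur"].transformed(align)
    epi = landmarks.get("epicondyles")
    if epi is not None:
        epi = align.apply(np.asarray(epi, dtype=float))
    fct_point, fct_dir = compute_fct(
        femur_a, cut_fraction=epicondyle_cut_fraction, epicondyles=epi
    )
    plateau_a = align.apply(np.asarray(landmarks["plateau_points"], dtype=float))
    tct_point, tct_normal, _ = fit_plane(plateau_a, orient=(0.0, 1.0, 0.0))
    jlca = compute_jlca(fct_dir, tct_normal, side)

    return MeasurementResult(
        ma=ma,
        jlca=jlca,
        fct_point=fct_point,
        fct_direction=fct_dir,
        tct_point=tct_point,
        tct_normal=tct_normal,
        joint_centers=JointCenters(hjc=hjc_a, kjc=kjc_a, ajc=ajc_a),
        alignment=align,
        ajc_point_count=n_sel,
    )
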