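"""Joint centers, anatomical alignment and the MA/JLCA angle conventions."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from limbreg.measurements import (BoneMesh, align_anatomical, compute_ajc,
                                  compute_fct, compute_jlca, compute_kjc,
                                  compute_ma, fit_plane, fit_sphere,
                                  measure_alignment, point_mesh_distance)
from limbreg.phantom import PhantomSpec, build_phantom
from limbreg.transforms import RigidTransform


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    r = Rotation.random(random_state=seed).as_matrix()
    return RigidTransform.from_rotation_translation(r, rng.uniform(-50, 50, 3))


class TestFitSphere:
    def test_exact_points_recovered(self):
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(20, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = np.array([1.0, 2.0, 3.0]) + 24.0 * dirs
        center, radius, rms = fit_sphere(pts)
        assert center == pytest.approx([1, 2, 3], abs=1e-9)
        assert radius == pytest.approx(24.0, abs=1e-9)
        assert rms < 1e-9

    def test_noisy_points_center_within_tolerance(self):
        rng = np.random.default_rng(12)
        dirs = rng.normal(size=(200, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = np.array([-5.0, 7.0, 2.0]) + 30.0 * dirs + rng.normal(0, 0.1, (200, 3))
        center, _, _ = fit_sphere(pts)
        assert np.linalg.norm(center - [-5, 7, 2]) < 0.05

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="coplanar|ill-conditioned"):
            fit_sphere(pts)


class TestFitPlane:
    def test_exact_plane(self):
        rng = np.random.default_rng(1)
        uv = rng.uniform(-10, 10, size=(8, 2))
        pts = np.array([3.0, 1.0, 2.0]) + np.outer(uv[:, 0], [1, 0, 0]) + np.outer(uv[:, 1], [0, 0, 1])
        point, normal, rms = fit_plane(pts)
        assert rms < 1e-9
        assert abs(normal @ [0, 1, 0]) == pytest.approx(1.0, abs=1e-12)
        assert normal[1] > 0  # oriented superiorly

    def test_noisy_plane_normal_within_half_degree(self):
        rng = np.random.default_rng(2)
        uv = rng.uniform(-20, 20, size=(100, 2))
        pts = np.outer(uv[:, 0], [1, 0, 0]) + np.outer(uv[:, 1], [0, 0, 1])
        pts = pts + rng.normal(0, 0.1, pts.shape)
        _, normal, _ = fit_plane(pts)
        angle = np.degrees(np.arccos(np.clip(abs(normal @ [0, 1, 0]), 0, 1)))
        assert angle < 0.5

    def test_equals_eigen_decomposition_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(15, 3)) * [5, 0.5, 8]
        _, normal, _ = fit_plane(pts)
        q = pts - pts.mean(axis=0)
        w, v = np.linalg.eigh(q.T @ q)
        oracle = v[:, 0]  # smallest eigenvalue
        assert abs(abs(normal @ oracle) - 1) < 1e-9

    def test_collinear_rejected(self):
        pts = np.outer(np.arange(5.0), [1, 2, 3])
        with pytest.raises(ValueError, match="collinear"):
            fit_plane(pts)


class TestKJC:
    def test_midpoint(self):
        assert compute_kjc([0, 0, 0], [10, 0, 0]) == pytest.approx([5, 0, 0])

    def test_symmetric_in_arguments(self):
        a, b = np.array([1.0, 2, 3]), np.array([-4.0, 5, 6])
        assert compute_kjc(a, b) == pytest.approx(compute_kjc(b, a))

    def test_equivariant_under_rigid_motion(self):
        t = random_rigid(9)
        a, b = np.array([1.0, 2, 3]), np.array([-4.0, 5, 6])
        assert t.apply(compute_kjc(a, b)) == pytest.approx(compute_kjc(t.apply(a), t.apply(b)))


def _plane_mesh(z=0.0, half=30.0, n=13):
    """A flat square mesh in the z = const plane."""
    xs = np.linspace(-half, half, n)
    vv, uu = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([uu.ravel(), vv.ravel(), np.full(uu.size, z)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return BoneMesh(verts, np.array(faces), "talus")


def _tube_mesh(radius=8.0, z0=2.0, z1=60.0, n_ang=24, n_z=20, cap=True, label="tibia"):
    """An open cylinder along z with an optional flat end cap at z0."""
    angs = np.linspace(0, 2 * np.pi, n_ang, endpoint=False)
    zs = np.linspace(z0, z1, n_z)
    verts = [[radius * np.cos(a), radius * np.sin(a), z] for z in zs for a in angs]
    faces = []
    for iz in range(n_z - 1):
        for ia in range(n_ang):
            a = iz * n_ang + ia
            b = iz * n_ang + (ia + 1) % n_ang
            faces.append([a, b, a + n_ang])
            faces.append([b, b + n_ang, a + n_ang])
    if cap:
        verts.append([0.0, 0.0, z0])
        c = len(verts) - 1
        for ia in range(n_ang):
            faces.append([ia, (ia + 1) % n_ang, c])
    return BoneMesh(np.array(verts), np.array(faces), label)


class TestAJC:
    def test_flat_ended_tube_above_plane(self):
        # tibia tube ends 2 mm above the talus plane; threshold 3 mm selects
        # the cap, whose centroid is the tube axis center
        tibia = _tube_mesh()
        talus = _plane_mesh(z=0.0)
        ajc, count = compute_ajc(tibia, None, talus, threshold=3.0)
        assert count > 0
        assert ajc[:2] == pytest.approx([0.0, 0.0], abs=1e-9)
        assert 1.9 < ajc[2] < 3.1

    def test_threshold_below_gap_rejected(self):
        tibia = _tube_mesh()
        talus = _plane_mesh(z=0.0)
        with pytest.raises(ValueError, match="threshold"):
            compute_ajc(tibia, None, talus, threshold=1.0)

    def test_selection_monotone_in_threshold(self):
        tibia = _tube_mesh()
        talus = _plane_mesh(z=0.0)
        counts = [compute_ajc(tibia, None, talus, threshold=t)[1] for t in (2.5, 4.0, 8.0)]
        assert counts[0] <= counts[1] <= counts[2]

    def test_point_mesh_distance_exact_on_plane(self):
        talus = _plane_mesh(z=0.0)
        pts = np.array([[0, 0, 5.0], [3, -2, 1.0], [0, 0, -4.0], [10, 10, 2.0]])
        d = point_mesh_distance(pts, talus)
        assert d == pytest.approx([5, 1, 4, 2], abs=1e-9)


class TestAlignAnatomical:
    def _inputs(self):
        hjc = np.array([3.0, -2.0, 400.0])
        ajc = np.array([1.0, 4.0, 30.0])
        rng = np.random.default_rng(4)
        uv = rng.uniform(-8, 8, (6, 2))
        # patella patch anterior of the leg axis, roughly facing -y
        pat = np.array([2.0, -40.0, 220.0]) + np.outer(uv[:, 0], [1, 0, 0]) \
            + np.outer(uv[:, 1], [0, 0.05, 1])
        return hjc, ajc, pat

    def test_mechanical_axis_maps_to_plus_y(self):
        hjc, ajc, pat = self._inputs()
        t = align_anatomical(hjc, ajc, pat)
        d = t.apply(hjc) - t.apply(ajc)
        d /= np.linalg.norm(d)
        assert d == pytest.approx([0, 1, 0], abs=1e-9)

    def test_patella_normal_has_zero_x_and_faces_anterior(self):
        hjc, ajc, pat = self._inputs()
        t = align_anatomical(hjc, ajc, pat)
        from limbreg.measurements import fit_plane as fp
        _, n, _ = fp(t.apply(pat), orient=(0, 0, 1))
        assert abs(n[0]) < 1e-9
        assert n[2] > 0.9

    def test_collinear_patella_points_rejected(self):
        hjc, ajc, _ = self._inputs()
        pat = np.outer(np.arange(5.0), [1.0, 0, 0]) + [0, -40, 200]
        with pytest.raises(ValueError, match="collinear"):
            align_anatomical(hjc, ajc, pat)


class TestMA:
    def test_collinear_centers_zero(self):
        assert compute_ma([0, 400, 0], [0, 200, 0], [0, 0, 0], "right") == pytest.approx(0.0)

    def test_constructed_five_degree_varus(self):
        # right leg: knee displaced laterally (-x) so that each segment makes
        # 2.5 deg with the vertical -> MA = +5 varus
        l1 = l2 = 200.0
        dx = -l1 * np.tan(np.radians(2.5))
        hjc = [0, l1 + l2, 0]
        kjc = [dx, l2, 0]
        ajc = [0, 0, 0]
        assert compute_ma(hjc, kjc, ajc, "right") == pytest.approx(5.0, abs=1e-9)
        # mirrored: same construction is valgus on the left leg
        assert compute_ma(hjc, kjc, ajc, "left") == pytest.approx(-5.0, abs=1e-9)

    def test_sagittal_offset_invisible_in_frontal_plane(self):
        assert compute_ma([0, 400, 0], [0, 200, 25.0], [0, 0, 0], "right") == pytest.approx(0.0)

    def test_coincident_projection_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            compute_ma([0, 200, 0], [0, 200, 10], [0, 0, 0], "right")


def _condyle_sphere_femur(height_offset=0.0, sep=50.0, r=15.0):
    """Synthetic femur: vertical shaft tube + two condyle spheres whose
    centers are separated mediolaterally, optionally offset in height."""
    import trimesh

    shaft = _tube_mesh(radius=10.0, z0=40.0, z1=320.0, cap=False, label="femur")
    parts = [np.column_stack([shaft.vertices[:, 0], shaft.vertices[:, 2],
                              shaft.vertices[:, 1]])]  # reorient: y superior
    faces = [shaft.faces]
    offset = len(parts[0])
    for sign, dz in ((-1, 0.0), (1, height_offset)):
        s = trimesh.creation.icosphere(subdivisions=3, radius=r)
        v = np.asarray(s.vertices) + [sign * sep / 2, 30.0 + dz, 0.0]
        parts.append(v)
        faces.append(np.asarray(s.faces) + offset)
        offset += len(v)
    return BoneMesh(np.vstack(parts), np.vstack(faces), "femur")


class TestFCT:
    def test_symmetric_condyles_give_mediolateral_tangent(self):
        femur = _condyle_sphere_femur(height_offset=0.0)
        _, direction = compute_fct(femur)
        assert abs(direction[1]) < 0.02  # no frontal inclination
        assert abs(direction[0]) > 0.99

    def test_height_offset_gives_analytic_inclination(self):
        sep, dz = 50.0, 2.0
        femur = _condyle_sphere_femur(height_offset=dz, sep=sep)
        _, direction = compute_fct(femur)
        if direction[0] < 0:  # line direction is defined up to sign
            direction = -direction
        expected = np.degrees(np.arctan2(dz, sep))
        got = np.degrees(np.arctan2(direction[1], direction[0]))
        assert got == pytest.approx(expected, abs=0.5)

    def test_kmeans_split_matches_halfspace_oracle(self):
        femur = _condyle_sphere_femur()
        from sklearn.cluster import KMeans  # noqa: F401  (used inside compute_fct)
        # condyle points are below the epiphysis cut; a half-space split at
        # x = 0 must match the clustering for well-separated spheres
        point, direction = compute_fct(femur)
        # tangent endpoints straddle x = 0 symmetrically
        assert abs(point[0]) < 1.0


class TestJLCA:
    def test_parallel_lines_zero(self):
        assert compute_jlca([1, 0, 0], [0, 1, 0], "right") == pytest.approx(0.0)

    def test_three_degree_lateral_opening_positive(self):
        # right leg: plateau drops toward lateral (-x) by 3 deg while the
        # femoral tangent stays horizontal -> joint space opens laterally
        tau = np.radians(3.0)
        normal = np.array([-np.sin(tau), np.cos(tau), 0.0])
        assert compute_jlca([1, 0, 0], normal, "right") == pytest.approx(3.0, abs=1e-9)

    def test_mirror_symmetry(self):
        tau = np.radians(3.0)
        n_right = np.array([-np.sin(tau), np.cos(tau), 0.0])
        n_left = np.array([np.sin(tau), np.cos(tau), 0.0])  # mirrored across sagittal
        right = compute_jlca([1, 0, 0], n_right, "right")
        left = compute_jlca([1, 0, 0], n_left, "left")
        assert right == pytest.approx(left, abs=1e-12)

    def test_pure_sagittal_fct_rejected(self):
        with pytest.raises(ValueError, match="sagittal"):
            compute_jlca([0, 0, 1], [0, 1, 0], "right")


class TestRigidInvariance:
    def test_full_measurement_invariant_under_common_rigid_motion(self):
        truth = build_phantom(PhantomSpec())
        base = measure_alignment(truth.meshes, truth.landmarks, side="right")
        t = random_rigid(21)
        meshes = {k: m.transformed(t) for k, m in truth.meshes.items()}
        landmarks = {k: t.apply(np.asarray(v)) for k, v in truth.landmarks.items()}
        moved = measure_alignment(meshes, landmarks, side="right")
        assert moved.ma == pytest.approx(base.ma, abs=1e-6)
        assert moved.jlca == pytest.approx(base.jlca, abs=1e-6)
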