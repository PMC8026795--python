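"""LNCC similarity, arrow initialization, cost assembly and pose recovery."""

import numpy as np
import pytest

from limbreg.drr import hu_to_attenuation
from limbreg.geometry import PixelCoord, project_point
from limbreg.phantom import PhantomSpec, build_phantom, phantom_geometry, simulate_eos_pair
from limbreg.registration import (ArrowAnnotation, ROIMask, RegistrationConfig,
                                  initialize_pose, lncc_similarity,
                                  register_bone, registration_cost)
from limbreg.transforms import RigidTransform, pose_to_transform
from limbreg.validation import registration_error


def lncc_oracle(a, b, mask, patch_size):
    """Brute-force per-patch NCC with variance weights, plain loops."""
    k = patch_size // 2
    r0, c0, r1, c1 = mask
    num = den = 0.0
    for r in range(max(r0, k), min(r1, a.shape[0] - k)):
        for c in range(max(c0, k), min(c1, a.shape[1] - k)):
            pa = a[r - k:r + k + 1, c - k:c + k + 1].ravel()
            pb = b[r - k:r + k + 1, c - k:c + k + 1].ravel()
            va = pa.var()
            vb = pb.var()
            if vb <= 1e-12:
                continue
            ncc = 0.0
            if va > 1e-12:
                ncc = ((pa - pa.mean()) * (pb - pb.mean())).mean() / np.sqrt(va * vb)
            num += vb * ncc
            den += vb
    return num / den if den > 0 else 0.0


class TestLNCC:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(20, 20))
        assert lncc_similarity(img, img, patch_size=5) == pytest.approx(1.0)

    def test_constant_image_scores_zero_without_error(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(15, 15))
        assert lncc_similarity(img, np.ones((15, 15)), patch_size=5) == 0.0

    def test_matches_bruteforce_oracle_on_toys(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.normal(size=(6, 6))
            b = rng.normal(size=(6, 6))
            got = lncc_similarity(a, b, ROIMask(0, 0, 6, 6), patch_size=3)
            assert got == pytest.approx(lncc_oracle(a, b, (0, 0, 6, 6), 3), abs=1e-12)

    def test_oracle_with_flat_patches(self):
        a = np.zeros((8, 8))
        b = np.zeros((8, 8))
        b[2:5, 2:5] = 1.0
        a[2:5, 3:6] = 2.0
        got = lncc_similarity(a, b, ROIMask(0, 0, 8, 8), patch_size=3)
        assert got == pytest.approx(lncc_oracle(a, b, (0, 0, 8, 8), 3), abs=1e-12)

    def test_score_bounded(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 12, 12))
        assert -1.0 <= lncc_similarity(a, b, patch_size=5) <= 1.0

    def test_empty_mask_rejected(self):
        a = np.zeros((10, 10))
        with pytest.raises(ValueError, match="mask"):
            lncc_similarity(a, a, ROIMask(0, 0, 2, 2), patch_size=9)

    def test_even_patch_rejected(self):
        a = np.zeros((10, 10))
        with pytest.raises(ValueError, match="patch"):
            lncc_similarity(a, a, patch_size=4)


@pytest.fixture(scope="module")
def phantom_case():
    spec = PhantomSpec()
    truth = build_phantom(spec)
    geom = phantom_geometry(spec)
    mu = hu_to_attenuation(truth.volume)
    return spec, truth, geom, mu


def _arrow_and_masks(ann, bone):
    arrow = ArrowAnnotation.from_dict(ann["arrows"][bone])
    masks = tuple(ROIMask(*ann["masks"][bone][p]) for p in ("frontal", "lateral"))
    return arrow, masks


class TestInitialization:
    def test_exact_annotations_at_identity_give_identity(self, phantom_case):
        _, truth, geom, _ = phantom_case
        ident = RigidTransform.identity()
        _, ann = simulate_eos_pair(truth, ident, ident, geom)
        for bone in ("femur", "tibia"):
            arrow, _ = _arrow_and_masks(ann, bone)
            init = initialize_pose(arrow, geom)
            assert np.allclose(init.matrix, np.eye(4), atol=1e-6)

    def test_recovers_known_pose_up_to_roll(self, phantom_case):
        # arrows annotated exactly from the projected truth: the initial pose
        # reproduces the true action on the arrow axis; the residual is a
        # pure roll about the arrow direction
        _, truth, geom, _ = phantom_case
        pose = pose_to_transform([2, -1, 3, 4, -6, 2], truth.joint_centers["kjc"])
        _, ann = simulate_eos_pair(truth, pose, pose, geom)
        for bone in ("femur", "tibia"):
            arrow, _ = _arrow_and_masks(ann, bone)
            init = initialize_pose(arrow, geom)
            for pt in (arrow.ct_start, arrow.ct_end):
                assert np.allclose(init.apply(pt), pose.apply(pt), atol=1e-6)
            resid = init.inverse() @ pose
            axis_ct = arrow.ct_end - arrow.ct_start
            axis_ct = axis_ct / np.linalg.norm(axis_ct)
            # rotation axis of the residual is along the arrow
            from scipy.spatial.transform import Rotation
            rv = Rotation.from_matrix(resid.rotation).as_rotvec()
            if np.linalg.norm(rv) > 1e-9:
                assert abs(abs(np.dot(rv / np.linalg.norm(rv), axis_ct)) - 1) < 1e-6

    def test_zero_length_arrow_rejected(self):
        with pytest.raises(ValueError, match="zero length"):
            ArrowAnnotation(
                frontal_start=PixelCoord("frontal", 5, 5),
                frontal_end=PixelCoord("frontal", 5, 5),
                lateral_start=PixelCoord("lateral", 1, 1),
                lateral_end=PixelCoord("lateral", 2, 2),
                ct_start=[0, 0, 0], ct_end=[0, 0, 1],
            )


class TestCost:
    def test_self_match_cost_is_minus_two(self, phantom_case):
        spec, truth, geom, mu = phantom_case
        ident = RigidTransform.identity()
        pair, ann = simulate_eos_pair(truth, ident, ident, geom)
        arrow, masks = _arrow_and_masks(ann, "tibia")
        cfg = RegistrationConfig(drr_step=spec.spacing / 2)  # match simulation step
        cost = registration_cost(np.zeros(6), mu, pair, masks, cfg)
        assert cost == pytest.approx(-2.0, abs=1e-6)

    def test_sum_decomposition(self, phantom_case):
        from limbreg.registration import _masked_drr_similarity

        spec, truth, geom, mu = phantom_case
        ident = RigidTransform.identity()
        pair, ann = simulate_eos_pair(truth, ident, ident, geom)
        _, masks = _arrow_and_masks(ann, "femur")
        cfg = RegistrationConfig(drr_step=spec.spacing)
        pose = pose_to_transform([1, 0, 2, 3, 0, -2], truth.joint_centers["kjc"])
        parts = [_masked_drr_similarity(mu, pose, pair, m, pl, cfg)
                 for pl, m in zip(("frontal", "lateral"), masks)]
        total = registration_cost(np.array([1, 0, 2, 3, 0, -2]), mu, pair, masks, cfg,
                                  center=truth.joint_centers["kjc"])
        assert total == pytest.approx(-(parts[0] + parts[1]), abs=1e-12)

    def test_cost_decreases_toward_truth(self, phantom_case):
        # 1-D profile: from a 5 mm offset the cost decreases monotonically in
        # 2.5 mm steps toward the true pose, for each translation axis
        spec, truth, geom, mu = phantom_case
        ident = RigidTransform.identity()
        pair, ann = simulate_eos_pair(truth, ident, ident, geom)
        _, masks = _arrow_and_masks(ann, "tibia")
        cfg = RegistrationConfig(drr_step=spec.spacing)
        center = truth.joint_centers["kjc"]
        for axis in range(3):
            costs = []
            for offset in (5.0, 2.5, 0.0):
                params = np.zeros(6)
                params[3 + axis] = offset
                costs.append(registration_cost(params, mu, pair, masks, cfg, center))
            assert costs[0] > costs[1] > costs[2]


class TestRegisterBone:
    def test_self_registration_recovers_truth(self, phantom_case):
        # EOS := DRR at the true pose, init at truth: recovery < 0.1 mm/0.1 deg
        spec, truth, geom, mu = phantom_case
        pose = pose_to_transform([1.5, -1, 2, 3, -4, 2], truth.joint_centers["kjc"])
        pair, ann = simulate_eos_pair(truth, pose, pose, geom)
        arrow, masks = _arrow_and_masks(ann, "tibia")
        cfg = RegistrationConfig(drr_step=spec.spacing)
        res = register_bone(mu, pair, arrow, masks, cfg, initial_pose=pose)
        err = registration_error(res.transform, pose)
        assert err.max_abs_translation() < 0.1
        assert err.max_abs_rotation() < 0.1
        assert res.cost < -1.99

    def test_start_at_optimum_stays_within_tolerance(self, phantom_case):
        spec, truth, geom, mu = phantom_case
        ident = RigidTransform.identity()
        pair, ann = simulate_eos_pair(truth, ident, ident, geom)
        arrow, masks = _arrow_and_masks(ann, "tibia")
        cfg = RegistrationConfig(drr_step=spec.spacing)
        res = register_bone(mu, pair, arrow, masks, cfg)
        assert np.max(np.abs(res.params[:3])) < 0.5   # degrees
        assert np.max(np.abs(res.params[3:])) < 0.5   # mm

    def test_translation_equivariance(self, phantom_case):
        # shifting the ground truth and the initialization by delta shifts
        # the recovered pose by delta
        spec, truth, geom, mu = phantom_case
        cfg = RegistrationConfig(drr_step=spec.spacing, max_evaluations=300)
        recovered = []
        for delta in (np.zeros(3), np.array([4.0, 0.0, -6.0])):
            pose = pose_to_transform([0, 0, 0, *delta])
            pair, ann = simulate_eos_pair(truth, pose, pose, geom)
            arrow, masks = _arrow_and_masks(ann, "tibia")
            start = pose_to_transform([0, 0, 0, *(delta + [1.5, -1.0, 2.0])])
            res = register_bone(mu, pair, arrow, masks, cfg, initial_pose=start)
            recovered.append(res.transform.translation)
        shift = recovered[1] - recovered[0]
        assert np.allclose(shift, [4.0, 0.0, -6.0], atol=0.2)

    def test_result_transform_is_rigid(self, phantom_case):
        spec, truth, geom, mu = phantom_case
        ident = RigidTransform.identity()
        pair, ann = simulate_eos_pair(truth, ident, ident, geom)
        arrow, masks = _arrow_and_masks(ann, "femur")
        cfg = RegistrationConfig(drr_step=spec.spacing, max_evaluations=60)
        res = register_bone(mu, pair, arrow, masks, cfg)
        r = res.transform.rotation
        assert np.allclose(r.T @ r, np.eye(3), atol=1e-9)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)
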