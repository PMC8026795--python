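"""Register the tibia of the synthetic phantom to a simulated biplanar pair.

The phantom is placed at a known rigid pose; the arrow-based initialization
is deliberately perturbed by 5 mm / 5 degrees, and the intensity-based
optimization recovers the pose. The residual E = T^-1 GT is decomposed into
per-axis translation and rotation errors — the quantities the phantom
validation reports. Takes ~half a minute.
"""

import numpy as np

from limbreg import (PhantomSpec, RegistrationConfig, build_phantom,
                     hu_to_attenuation, phantom_geometry, register_bone,
                     registration_error, simulate_eos_pair)
from limbreg.registration import ArrowAnnotation, ROIMask, initialize_pose
from limbreg.validation import perturbation_pose, random_rigid_pose

spec = PhantomSpec()
truth = build_phantom(spec)
geom = phantom_geometry(spec)
mu = hu_to_attenuation(truth.volume)

rng = np.random.default_rng(0)
gt_pose = random_rigid_pose(rng, 3.0, 8.0, truth.joint_centers["kjc"])
pair, ann = simulate_eos_pair(truth, gt_pose, gt_pose, geom)

arrow = ArrowAnnotation.from_dict(ann["arrows"]["tibia"])
masks = tuple(ROIMask(*ann["masks"]["tibia"][p]) for p in ("frontal", "lateral"))
init = initialize_pose(arrow, geom)
center = init.apply((arrow.ct_start + arrow.ct_end) / 2)
start = perturbation_pose(rng, 5.0, 5.0, center) @ init  # 5 mm / 5 deg off

cfg = RegistrationConfig(drr_step=2 * spec.spacing, xtol=0.02, ftol=1e-5)
result = register_bone(mu, pair, arrow, masks, cfg, initial_pose=start)
print(f"optimizer: {result.n_evaluations} cost evaluations, "
      f"final cost {result.cost:.4f} (perfect biplanar match = -2)")

err = registration_error(result.transform, gt_pose)
print(f"translation error (x,y,z): {np.round(err.translation, 3)} mm, "
      f"norm {err.translation_norm:.3f} mm")
print(f"rotation error (x,y,z): {np.round(err.rotation_deg, 3)} deg")
print("errors are the residual pose after registration; sub-0.1 mm/deg means "
      "the standing pose of the bone is recovered essentially exactly")
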