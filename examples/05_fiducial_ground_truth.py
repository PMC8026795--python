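"""Fiducial-based ground truth: the validation chain of the registration.

Marker centers are sphere-fit in the CT volume, triangulated from their 2D
projections, and rigidly fit to each other — yielding the ground-truth
transform a physical phantom validation would use.
"""

import numpy as np

from limbreg import (PhantomSpec, build_phantom, marker_centers_from_volume,
                     phantom_geometry, registration_error, rigid_fit_points,
                     simulate_eos_pair, triangulate_markers)
from limbreg.transforms import pose_to_transform
from limbreg.validation import MarkerSet

spec = PhantomSpec()
truth = build_phantom(spec)
geom = phantom_geometry(spec)

# place the (rigidly mounted) phantom at a known pose and simulate the images
pose = pose_to_transform([1.5, -1.0, 2.0, 4.0, -3.0, 6.0], truth.joint_centers["kjc"])
_, ann = simulate_eos_pair(truth, pose, pose, geom)

ct_markers = marker_centers_from_volume(truth.volume, intensity_threshold=2000.0,
                                        expected_diameter=spec.marker_diameter)
print(f"CT: {len(ct_markers.labels)} fiducials extracted, "
      f"worst sphere-fit residual {ct_markers.residuals.max():.3f} mm")

eos_markers = triangulate_markers(ann["markers"]["frontal"],
                                  ann["markers"]["lateral"], geom)
# relabel CT markers by matching to the known layout so correspondences align
order = [int(np.argmin(np.linalg.norm(ct_markers.centers - c, axis=1)))
         for c in truth.marker_centers]
ct_matched = MarkerSet(labels=truth.marker_labels,
                       centers=ct_markers.centers[order], frame="CT")

gt, rmsd = rigid_fit_points(ct_matched, eos_markers)
print(f"ground-truth fit over 12 markers: RMSD = {rmsd:.3f} mm")

err = registration_error(gt, pose)
print(f"GT vs true pose: translation {np.round(err.translation, 3)} mm, "
      f"rotation {np.round(err.rotation_deg, 3)} deg")
print("the fiducial chain recovers the mounted pose to a fraction of a "
      "voxel — the accuracy floor against which registration is judged")
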