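"""Project a 3D point into the biplanar fan-beam geometry and recover it.

The frontal and lateral images share an unmagnified vertical axis (the scan
direction); horizontal coordinates are perspective projections rescaled to
the isocenter detector. Triangulating the two horizontal coordinates plus
averaging the two vertical ones inverts the projection exactly.
"""

import numpy as np

from limbreg import geometry_from_parameters, project_point, triangulate_point

geom = geometry_from_parameters()  # reference device calibration
print(f"calibration: f = {geom.f_frontal} mm, z0 = {geom.z0} mm, "
      f"vertical pitch = {geom.pitch_z} mm/px")

landmark = np.array([42.0, -18.0, 310.0])  # mm: left, posterior, superior
front = project_point(landmark, geom, "frontal")
side = project_point(landmark, geom, "lateral")
print(f"frontal pixel: h = {front.h:.2f}, v = {front.v:.2f}")
print(f"lateral pixel: h = {side.h:.2f}, v = {side.v:.2f}")

recovered = triangulate_point(front, side, geom)
print(f"triangulated back: {np.round(recovered, 9)} (round-trip error "
      f"{np.abs(recovered - landmark).max():.2e} mm)")

# a landmark at vertical pixel 0 in both planes sits at the initial emitter
# height z0 — the anchor case of the height formula
at_top = triangulate_point(
    type(front)("frontal", geom.principal_frontal, 0.0),
    type(side)("lateral", geom.principal_lateral, 0.0),
    geom,
)
print(f"landmark at v=0 in both planes -> P_z = {at_top[2]} mm (= z0)")
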