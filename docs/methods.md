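# Methods

`limbreg` transfers CT-derived 3D bone models of the lower limb into the
standing (weight-bearing) pose by intensity-based 2D-3D rigid registration
against calibrated biplanar standing radiographs, and measures the two
frontal-plane deformity parameters used to plan corrective osteotomies — the
mechanical axis deviation (MA) and the joint line convergence angle (JLCA) —
directly in 3D. This note documents the models, conventions, parameters and
numerical choices, and what the synthetic phantom does and does not show.

## Imaging model

The biplanar scanner (EOS-style) acquires frontal and lateral images with two
perpendicular fan beams sweeping vertically in synchrony. Each image row is a
1D perspective projection in the horizontal plane; the vertical axis maps to
world height with no magnification. The vendor rescales horizontal
coordinates to a virtual detector through the machine isocenter, so a
horizontal segment at the isocenter projects at scale exactly 1.

World frame (right-handed): x to the patient's left, y posterior, z superior.
The frontal line source is placed at y = -f_f and the lateral line source at
x = -f_l; this placement is a convention (the calibration does not determine
the side) and all signs in the package are consistent with it. For a point
P = (Px, Py, Pz):

    frontal:  h_mm = f_f Px / (f_f + Py)      v = (z0 - Pz) / lambda_z
    lateral:  h_mm = f_l Py / (f_l + Px)      v = (z0 - Pz) / lambda_z

with f_f = f_l = 918 mm, z0 = 477.5 mm and lambda_z = 0.179363 mm/px in the
reference calibration. Stereo triangulation solves the two horizontal
constraints as a 2x2 linear system whose right-hand side carries the products
f·h (in mm), and recovers height as P_z = z0 - lambda_z (v_f + v_l)/2. The
system is derived from the forward model above rather than transcribed, and
its correctness is pinned by the round-trip property
(triangulate ∘ project = identity to 1e-9 mm), which holds for any emitter
convention. Horizontal pixel pitches default to lambda_z (square pixels) and
the principal pixel to the image-center column; both are overridable in the
calibration file, since real headers may carry explicit values.

## DRR rendering

Digitally reconstructed radiographs are monochromatic line integrals of
linear attenuation, mu = max(0, (HU + 1000)/1000) * mu_water with
mu_water = 0.02/mm. No exponential detector conversion is applied: the
similarity metric (localized NCC) is invariant to monotone local intensity
rescaling, so the line integral carries the same information at lower cost.
Rays start at the row's emitter position (the line source sampled at
z = z0 - lambda_z v), pass through the pixel's isocenter-detector position,
are clipped to the volume bounding box, and are integrated by the trapezoid
rule on trilinear samples. The default step is half the smallest voxel
spacing; halving the step changes integrals on a smooth object by < 1%
(convergence test). Outside-volume samples contribute zero. The pose maps CT
coordinates into the world frame — the same direction as the per-bone output
transforms.

## Registration

Six degrees of freedom: intrinsic x-y-z Euler angles (degrees) and
translations (mm), rotating about the annotated bone midpoint so rotational
and translational parameters stay decoupled.

*Initialization.* The user draws the same anatomical arrow (e.g. distal
tibia to tibial plateau center) in the frontal image, the lateral image and
the CT. The 2D endpoints are triangulated; the initial pose is the minimal
rotation (about the cross-product axis) aligning the CT arrow direction with
the triangulated direction plus the midpoint translation. Roll about the
arrow axis is unobservable from the arrows and left at zero; antiparallel
arrows fall back to a fixed perpendicular axis. Restarting after manual
adjustment is re-invocation with a new initial pose.

*Similarity.* Variance-weighted localized normalized cross correlation with
a 9-pixel patch: per pixel inside the user's rectangular mask the NCC of the
9x9 neighborhoods of DRR and radiograph is computed and averaged with
weights equal to the local variance of the fixed radiograph patch
(normalized over the mask), so structured bone regions dominate and flat
background contributes nothing; zero-variance patches get weight zero.
Scored pixels are restricted to those whose full patch lies inside the
image, so no padding convention enters the score. The cost is the negated
sum over the two planes (minimum -2).

*Optimization.* Bound-constrained derivative-free minimization
(scipy's Powell method) with default box bounds of +-30 mm and +-30 degrees
around the initialization — generous relative to the manual initialization's
accuracy. Default tolerances: 0.01 (mm/deg) parameter tolerance, 1e-6
relative cost tolerance, at most 2000 cost evaluations. Only the masked
rectangles (expanded by the patch half-width) are rendered per evaluation.
The registration is deterministic for identical inputs. Bound saturation is
flagged in the result status and the best-so-far pose returned.

## Measurements

Joint centers: HJC = algebraic least-squares sphere fit to user-picked
femoral head points; KJC = midpoint of the two intercondylar eminence picks;
AJC = centroid of tibial + fibular vertices whose exact closest-point
distance to the talus surface is below a threshold (default 3.0 mm,
configurable; the selected count is reported so the threshold can be raised
until the articular surface is covered, mirroring the visual workflow).

Anatomical frame: the mechanical axis AJC->HJC is rotated onto +y (superior),
then the limb is rotated about it until the best-fit plane of the anterior
patellar points faces +z. The anterior sense is resolved anatomically — the
patella centroid lies in front of the leg axis — so no extra user input is
needed.

MA is the frontal-plane (x-y) deviation from collinearity between HJC->KJC
and KJC->AJC (straight leg = 0; the 0-based convention matches the
varus-positive signing and the single-digit magnitudes clinicians quote,
rather than the 180-degree hip-knee-ankle form). Positive = knee deviated
laterally (varus), with `side` resolving medial/lateral.

JLCA is the frontal-plane angle between the femoral condyle tangent (FCT)
and the trace of the tibial plateau plane (TCT), positive when the joint
space opens laterally. FCT: the femoral long axis is the first principal
component of the mesh vertices; the distal epiphysis is cut at the
most-distal 15% of femoral length (or 5 mm proximal of the more proximal of
two epicondyle picks when given); a 2-means split with deterministic seeds
(the two mediolaterally extremal epiphysis vertices) separates the condyles;
per condyle the three most distal vertices along the axis are averaged and
the FCT joins the two means. TCT: total-least-squares plane through eight
plateau picks, projected to the frontal plane as n x z.

All measurements are invariant under a common rigid motion of the inputs
(tested to 1e-6 degrees).

## Validation machinery

Ground truth for a rigidly mounted phantom comes from six 3 mm radiopaque
spherical fiducials per bone: CT centers by connected components above an HU
threshold, per-component sub-voxel surface extraction (local marching cubes
at the threshold iso-level) and sphere fitting, with a +-50% diameter gate
against the nominal size; world centers by triangulating labeled 2D
projections; and a labeled closed-form rigid fit (Kabsch — the
one-assignment case of ICP) over all twelve correspondences, which is the
default (a per-bone fit is available). Registration error is E = T^-1 GT,
reported as per-axis translations and intrinsic x-y-z Euler angles — at the
sub-degree magnitudes involved, Euler conventions agree to first order.

## Synthetic phantom

The digital leg phantom replaces physical phantom scans and patient data.
Bones are schematic solids — femoral head sphere (r 15 mm), shaft capsules,
two condyle spheres (r 14 mm, 36 mm apart), a tilted tibial plateau disk
(r 22 mm), fibula, patella with a flat anterior face, and a flat-topped talus
2 mm below the tibial end face. Defaults: 350 mm hip-to-ankle length,
1.5 mm voxels (coarser than the 0.5-1 mm clinical protocol; a finer spacing
is one spec field away), cortical bone 1200 HU, markers 3000 HU, soft-tissue
sheath 40 HU (5 mm around each bone), air -1000 HU. The HU values are
fixture parameters giving plausible contrast, not tissue claims.

Voxelization is anti-aliased (a one-voxel linear ramp of the signed distance
at each surface), so marching cubes recovers surfaces with sub-voxel
accuracy — this is what lets a 1.5 mm lattice support 0.2-degree angle
recovery and half-voxel fiducial localization. Tissue classes compose in
priority order (soft, bone, marker) with union-of-segments SDFs per posed
group, and the composite volume adds group attenuations, which is exact for
spatially disjoint groups.

The frontal-plane deformity is constructed exactly: the knee is displaced
laterally until atan(|x|/L1) + atan(|x|/L2) equals the requested MA, and the
plateau normal is tilted by the requested JLCA in the lateral-opening sense;
condyle centers sit at equal height so the FCT is exactly mediolateral.
Landmark picks (head points, eminences, plateau rhomboid, patellar face,
epicondyles) are emitted analytically.

Simulated acquisitions render the femur group (femur + patella) and tibia
group (tibia + fibula + talus) at independent rigid poses and composite
additively — a schematic posture change that ignores soft-tissue deformation
and any bending within a bone. The emitted 2D annotations (marker
projections, arrows, masks) are exact. The phantom geometry uses the
reference 918 mm source distances with a coarsened 2 mm vertical / 1 mm
horizontal pitch so full images stay small.

*What passing tests show — and don't.* The phantom shares the renderer with
the registration (an "inverse crime"): simulated images contain no scatter,
beam hardening, soft-tissue mismatch, patient motion or detector noise, and
bones are smooth solids with strong fiducial contrast. Accuracy numbers on
the phantom therefore demonstrate correctness of the geometry, cost,
optimizer and error accounting — not expected clinical accuracy. Conversely,
failure modes that are purely geometric (out-of-plane rotation about the
vertical axis being the weakly observed direction in a biplanar setup) do
reproduce.

## Validation experiment

The registration accuracy experiment places the whole phantom (rigid, like a
mounted physical phantom — one ground truth for both bones) at a random pose
(rotation up to 3 degrees, translation up to 8 mm), simulates the image
pair, perturbs the arrow-derived initialization by exactly 5 mm and
5 degrees in random directions, registers femur and tibia independently, and
decomposes E = T^-1 GT. Five seeded repetitions; the maxima across axes,
bones and repetitions are the reported accuracy figures. The known
simulation pose serves as ground truth (exact); the fiducial chain recovers
the same pose to a fraction of a voxel and is exercised separately. The
experiment uses a ray step of twice the voxel spacing and a 0.02 (mm/deg)
parameter tolerance — accuracy on the smooth phantom is insensitive to both,
as the step-convergence and self-registration tests show — keeping a full
10-registration experiment within a few minutes on one CPU.

## Known limitations

- Axis-aligned volumes only; oblique acquisitions must be resampled first.
- No deformable registration, no multi-bone joint optimization, no GPU path.
- No detector tilt, scatter, beam hardening or scan-motion distortion in the
  imaging model.
- Landmark picks are inputs (the synthetic phantom emits them); there is no
  automatic landmark detection.
- Inferential statistics of clinical cohorts (significance tests,
  reliability coefficients) are out of scope; the pipeline reports per-case
  measurements and differences only.
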