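# Methods

This note documents the geometric model, the measurement pipeline, the
synthetic-data generator and the numerical choices behind `acl-impinge`.

## Problem and model

Graft impingement in single-bundle ACL reconstruction is modelled purely
geometrically: the graft is a rigid straight cylinder joining the femoral
and tibial tunnel footprint centres, and impingement is the Boolean
overlap volume (mm³) between that cylinder and the femoral bone solid.
No graft bending, wrapping at the notch margin, pretension or soft-tissue
interaction is modelled; the knee is posed rigidly at discrete flexion
angles.  These simplifications mirror the virtual-cylinder approach used
in CT-based surgical-planning studies, and they bound the physical
interpretation: a positive overlap volume marks a configuration in which
a real graft would be compressed or notched against bone, but the number
is not a contact force.

### Footprint coordinate systems

* **Femur.**  A quadrant ("grid") frame on the medial wall of the lateral
  femoral condyle, constructed from named landmarks: the highest point of
  the intercondylar notch (the superior border passes through it, along
  the Blumensaat direction), the anterior- and posterior-most points of
  the wall outline along that border, an inferior extent point, and the
  wall's outward normal.  Footprints are fractions of the frame's total
  height (superior→inferior) and depth.  **Depth is measured from the
  posterior border**, the operational convention of the quadrant method;
  `femoral_depth_from="anterior"` switches to the opposite reading, which
  some texts state in prose.  The published fractions shipped in
  `data/footprint_fractions.yaml` are AM = (25 % height, 33 % depth) and
  PL = (45.1 %, 50 %).
* **Tibia.**  The bounding rectangle of the plateau's cortical outline in
  top view, from the four extreme outline points; AM = (35 % depth from
  anterior, 50.5 % width from medial), PL = (46.4 %, 52.4 %).
* **Central** is defined on both bones as the midpoint of the AM and PL
  surface points, re-projected onto the surface; it has no independent
  fractions.

Grid points are mapped to bone by projecting along the frame normal and
taking the intersection nearest the in-plane point.  Landmark provenance:
synthetic knees emit landmarks analytically; real meshes require a JSON
sidecar of named points (automatic landmark detection is out of scope,
matching the manual frame construction of the source workflow).  Frames
are re-fitted per pose rather than propagated across poses.

### The insertion-overlap question

A straight cylinder that terminates *on* a bone wall necessarily
penetrates the bone behind its insertion: for a wall at angle α to the
graft axis the overlap is of order r³/sin α — tens to hundreds of mm³
for 7–9 mm grafts, at *every* flexion angle.  Counting that term would
swamp the notch-conflict signal and make deep-flexion volumes large even
when the graft visibly clears the notch.  The package therefore clips
the impingement probe at the femoral-attachment tangent plane (known
exactly from the fitted frame normal) by default, which removes exactly
the behind-the-wall part; on the synthetic knees this yields exact zeros
whenever the graft clears the roof.  Two alternatives are exposed for
sensitivity analysis: `cap_depth` truncates the probe axially at each
end, and `clip_at_insertion=False` measures the raw cylinder.

## The voxel Boolean kernel

`intersection_volume(a, b, spacing)` counts voxel centres lying inside
both watertight solids and multiplies by `spacing³`.

* **Inside test**: generalized winding number (sum of signed solid
  angles), robust to near-degenerate triangles; a parity ray-cast
  (Möller–Trumbore crossing count) is kept as an independent oracle in
  the tests and is never used by the production path.
* **Common grid**: anchored at the snapped minimum corner of the
  intersected AABBs, making the result exactly symmetric in (a, b);
  disjoint AABBs short-circuit to zero.
* **Spacing default 0.5 mm**, configurable.  The CT-based measurement
  chain this emulates is validated to about 1 mm; 0.5 mm halves that
  while keeping a full 72-cell factorial around half a minute per knee
  on one CPU.  A convergence report over {1.0, 0.5, 0.25} mm is
  available (`convergence_report`), and the benchmark suite checks the
  kernel against closed-form intersection volumes (cube/cube,
  cylinder/slab, sphere/cube) with non-increasing error over those
  spacings and <1 % error at 0.25 mm.
* **Convex half-space clipping** (for the insertion probe) re-closes the
  cut with a centroid-fan cap; the plane is nudged ~1 µm into the
  removed side when a vertex lies on it, avoiding T-junction cracks at a
  volume cost far below voxel resolution.  The routine assumes a convex
  solid (always true for the cylinder probes).

Exact mesh–mesh Boolean construction (CSG) is deliberately out of scope:
only the intersection *volume* is needed.

## Notch width

The notch width is the widest medial–lateral opening between the
condylar inner walls in the anterior projection, conventionally read at
90° of flexion (the femur is the fixed body in this implementation, so
its measurement is pose-invariant unless a pose is supplied).  The femur
is sectioned by horizontal planes at 0.25 mm steps; at each height the
cross-section bodies are projected onto the medial–lateral axis and the
largest gap *between* bone intervals is taken; the maximum over heights
is returned.  The chord is not constrained to a particular height —
"widest part" is taken literally.

## Synthetic knee generator

The generator stands in for CT reconstructions with controllable,
analytic geometry — not anatomical fidelity:

* two condyles modelled as cylinders of radius `condyle_radius` (22 mm)
  about the transepicondylar axis, each `condyle_width` (25 mm) thick,
  separated by the notch of width `notch_width` (19.0 mm; population sd
  3.4 mm);
* a notch-roof slab between the condylar walls whose lower surface
  descends anteriorly at `roof_angle` from the notch apex to an outlet
  `roof_anterior_clearance` (6 mm) above the plateau;
* an elliptic tibial plateau (semi-axes 25 × 18 mm, anterior offset
  `tibia_offset` = 8 mm) as the proximal tibia;
* hinge kinematics: flexion rotates the tibia about the fixed
  transepicondylar axis.

Every ground-truth quantity the generator emits (frames, landmarks,
footprint points, notch width) is independently recoverable by the
pipeline's own measurement operations — that closed loop is the module's
purpose.  Output is bit-for-bit deterministic in the parameters;
populations draw truncated Gaussians (rejection sampling against the
feasibility constraints, 100 attempts) reproducibly per seed.

**Tuning declared as tuning.**  `roof_angle` = 50° with the anterior-reach
defaults above was chosen once so that, at full extension, the AM–AM
pairing impinges substantially while PL–PL barely does, reproducing the
qualitative contrast of the clinical Table-1 pattern on this schematic
geometry.  The angle is steeper than an anatomical Blumensaat angle
(~35–40°) because the flat plateau and cylindrical condyles lack the
distal curvature that brings a real notch outlet close to the tibial
footprints.

### What the generator does and does not emulate

It reproduces: the orderings that the simulation is meant to detect
(9 mm ≥ 7 mm everywhere; tibial and femoral AM ≥ central ≥ PL at
extension; extension ≥ 45° ≥ deep flexion ≈ 0), inter-subject variation
via parameter draws, and exact-zero impingement in deep flexion.  It
does **not** reproduce: absolute overlap volumes of real knees (the
synthetic values are roughly 2–4× smaller than published clinical
means), the relative statistical sensitivity of femoral vs tibial
positioning (on this geometry the femoral factor is *more* significant,
whereas clinical data find the tibial factor dominant), or any
morphological variability beyond the parameterized dimensions.  With the
default hinge, the tibial footprints swing posterior of the roof already
at 45°, so 45° volumes are ≈ 0 rather than merely reduced.  Passing
tests therefore demonstrate correctness of the measurement chain and of
the orderings' geometric logic — not clinical accuracy of magnitudes.

## Statistics

The battery mirrors the analysis plan of the study design it supports:
independent *t*-test between graft diameters, paired *t*-tests between
flexion angles (all pairs are computed, since the source plan does not
name them), one-way ANOVA over each footprint factor, and two-way ANOVA
with interaction; partial eta squared = SS_effect/(SS_effect + SS_error).

Choices where the plan is silent: two-sided tests, pooled variance
(Welch switchable), no multiplicity correction.  The unit of analysis is
the knee-level record within a stratum (extension angle × diameter) for
the ANOVAs, matching the headline-table stratification; the diameter
*t*-test averages within knees first (`per_knee=False` pools raw cells).
Balanced layouts use the closed-form sum-of-squares decomposition (type
I/II/III coincide); unbalanced input warns and uses a type-II OLS
decomposition via statsmodels.  Degenerate paired input (zero variance
of differences, nonzero mean) is reported as t = ±∞, p = 0 with an
explicit note.  Mixed-effects modelling with knee as a random effect
would be the natural extension; it is intentionally not part of the
battery.

Calibration: each test's type-I error is verified by 1000-rep null
simulation (rejection rate within two standard errors of α = 0.05), the
F = t² identity for two-level one-way ANOVA holds to 1e-9, and the
*t*-tests agree with the scipy reference to machine precision on shared
draws.

## Numerical conventions and degenerate inputs

* All coordinates in mm, right-handed frames, no unit auto-detection.
* STL vertex merge tolerance 1e-6 mm (STL duplicates vertices per facet);
  meshes read with negative signed volume are re-oriented.
* Watertightness = every edge shared by exactly two faces; violations
  raise with the open-edge count.  Degenerate triangles (area ≤ 1e-9
  mm²) are rejected.
* Rotation matrices must be orthonormal with det +1 within 1e-9.
* Fractions outside [0, 1], missing landmarks, collinear landmarks,
  swapped anterior/posterior landmarks, projection rays that miss the
  surface, coincident graft endpoints, oversize `cap_depth`, and empty
  ANOVA cells all raise typed errors; a factorial run isolates failures
  per cell and continues, emitting structured failure records.

## Problem sizes used in the shipped checks

The bundled verification suite uses one default knee for the worked
example and unit checks, a 9-knee population (the study's sample size)
for the ordering and statistics checks, a 20-knee population for
parameter recovery, 1000-rep null simulations for calibration, and
kernel benchmarks at 1.0/0.5/0.25 mm spacing — all chosen to exercise
the full pipeline at the scale the method is designed for while staying
comfortably reproducible on a single CPU.
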