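# acl-impinge

Virtual 3D simulation of graft impingement in single-bundle anterior
cruciate ligament (ACL) reconstruction.

After ACL reconstruction, the tendon graft can collide with the femoral
intercondylar notch near full extension ("graft impingement"), abrading
the graft and limiting motion.  Where the bone tunnels are placed — and
how thick the graft is — largely determines how much conflict occurs.
This package lets surgical-planning and biomechanics researchers quantify
that conflict *in silico*: it places virtual cylindrical grafts between
candidate femoral and tibial footprint positions on 3D knee surface
models, measures the graft–femur overlap volume with a voxel Boolean
kernel, and runs the associated statistical comparisons.

## What it computes

* **Footprint positioning.**  Tunnel positions are specified on the
  classical quadrant grid of the medial wall of the lateral femoral
  condyle (superior border through the highest point of the notch, along
  the Blumensaat direction) and on the bounding rectangle of the tibial
  plateau's cortical outline.  The shipped fraction table holds the
  standard percentage coordinates: femoral AM at 25 % height / 33 % depth
  (from the posterior border) and PL at 45.1 % / 50 %; tibial AM at 35 %
  depth / 50.5 % width and PL at 46.4 % / 52.4 %; the *central* position
  is the re-projected midpoint of AM and PL.
* **Virtual graft.**  The graft is a rigid straight cylinder (clinically
  motivated diameters 7 and 9 mm) spanning the femoral and tibial
  footprint centres.  By default the impingement probe is the graft
  clipped at the femoral-attachment tangent plane, so the geometrically
  unavoidable overlap of a straight cylinder with the bone behind its own
  insertion is not counted as impingement (an axial `cap_depth`
  truncation is also available).
* **Overlap volume.**  `intersection_volume(a, b, spacing)` counts voxel
  centres inside both watertight solids (generalized winding number) on a
  common grid; it converges to the Boolean intersection volume as the
  spacing shrinks (default 0.5 mm).
* **Factorial design.**  3 femoral × 3 tibial positions × {7, 9} mm ×
  {0°, 45°, 90°, 120°} of knee flexion = 72 cells per knee.
* **Statistics.**  Independent *t*-test (diameter), paired *t*-tests
  (flexion angles), one-way and two-way ANOVA over footprint positions
  with partial eta squared (SS_effect / (SS_effect + SS_error)).
* **Synthetic knees.**  A parametric generator (condyle cylinders, an
  inclined notch-roof slab, an elliptic plateau, hinge kinematics)
  produces watertight femur/tibia meshes with *analytic* ground truth —
  frames, landmarks, footprints, notch width (population default
  19.0 ± 3.4 mm) — so the whole pipeline is testable without clinical CT
  data.  Real meshes are ingested as STL plus a JSON landmark sidecar.

## Worked example

```python
from acl_impinge import generate_knee, run_knee, records_to_dataframe, extension_table

knee = generate_knee()                      # default synthetic knee
records, failures = run_knee(knee)          # 72-cell factorial, ~30 s
df = records_to_dataframe(records)
print(extension_table(df, diameter=9.0))
```

prints the graft–notch overlap volumes (mm³, mean ± sd — zero spread for
a single knee) at 0° extension for the 9 mm graft:

```
tibial_position            AM      central          PL
femoral_position
AM                182.8 ± 0.0  132.2 ± 0.0  80.5 ± 0.0
central            71.4 ± 0.0   46.2 ± 0.0  22.2 ± 0.0
PL                 21.9 ± 0.0   12.0 ± 0.0   4.1 ± 0.0
```

Reading: impingement grows as either footprint moves anteriorly (AM >
central > PL on both bones), the AM–AM pairing is worst, the PL–PL
pairing nearly clears the notch, and (not shown) all volumes at 45–120°
of flexion are zero for this geometry.  The same pipeline runs from the
shell:

```sh
acl-impinge synth --n 9 --seed 1 --out knees/
acl-impinge run --knees knees/ --out results.csv
acl-impinge stats results.csv
```

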