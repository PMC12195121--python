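"""Parametric synthetic knee generator with analytic ground truth.

The generator emulates the study inputs this pipeline needs — watertight
distal-femur and proximal-tibia surface models poseable at 0/45/90/120
degrees of flexion — with controllable, analytic geometry rather than
anatomical fidelity:

* two femoral condyles modelled as cylinders about the transepicondylar
  (flexion) axis, separated by the intercondylar notch of configurable
  width (population default 19.0 +/- 3.4 mm);
* a notch roof slab whose lower surface descends anteriorly at
  ``roof_angle`` (the Blumensaat direction); the anterior part of this
  descending roof is what an anteriorly placed graft collides with near
  full extension;
* a tibial plateau modelled as an elliptic slab, optionally shifted
  anteriorly (``tibia_offset``);
* simple hinge kinematics about the fixed transepicondylar axis.

Coordinate convention: +x lateral, +y anterior, +z superior; the flexion
axis is the x-axis through the origin; all lengths in mm.  Every emitted
ground-truth quantity (frames, landmarks, footprint points, notch width)
is independently recoverable by the pipeline's own measurement operations.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import trimesh

from .errors import InfeasibleParamsError
from .footprint_grid import (
    FOOTPRINT_FRACTIONS,
    FemoralFrame,
    TibialFrame,
)
from .mesh_core import (
    RigidTransform,
    SurfaceMesh,
    apply_transform,
    validate_mesh,
)

FLEXION_ANGLES = (0.0, 45.0, 90.0, 120.0)

#: fields drawn from truncated Gaussians in population sampling, with the
#: default population standard deviations (the notch value mirrors the
#: reported inter-subject spread; the others are modest shape variation).
DEFAULT_POPULATION_SDS = {
    "notch_width": 3.4,
    "condyle_radius": 1.5,
    "plateau_semi_ml": 1.5,
    "plateau_semi_ap": 1.2,
    "tibia_offset": 1.0,
    "roof_angle": 2.0,
}


@dataclass(frozen=True)
class SyntheticKneeParams:
    """Generator knobs (mm / degrees).  ``seed`` fixes the output bit-for-bit
    (a single knee is a deterministic function of its parameters; the seed
    matters for population draws)."""

    notch_width: float = 19.0
    notch_height: float = 22.0  # femoral grid total height
    condyle_radius: float = 22.0
    condyle_width: float = 25.0  # medial-lateral thickness of each condyle
    roof_angle: float = 50.0  # inclination of the notch roof, deg from horizontal
    roof_posterior_y: float = -14.0  # AP position of the notch apex
    roof_apex_height: float = 4.0  # z of the notch apex (highest point)
    roof_top_height: float = 10.0  # top of the roof slab
    roof_anterior_clearance: float = 6.0  # roof outlet height above the plateau
    plateau_semi_ml: float = 25.0  # tibial plateau semi-axis, medial-lateral
    plateau_semi_ap: float = 18.0  # tibial plateau semi-axis, antero-posterior
    plateau_thickness: float = 12.0
    joint_gap: float = 3.0  # femoro-tibial clearance at extension
    tibia_offset: float = 8.0  # anterior shift of the plateau centre
    mesh_resolution: float = 1.5  # target edge length for curved surfaces
    seed: int = 0

    # -- derived geometry ---------------------------------------------------

    @property
    def plateau_top_z(self) -> float:
        return -(self.condyle_radius + self.joint_gap)

    @property
    def roof_outlet_z(self) -> float:
        """z of the roof's lower surface at its anterior end."""
        return self.plateau_top_z + self.roof_anterior_clearance

    @property
    def roof_anterior_y(self) -> float:
        drop = self.roof_apex_height - self.roof_outlet_z
        return self.roof_posterior_y + drop / np.tan(np.deg2rad(self.roof_angle))

    @property
    def flexion_axis(self):
        return np.zeros(3), np.array([1.0, 0.0, 0.0])


class PosedTibia(NamedTuple):
    mesh: SurfaceMesh
    landmarks: dict
    transform: RigidTransform


@dataclass
class GroundTruth:
    """Analytic ground truth emitted alongside the meshes."""

    femoral_frame: FemoralFrame
    tibial_frame: TibialFrame
    femoral_landmarks: dict
    tibial_landmarks: dict
    footprints: dict  # (side, bundle) -> 3D point at 0 deg
    notch_width: float


@dataclass
class SyntheticKnee:
    """One generated knee: meshes + landmarks + ground truth + kinematics."""

    knee_id: str
    params: SyntheticKneeParams
    femur: SurfaceMesh
    tibia: SurfaceMesh  # at 0 degrees (full extension)
    truth: GroundTruth

    @property
    def femoral_landmarks(self) -> dict:
        return self.truth.femoral_landmarks

    def pose(self, angle: float) -> PosedTibia:
        return pose_at_flexion(self, angle)


# ---------------------------------------------------------------------------
# parameter validation


def validate_params(p: SyntheticKneeParams) -> None:
    """Raise InfeasibleParamsError naming the violated constraint."""
    problems = []
    for name in (
        "notch_width",
        "notch_height",
        "condyle_radius",
        "condyle_width",
        "plateau_semi_ml",
        "plateau_semi_ap",
        "plateau_thickness",
        "joint_gap",
        "mesh_resolution",
    ):
        if getattr(p, name) <= 0:
            problems.append(f"{name} must be > 0")
    if not (15.0 <= p.roof_angle <= 80.0):
        problems.append("roof_angle must lie in [15, 80] degrees")
    if p.notch_width < 4.0:
        problems.append("notch_width < 4 mm leaves no room for a graft")
    if p.roof_top_height <= p.roof_apex_height:
        problems.append("roof_top_height must exceed roof_apex_height")
    if p.roof_outlet_z >= p.roof_apex_height:
        problems.append("roof outlet must lie below the notch apex")
    if p.roof_anterior_clearance <= 0:
        problems.append("roof_anterior_clearance must be > 0")
    # the notch apex and every femoral footprint must lie on the condylar
    # inner wall (within the condyle disk, below the roof line)
    margin = 1.0
    rr = (p.condyle_radius - margin) ** 2
    apex = np.array([p.roof_posterior_y, p.roof_apex_height])
    if apex @ apex >= rr:
        problems.append("notch apex falls outside the condyle cross-section")
    frame = _femoral_frame(p)
    for bundle in ("AM", "PL"):
        f1, f2 = FOOTPRINT_FRACTIONS[("femur", bundle)]
        pt = frame.grid_point(f1, f2)
        if pt[1] ** 2 + pt[2] ** 2 >= rr:
            problems.append(
                f"femoral {bundle} footprint falls outside the condylar wall"
            )
    if problems:
        raise InfeasibleParamsError("; ".join(problems))


# ---------------------------------------------------------------------------
# analytic frames / landmarks / footprints


def _femoral_frame(p: SyntheticKneeParams) -> FemoralFrame:
    rho = np.deg2rad(p.roof_angle)
    u = np.array([0.0, np.cos(rho), -np.sin(rho)])  # posterior -> anterior
    h = np.array([0.0, -np.sin(rho), -np.cos(rho)])  # superior -> inferior
    n = np.array([-1.0, 0.0, 0.0])  # lateral wall outward (into the notch)
    origin = np.array(
        [p.notch_width / 2.0, p.roof_posterior_y, p.roof_apex_height]
    )
    depth = (p.roof_anterior_y - p.roof_posterior_y) / np.cos(rho)
    return FemoralFrame(
        origin=origin,
        height_axis=h,
        depth_axis=u,
        normal=n,
        total_height=p.notch_height,
        total_depth=float(depth),
    )


def _tibial_frame(p: SyntheticKneeParams) -> TibialFrame:
    origin = np.array(
        [-p.plateau_semi_ml, p.tibia_offset + p.plateau_semi_ap, p.plateau_top_z]
    )
    return TibialFrame(
        origin=origin,
        depth_axis=np.array([0.0, -1.0, 0.0]),
        width_axis=np.array([1.0, 0.0, 0.0]),
        normal=np.array([0.0, 0.0, 1.0]),
        total_depth=2.0 * p.plateau_semi_ap,
        total_width=2.0 * p.plateau_semi_ml,
    )


def _femoral_landmarks(p: SyntheticKneeParams, frame: FemoralFrame) -> dict:
    return {
        "notch_apex": frame.origin.copy(),
        "wall_posterior": frame.origin.copy(),
        "wall_anterior": frame.origin + frame.total_depth * frame.depth_axis,
        "wall_inferior": frame.origin + frame.total_height * frame.height_axis,
        "wall_normal": frame.normal.copy(),
    }


def _tibial_landmarks(p: SyntheticKneeParams, frame: TibialFrame) -> dict:
    cx = np.array([0.0, p.tibia_offset, p.plateau_top_z])
    return {
        "plateau_anterior": cx + np.array([0.0, p.plateau_semi_ap, 0.0]),
        "plateau_posterior": cx - np.array([0.0, p.plateau_semi_ap, 0.0]),
        "plateau_medial": cx - np.array([p.plateau_semi_ml, 0.0, 0.0]),
        "plateau_lateral": cx + np.array([p.plateau_semi_ml, 0.0, 0.0]),
    }


def _true_footprints(ffr: FemoralFrame, tfr: TibialFrame) -> dict:
    pts = {}
    for side, frame in (("femur", ffr), ("tibia", tfr)):
        for bundle in ("AM", "PL"):
            f1, f2 = FOOTPRINT_FRACTIONS[(side, bundle)]
            pts[(side, bundle)] = frame.grid_point(f1, f2)
        # footprints live on planar surfaces here, so the central midpoint
        # already lies on the surface
        pts[(side, "central")] = 0.5 * (pts[(side, "AM")] + pts[(side, "PL")])
    return pts


# ---------------------------------------------------------------------------
# mesh construction (watertight prisms / cylinders, no boolean engine)


def _circle_sections(p: SyntheticKneeParams, radius: float) -> int:
    n = int(np.ceil(2.0 * np.pi * radius / p.mesh_resolution / 4.0)) * 4
    return max(n, 32)


def _prism(poly2d: np.ndarray, lo: float, hi: float, axes) -> tuple:
    """Extrude a convex CCW polygon between two offsets along an axis.

    ``axes`` maps 2D polygon coords + extrusion offset into 3D: a tuple of
    three unit vectors (e1, e2, e_extrude) forming a right-handed set so
    that CCW polygons produce outward-oriented faces.
    """
    e1, e2, ax = (np.asarray(v, dtype=np.float64) for v in axes)
    k = len(poly2d)
    ring = poly2d[:, 0:1] * e1 + poly2d[:, 1:2] * e2
    bottom = ring + lo * ax
    top = ring + hi * ax
    verts = np.vstack([bottom, top])
    faces = []
    for i in range(k):
        j = (i + 1) % k
        faces.append([i, j, k + j])
        faces.append([i, k + j, k + i])
    for i in range(1, k - 1):  # top cap (+ax side), CCW from +ax
        faces.append([k, k + i, k + i + 1])
    for i in range(1, k - 1):  # bottom cap, reversed
        faces.append([0, i + 1, i])
    return verts, np.array(faces, dtype=np.int64)


def _concat(parts) -> tuple:
    verts = []
    faces = []
    off = 0
    for v, f in parts:
        verts.append(v)
        faces.append(f + off)
        off += len(v)
    return np.vstack(verts), np.vstack(faces)


def _build_femur(p: SyntheticKneeParams) -> SurfaceMesh:
    w2 = p.notch_width / 2.0
    R = p.condyle_radius
    sections = _circle_sections(p, R)
    parts = []
    for x0, x1 in ((w2, w2 + p.condyle_width), (-w2 - p.condyle_width, -w2)):
        tm = trimesh.creation.cylinder(
            radius=R, segment=[[x0, 0.0, 0.0], [x1, 0.0, 0.0]], sections=sections
        )
        parts.append((np.asarray(tm.vertices), np.asarray(tm.faces, dtype=np.int64)))
    roof_poly = np.array(
        [
            [p.roof_posterior_y, p.roof_apex_height],
            [p.roof_anterior_y, p.roof_outlet_z],
            [p.roof_anterior_y, p.roof_top_height],
            [p.roof_posterior_y, p.roof_top_height],
        ]
    )
    # polygon lives in the (y, z) plane, extruded along x; (y, z, x) is a
    # right-handed cyclic permutation
    parts.append(
        _prism(
            roof_poly,
            -w2,
            w2,
            axes=([0, 1, 0], [0, 0, 1], [1, 0, 0]),
        )
    )
    verts, faces = _concat(parts)
    mesh = SurfaceMesh(verts, faces, label="femur")
    validate_mesh(mesh)
    return mesh


def _build_tibia(p: SyntheticKneeParams) -> SurfaceMesh:
    n = _circle_sections(p, max(p.plateau_semi_ml, p.plateau_semi_ap))
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    ellipse = np.column_stack(
        [
            p.plateau_semi_ml * np.cos(theta),
            p.tibia_offset + p.plateau_semi_ap * np.sin(theta),
        ]
    )
    verts, faces = _prism(
        ellipse,
        p.plateau_top_z - p.plateau_thickness,
        p.plateau_top_z,
        axes=([1, 0, 0], [0, 1, 0], [0, 0, 1]),
    )
    mesh = SurfaceMesh(verts, faces, label="tibia")
    validate_mesh(mesh)
    return mesh


# ---------------------------------------------------------------------------
# public operations


def generate_knee(
    params: SyntheticKneeParams | None = None, knee_id: str = "knee_000"
) -> SyntheticKnee:
    """Generate one synthetic knee with its analytic ground-truth bundle.

    Identical parameters yield bit-identical meshes.  Raises
    InfeasibleParamsError listing every violated constraint.
    """
    p = params or SyntheticKneeParams()
    validate_params(p)
    ffr = _femoral_frame(p)
    tfr = _tibial_frame(p)
    truth = GroundTruth(
        femoral_frame=ffr,
        tibial_frame=tfr,
        femoral_landmarks=_femoral_landmarks(p, ffr),
        tibial_landmarks=_tibial_landmarks(p, tfr),
        footprints=_true_footprints(ffr, tfr),
        notch_width=p.notch_width,
    )
    return SyntheticKnee(
        knee_id=knee_id,
        params=p,
        femur=_build_femur(p),
        tibia=_build_tibia(p),
        truth=truth,
    )


def pose_at_flexion(knee: SyntheticKnee, angle: float) -> PosedTibia:
    """Pose the tibia (and its landmarks) at a flexion angle.

    Flexion is a hinge rotation about the transepicondylar x-axis; positive
    angles carry the tibia posteriorly, with 0 degrees the full-extension
    reference.  Angles outside the study set {0, 45, 90, 120} are accepted
    with a warning.
    """
    if float(angle) not in FLEXION_ANGLES:
        warnings.warn(
            f"flexion angle {angle} deg outside the study set {FLEXION_ANGLES}",
            stacklevel=2,
        )
    point, direction = knee.params.flexion_axis
    t = RigidTransform.about_axis(point, direction, -float(angle))
    posed = apply_transform(knee.tibia, t)
    lms = {k: t.apply(v) for k, v in knee.truth.tibial_landmarks.items()}
    return PosedTibia(mesh=posed, landmarks=lms, transform=t)


def generate_population(
    n: int,
    param_means: dict | None = None,
    param_sds: dict | None = None,
    seed: int = 0,
    base_params: SyntheticKneeParams | None = None,
) -> list:
    """Draw ``n`` knees with truncated-Gaussian parameter variation.

    Continuous parameters listed in ``param_sds`` (defaults:
    ``DEFAULT_POPULATION_SDS``) are drawn independently per knee and
    re-drawn (up to 100 attempts) until the parameter set is feasible.
    Reproducible for a fixed ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_params or SyntheticKneeParams()
    means = dict(param_means or {})
    sds = dict(DEFAULT_POPULATION_SDS if param_sds is None else param_sds)
    if any(s < 0 for s in sds.values()):
        raise ValueError("standard deviations must be >= 0")
    unknown = (set(means) | set(sds)) - {
        f.name for f in dataclasses.fields(SyntheticKneeParams)
    }
    if unknown:
        raise ValueError(f"unknown parameter(s): {', '.join(sorted(unknown))}")
    rng = np.random.default_rng(seed)
    knees = []
    for i in range(n):
        params = None
        for _attempt in range(100):
            draw = {}
            for name in sorted(set(means) | set(sds)):
                mu = means.get(name, getattr(base, name))
                sd = sds.get(name, 0.0)
                draw[name] = float(rng.normal(mu, sd)) if sd > 0 else float(mu)
            candidate = dataclasses.replace(
                base, seed=int(rng.integers(2**31)), **draw
            )
            try:
                validate_params(candidate)
            except InfeasibleParamsError:
                continue
            params = candidate
            break
        if params is None:
            raise InfeasibleParamsError(
                "could not draw feasible parameters within 100 attempts"
            )
        knees.append(generate_knee(params, knee_id=f"knee_{i:03d}"))
    return knees


# ---------------------------------------------------------------------------
# fixture I/O: femur.stl + tibia.stl + truth.json per knee


def write_knee(knee: SyntheticKnee, outdir) -> Path:
    from .mesh_core import write_stl

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_stl(knee.femur, outdir / "femur.stl")
    write_stl(knee.tibia, outdir / "tibia.stl")
    point, direction = knee.params.flexion_axis
    sidecar = {
        "knee_id": knee.knee_id,
        "params": dataclasses.asdict(knee.params),
        "femoral_landmarks": {
            k: np.asarray(v).tolist() for k, v in knee.femoral_landmarks.items()
        },
        "tibial_landmarks": {
            k: np.asarray(v).tolist()
            for k, v in knee.truth.tibial_landmarks.items()
        },
        "flexion_axis": {"point": point.tolist(), "direction": direction.tolist()},
        "notch_width": knee.truth.notch_width,
        "footprints": {
            f"{side}/{bundle}": np.asarray(v).tolist()
            for (side, bundle), v in knee.truth.footprints.items()
        },
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return outdir


def load_knee(knee_dir) -> SyntheticKnee:
    """Reload a written knee fixture (STL pair + ground-truth sidecar)."""
    from .mesh_core import read_stl

    knee_dir = Path(knee_dir)
    with open(knee_dir / "truth.json") as fh:
        sidecar = json.load(fh)
    params = SyntheticKneeParams(**sidecar["params"])
    femur = read_stl(knee_dir / "femur.stl", label="femur")
    tibia = read_stl(knee_dir / "tibia.stl", label="tibia")
    ffr = _femoral_frame(params)
    tfr = _tibial_frame(params)
    truth = GroundTruth(
        femoral_frame=ffr,
        tibial_frame=tfr,
        femoral_landmarks={
            k: np.asarray(v) for k, v in sidecar["femoral_landmarks"].items()
        },
        tibial_landmarks={
            k: np.asarray(v) for k, v in sidecar["tibial_landmarks"].items()
        },
        footprints={
            tuple(k.split("/")): np.asarray(v)
            for k, v in sidecar["footprints"].items()
        },
        notch_width=float(sidecar["notch_width"]),
    )
    return SyntheticKnee(
        knee_id=sidecar["knee_id"],
        params=params,
        femur=femur,
        tibia=tibia,
        truth=truth,
    )


__all__ = [
    "SyntheticKneeParams",
    "SyntheticKnee",
    "GroundTruth",
    "PosedTibia",
    "FLEXION_ANGLES",
    "DEFAULT_POPULATION_SDS",
    "generate_knee",
    "pose_at_flexion",
    "generate_population",
    "validate_params",
    "write_knee",
    "load_knee",
]
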