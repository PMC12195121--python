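"""Quadrant-grid reference frames and footprint localization.

The femoral frame is the classical quadrant grid drawn on the medial wall
of the lateral femoral condyle in a true lateral view: the superior border
runs through the highest point of the intercondylar notch (the Blumensaat
direction), the height axis runs superior->inferior perpendicular to it.
The tibial frame is the bounding rectangle of the plateau's cortical
outline in a top view.  Footprint centres are expressed as fractions of
the frame extents and projected onto the bone surface along the frame
normal.

Published percentage coordinates carried by this module (fractions of the
frame extents):

=======  ========  ==================  ==================
side     bundle    frac 1              frac 2
=======  ========  ==================  ==================
femur    AM        0.25  (height)      0.33  (depth)
femur    PL        0.451 (height)      0.50  (depth)
tibia    AM        0.35  (depth)       0.505 (width)
tibia    PL        0.464 (depth)       0.524 (width)
=======  ========  ==================  ==================

Femoral depth is measured FROM THE POSTERIOR border (the operational
definition used by the quadrant method); the opposite convention is
available through ``femoral_depth_from="anterior"``.  The central bundle
is the midpoint of the AM and PL surface points, re-projected onto the
surface, and is therefore derived rather than stored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._kernels import line_mesh_intersections
from .errors import FrameError, LandmarkError, ProjectionError
from .mesh_core import SurfaceMesh

FEMORAL_LANDMARK_NAMES = (
    "notch_apex",
    "wall_anterior",
    "wall_posterior",
    "wall_inferior",
    "wall_normal",  # direction, not a point
)
TIBIAL_LANDMARK_NAMES = (
    "plateau_anterior",
    "plateau_posterior",
    "plateau_medial",
    "plateau_lateral",
)

BUNDLES = ("AM", "central", "PL")

#: published footprint fractions keyed by (side, bundle); femoral depth is
#: measured from the posterior border.
FOOTPRINT_FRACTIONS = {
    ("femur", "AM"): (0.25, 0.33),
    ("femur", "PL"): (0.451, 0.50),
    ("tibia", "AM"): (0.35, 0.505),
    ("tibia", "PL"): (0.464, 0.524),
}

_COLLINEAR_TOL = 1e-6


def _unit(v, what="vector"):
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise FrameError(f"{what} has zero length")
    return v / n


@dataclass(frozen=True)
class FemoralFrame:
    """Quadrant grid on the medial wall of the lateral condyle.

    ``origin`` is the superior-posterior grid corner; ``depth_axis`` runs
    posterior->anterior along the superior border; ``height_axis`` runs
    superior->inferior; ``normal`` is the lateral-wall outward normal
    (pointing into the notch).
    """

    origin: np.ndarray
    height_axis: np.ndarray
    depth_axis: np.ndarray
    normal: np.ndarray
    total_height: float
    total_depth: float

    def grid_point(
        self, frac_height: float, frac_depth: float, depth_from: str = "posterior"
    ) -> np.ndarray:
        """In-plane grid point for the given fractional coordinates."""
        _check_fraction(frac_height)
        _check_fraction(frac_depth)
        fd = frac_depth if depth_from == "posterior" else 1.0 - frac_depth
        return (
            self.origin
            + frac_height * self.total_height * self.height_axis
            + fd * self.total_depth * self.depth_axis
        )


@dataclass(frozen=True)
class TibialFrame:
    """Bounding rectangle of the plateau cortical outline in top view.

    ``origin`` is the anterior-medial corner; ``depth_axis`` runs
    anterior->posterior, ``width_axis`` medial->lateral; ``normal`` points
    away from the joint surface (towards the femur).
    """

    origin: np.ndarray
    depth_axis: np.ndarray
    width_axis: np.ndarray
    normal: np.ndarray
    total_depth: float
    total_width: float

    def grid_point(self, frac_depth: float, frac_width: float) -> np.ndarray:
        _check_fraction(frac_depth)
        _check_fraction(frac_width)
        return (
            self.origin
            + frac_depth * self.total_depth * self.depth_axis
            + frac_width * self.total_width * self.width_axis
        )


@dataclass(frozen=True)
class FootprintSpec:
    """A named footprint position in fractional grid coordinates."""

    side: str  # "femur" | "tibia"
    bundle: str  # "AM" | "central" | "PL"
    frac_1: float | None = None  # femur: height; tibia: depth
    frac_2: float | None = None  # femur: depth; tibia: width

    def __post_init__(self):
        if self.side not in ("femur", "tibia"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.bundle not in BUNDLES:
            raise ValueError(f"unknown bundle {self.bundle!r}")
        if self.bundle == "central":
            if self.frac_1 is not None or self.frac_2 is not None:
                raise ValueError(
                    "central is derived from AM and PL; it has no stored fractions"
                )
        else:
            f1, f2 = self.frac_1, self.frac_2
            if f1 is None or f2 is None:
                f1, f2 = FOOTPRINT_FRACTIONS[(self.side, self.bundle)]
                object.__setattr__(self, "frac_1", f1)
                object.__setattr__(self, "frac_2", f2)
            _check_fraction(self.frac_1)
            _check_fraction(self.frac_2)


def _check_fraction(f):
    if f is None or not (0.0 <= float(f) <= 1.0):
        raise ValueError(f"fraction {f!r} outside [0, 1]")


def _require(landmarks: dict, names) -> None:
    missing = [n for n in names if n not in landmarks]
    if missing:
        raise LandmarkError(f"missing landmark(s): {', '.join(missing)}")


def fit_femoral_frame(femur: SurfaceMesh, landmarks: dict) -> FemoralFrame:
    """Construct the femoral quadrant frame from named landmark points.

    Required landmarks: ``notch_apex`` (highest point of the intercondylar
    notch), ``wall_anterior`` / ``wall_posterior`` (extreme points of the
    lateral-wall outline along the superior border), ``wall_inferior``
    (inferior extent of the wall outline) and ``wall_normal`` (outward
    direction of the lateral wall; a direction, not a point).

    The axes are orthonormalized with the depth (superior-border) axis as
    the primary direction; a consistency check on ``wall_inferior``
    detects swapped anterior/posterior landmarks.
    """
    _require(landmarks, FEMORAL_LANDMARK_NAMES)
    apex = np.asarray(landmarks["notch_apex"], dtype=np.float64)
    ant = np.asarray(landmarks["wall_anterior"], dtype=np.float64)
    post = np.asarray(landmarks["wall_posterior"], dtype=np.float64)
    inf = np.asarray(landmarks["wall_inferior"], dtype=np.float64)

    if np.linalg.norm(ant - post) < _COLLINEAR_TOL:
        raise FrameError("anterior and posterior landmarks coincide")
    u = _unit(ant - post, "depth axis")
    n_raw = _unit(landmarks["wall_normal"], "wall normal")
    if np.linalg.norm(np.cross(n_raw, u)) < _COLLINEAR_TOL:
        raise FrameError("wall normal is collinear with the superior border")
    n = _unit(n_raw - (n_raw @ u) * u, "wall normal")
    h = np.cross(n, u)
    if h @ (inf - apex) < 0:
        raise FrameError(
            "axis orientation inconsistent with the inferior landmark "
            "(anterior/posterior landmarks swapped?)"
        )
    origin = apex + ((post - apex) @ u) * u
    total_depth = float((ant - origin) @ u)
    total_height = float((inf - origin) @ h)
    if total_depth <= 0 or total_height <= 0:
        raise FrameError("non-positive frame extents; landmarks are degenerate")
    return FemoralFrame(
        origin=origin,
        height_axis=h,
        depth_axis=u,
        normal=n,
        total_height=total_height,
        total_depth=total_depth,
    )


def fit_tibial_frame(tibia: SurfaceMesh, landmarks: dict) -> TibialFrame:
    """Construct the tibial plateau frame from the four extreme cortical
    outline points in top view."""
    _require(landmarks, TIBIAL_LANDMARK_NAMES)
    ant = np.asarray(landmarks["plateau_anterior"], dtype=np.float64)
    post = np.asarray(landmarks["plateau_posterior"], dtype=np.float64)
    med = np.asarray(landmarks["plateau_medial"], dtype=np.float64)
    lat = np.asarray(landmarks["plateau_lateral"], dtype=np.float64)

    if np.linalg.norm(post - ant) < _COLLINEAR_TOL:
        raise FrameError("anterior and posterior plateau landmarks coincide")
    if np.linalg.norm(lat - med) < _COLLINEAR_TOL:
        raise FrameError("medial and lateral plateau landmarks coincide")
    d = _unit(post - ant, "depth axis")
    w_raw = _unit(lat - med, "width axis")
    if np.linalg.norm(np.cross(w_raw, d)) < _COLLINEAR_TOL:
        raise FrameError("plateau outline is degenerate (collinear landmarks)")
    w = _unit(w_raw - (w_raw @ d) * d, "width axis")
    normal = np.cross(d, w)
    origin = ant + ((med - ant) @ w) * w
    total_depth = float((post - ant) @ d)
    total_width = float((lat - med) @ w)
    if total_depth <= 0 or total_width <= 0:
        raise FrameError("non-positive plateau extents")
    return TibialFrame(
        origin=origin,
        depth_axis=d,
        width_axis=w,
        normal=normal,
        total_depth=total_depth,
        total_width=total_width,
    )


def _project_to_surface(point: np.ndarray, normal: np.ndarray, mesh: SurfaceMesh):
    """Nearest intersection of the line through ``point`` along ``normal``
    with the mesh surface."""
    ts = line_mesh_intersections(point, normal, mesh.triangles)
    if len(ts) == 0:
        raise ProjectionError(
            "projection ray missed the mesh; the reference frame is "
            "inconsistent with this surface"
        )
    t = ts[np.argmin(np.abs(ts))]
    return point + t * normal


def grid_to_point(
    frame,
    frac_1: float,
    frac_2: float,
    mesh: SurfaceMesh,
    femoral_depth_from: str = "posterior",
) -> np.ndarray:
    """Map fractional grid coordinates to a 3D point on the bone surface.

    For a FemoralFrame ``frac_1`` is the height fraction and ``frac_2`` the
    depth fraction; for a TibialFrame they are depth and width.  The
    in-plane grid point is projected onto the surface along the frame
    normal (nearest hit).
    """
    if isinstance(frame, FemoralFrame):
        p0 = frame.grid_point(frac_1, frac_2, depth_from=femoral_depth_from)
    elif isinstance(frame, TibialFrame):
        p0 = frame.grid_point(frac_1, frac_2)
    else:
        raise TypeError(f"unsupported frame type {type(frame).__name__}")
    return _project_to_surface(p0, frame.normal, mesh)


def footprint_center(
    spec: FootprintSpec,
    frame,
    mesh: SurfaceMesh,
    femoral_depth_from: str = "posterior",
) -> np.ndarray:
    """3D surface point of a footprint centre.

    AM and PL use their stored fractions; central is the midpoint of the
    AM and PL surface points re-projected onto the surface.
    """
    if spec.bundle == "central":
        am = footprint_center(
            FootprintSpec(spec.side, "AM"), frame, mesh, femoral_depth_from
        )
        pl = footprint_center(
            FootprintSpec(spec.side, "PL"), frame, mesh, femoral_depth_from
        )
        return _project_to_surface(0.5 * (am + pl), frame.normal, mesh)
    return grid_to_point(
        frame, spec.frac_1, spec.frac_2, mesh, femoral_depth_from=femoral_depth_from
    )


# ---------------------------------------------------------------------------
# landmark sidecar I/O (JSON with named 3D points / directions)


def load_landmarks(path) -> dict:
    """Load a landmark sidecar: JSON mapping names to 3-vectors."""
    with open(path) as fh:
        raw = json.load(fh)
    return {k: np.asarray(v, dtype=np.float64) for k, v in raw.items()}


def save_landmarks(landmarks: dict, path) -> None:
    serial = {k: np.asarray(v, dtype=np.float64).tolist() for k, v in landmarks.items()}
    Path(path).write_text(json.dumps(serial, indent=1, sort_keys=True))


__all__ = [
    "FemoralFrame",
    "TibialFrame",
    "FootprintSpec",
    "FOOTPRINT_FRACTIONS",
    "BUNDLES",
    "FEMORAL_LANDMARK_NAMES",
    "TIBIAL_LANDMARK_NAMES",
    "fit_femoral_frame",
    "fit_tibial_frame",
    "grid_to_point",
    "footprint_center",
    "load_landmarks",
    "save_landmarks",
]
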