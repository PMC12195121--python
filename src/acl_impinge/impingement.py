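"""Graft-notch impingement volume and notch-width measurement.

Impingement is measured against the entire femoral solid — the
intercondylar notch is simply where overlap physically occurs — so no
separate notch region-of-interest needs defining.  The notch width is the
widest medial-lateral gap between the condylar inner walls visible in the
anterior projection, conventionally read at 90 degrees of flexion (the
femur is the fixed body here, so the femoral measurement itself is
pose-invariant unless an explicit pose is supplied).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import NotchError
from .mesh_core import (
    DEFAULT_SPACING,
    RigidTransform,
    SurfaceMesh,
    apply_transform,
    intersection_volume,
)

FEMORAL_POSITIONS = ("AM", "central", "PL")
TIBIAL_POSITIONS = ("AM", "central", "PL")


@dataclass(frozen=True)
class ImpingementRecord:
    """One factorial cell of the simulation."""

    knee_id: str
    flexion_angle: float
    femoral_position: str
    tibial_position: str
    diameter: float  # mm
    volume: float  # mm^3
    spacing: float  # mm

    def __post_init__(self):
        if self.femoral_position not in FEMORAL_POSITIONS:
            raise ValueError(f"unknown femoral position {self.femoral_position!r}")
        if self.tibial_position not in TIBIAL_POSITIONS:
            raise ValueError(f"unknown tibial position {self.tibial_position!r}")
        if self.volume < 0:
            raise ValueError("impingement volume cannot be negative")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def impingement_volume(
    femur: SurfaceMesh, graft_probe: SurfaceMesh, spacing: float = DEFAULT_SPACING
) -> float:
    """Overlap volume between the femoral solid and the graft probe, mm^3."""
    return intersection_volume(femur, graft_probe, spacing)


def notch_width(
    femur: SurfaceMesh,
    pose: RigidTransform | None = None,
    ml_axis=(1.0, 0.0, 0.0),
    vertical_axis=(0.0, 0.0, 1.0),
    step: float = 0.25,
) -> float:
    """Widest medial-lateral opening of the intercondylar notch in the
    anterior view.

    The femur (optionally posed) is cut by horizontal planes at ``step``-mm
    vertical increments; at each height the cross-section bodies are
    projected onto the medial-lateral axis and the largest gap *between*
    bone intervals is taken.  The maximum such chord over all heights is
    the notch width.  Raises NotchError when no bounded gap exists (no
    notch concavity).
    """
    if pose is not None:
        femur = apply_transform(femur, pose)
    ml = np.asarray(ml_axis, dtype=np.float64)
    ml = ml / np.linalg.norm(ml)
    up = np.asarray(vertical_axis, dtype=np.float64)
    up = up / np.linalg.norm(up)

    tm = femur.trimesh
    z = femur.vertices @ up
    z_lo, z_hi = z.min(), z.max()
    best = 0.0
    for height in np.arange(z_lo + step / 2.0, z_hi, step):
        section = tm.section(plane_origin=up * height, plane_normal=up)
        if section is None:
            continue
        intervals = []
        for curve in section.discrete:
            proj = np.asarray(curve) @ ml
            intervals.append((proj.min(), proj.max()))
        gap = _largest_interior_gap(intervals)
        if gap > best:
            best = gap
    if best <= 0.0:
        raise NotchError(
            "no intercondylar notch found: the anterior projection has no "
            "bounded medial-lateral gap"
        )
    return best


def _largest_interior_gap(intervals) -> float:
    """Largest gap strictly between the merged intervals (0 if none)."""
    if len(intervals) < 2:
        return 0.0
    merged = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    best = 0.0
    for (_, hi_a), (lo_b, _) in zip(merged[:-1], merged[1:]):
        best = max(best, lo_b - hi_a)
    return best


__all__ = [
    "ImpingementRecord",
    "FEMORAL_POSITIONS",
    "TIBIAL_POSITIONS",
    "impingement_volume",
    "notch_width",
]
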