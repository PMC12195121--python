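"""Factorial simulation runner and result tables.

The default design is the full study factorial: 3 femoral x 3 tibial
footprint positions x 2 graft diameters (7, 9 mm) x 4 flexion angles
(0, 45, 90, 120 degrees) = 72 cells per knee.  Cells fail independently:
one bad landmark aborts a cell with a structured failure record, not the
whole batch.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import AclImpingeError
from .footprint_grid import (
    FootprintSpec,
    fit_femoral_frame,
    fit_tibial_frame,
    footprint_center,
)
from .graft_model import GraftCylinder, insertion_probe
from .impingement import ImpingementRecord, impingement_volume
from .mesh_core import DEFAULT_SPACING

logger = logging.getLogger("acl_impinge")

RECORD_COLUMNS = [
    "knee_id",
    "flexion_angle",
    "femoral_position",
    "tibial_position",
    "diameter",
    "volume",
    "spacing",
]


@dataclass(frozen=True)
class FactorialDesign:
    """The crossed simulation design."""

    femoral_positions: tuple = ("AM", "central", "PL")
    tibial_positions: tuple = ("AM", "central", "PL")
    diameters: tuple = (7.0, 9.0)
    flexion_angles: tuple = (0.0, 45.0, 90.0, 120.0)
    spacing: float = DEFAULT_SPACING

    def __post_init__(self):
        for name in (
            "femoral_positions",
            "tibial_positions",
            "diameters",
            "flexion_angles",
        ):
            value = tuple(getattr(self, name))
            if not value:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, value)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    @classmethod
    def from_config(cls, config: RunConfig) -> "FactorialDesign":
        return cls(
            femoral_positions=config.femoral_positions,
            tibial_positions=config.tibial_positions,
            diameters=config.diameters,
            flexion_angles=config.flexion_angles,
            spacing=config.spacing,
        )

    @property
    def n_footprint_configurations(self) -> int:
        return len(self.femoral_positions) * len(self.tibial_positions)

    def __len__(self) -> int:
        return (
            self.n_footprint_configurations
            * len(self.diameters)
            * len(self.flexion_angles)
        )

    def cells(self):
        """All (angle, femoral, tibial, diameter) cells, in run order."""
        return list(
            itertools.product(
                self.flexion_angles,
                self.femoral_positions,
                self.tibial_positions,
                self.diameters,
            )
        )


def run_knee(case, config: RunConfig | None = None, design: FactorialDesign | None = None):
    """Run the factorial design on one knee.

    ``case`` must provide ``knee_id``, ``femur`` (SurfaceMesh),
    ``femoral_landmarks`` (dict) and ``pose(angle) -> (mesh, landmarks, ...)``
    — both synthetic knees and loaded STL fixtures do.

    Returns ``(records, failures)``: one ImpingementRecord per successful
    cell (exactly ``len(design)`` when nothing fails) and one structured
    failure dict per aborted cell.
    """
    config = config or RunConfig()
    design = design or FactorialDesign.from_config(config)

    records: list[ImpingementRecord] = []
    failures: list[dict] = []

    fem_frame = fit_femoral_frame(case.femur, case.femoral_landmarks)
    fem_points = {
        pos: footprint_center(
            FootprintSpec("femur", pos),
            fem_frame,
            case.femur,
            femoral_depth_from=config.femoral_depth_from,
        )
        for pos in design.femoral_positions
    }

    for angle in design.flexion_angles:
        try:
            posed = case.pose(angle)
            tib_mesh, tib_landmarks = posed[0], posed[1]
            tib_frame = fit_tibial_frame(tib_mesh, tib_landmarks)
            tib_points = {
                pos: footprint_center(
                    FootprintSpec("tibia", pos), tib_frame, tib_mesh
                )
                for pos in design.tibial_positions
            }
        except AclImpingeError as exc:
            for fem_pos, tib_pos, diameter in itertools.product(
                design.femoral_positions, design.tibial_positions, design.diameters
            ):
                failures.append(
                    _failure(case.knee_id, angle, fem_pos, tib_pos, diameter, exc)
                )
            continue
        for fem_pos, tib_pos, diameter in itertools.product(
            design.femoral_positions, design.tibial_positions, design.diameters
        ):
            try:
                graft = GraftCylinder(
                    fem_points[fem_pos],
                    tib_points[tib_pos],
                    diameter,
                    n_segments=config.n_segments,
                )
                probe = insertion_probe(
                    graft,
                    cap_depth=config.cap_depth,
                    clip_point=(
                        fem_points[fem_pos] if config.clip_at_insertion else None
                    ),
                    clip_normal=(
                        fem_frame.normal if config.clip_at_insertion else None
                    ),
                )
                volume = impingement_volume(case.femur, probe, design.spacing)
                records.append(
                    ImpingementRecord(
                        knee_id=case.knee_id,
                        flexion_angle=float(angle),
                        femoral_position=fem_pos,
                        tibial_position=tib_pos,
                        diameter=float(diameter),
                        volume=volume,
                        spacing=design.spacing,
                    )
                )
            except AclImpingeError as exc:
                failures.append(
                    _failure(case.knee_id, angle, fem_pos, tib_pos, diameter, exc)
                )
        logger.info(
            "%s @ %g deg: %d records", case.knee_id, angle, len(records)
        )
    return records, failures


def _failure(knee_id, angle, fem_pos, tib_pos, diameter, exc) -> dict:
    return {
        "knee_id": knee_id,
        "flexion_angle": float(angle),
        "femoral_position": fem_pos,
        "tibial_position": tib_pos,
        "diameter": float(diameter),
        "error": f"{type(exc).__name__}: {exc}",
    }


def run_population(cases, config: RunConfig | None = None):
    """Run the design over several knees; returns (records, failures)."""
    records, failures = [], []
    for case in cases:
        r, f = run_knee(case, config=config)
        records.extend(r)
        failures.extend(f)
    return records, failures


# ---------------------------------------------------------------------------
# tables


def records_to_dataframe(records) -> pd.DataFrame:
    """Tidy long-format record table with a uniqueness check on the natural
    key (knee, angle, femoral, tibial, diameter)."""
    df = pd.DataFrame([r.to_dict() for r in records], columns=RECORD_COLUMNS)
    key = RECORD_COLUMNS[:5]
    if len(df) and df.duplicated(subset=key).any():
        dupes = df[df.duplicated(subset=key, keep=False)]
        raise ValueError(
            f"duplicate factorial cells in records:\n{dupes[key].to_string()}"
        )
    return df


def aggregate(df: pd.DataFrame, group_by) -> pd.DataFrame:
    """Mean +/- sd (n-1 denominator) of the overlap volume per factor cell."""
    if isinstance(df, (list, tuple)):
        df = records_to_dataframe(df)
    if df.empty:
        raise ValueError("no records to aggregate")
    group_by = list(group_by)
    out = (
        df.groupby(group_by, observed=True)["volume"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)  # singleton groups have no spread
    return out


def extension_table(df: pd.DataFrame, diameter: float, angle: float = 0.0) -> pd.DataFrame:
    """3x3 femoral-by-tibial table of 'mean ± sd' strings at one flexion
    angle and diameter (the headline result layout)."""
    sub = df[(df["flexion_angle"] == angle) & (df["diameter"] == diameter)]
    agg = aggregate(sub, ["femoral_position", "tibial_position"])
    agg["cell"] = agg.apply(lambda r: f"{r['mean']:.1f} ± {r['sd']:.1f}", axis=1)
    order = ["AM", "central", "PL"]
    table = agg.pivot(
        index="femoral_position", columns="tibial_position", values="cell"
    )
    return table.reindex(index=order, columns=order)


def write_records_csv(df: pd.DataFrame, path) -> None:
    """Deterministic CSV export (stable column order, fixed float format)."""
    df.to_csv(path, index=False, float_format="%.6f", columns=RECORD_COLUMNS)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing column(s): {', '.join(sorted(missing))}")
    return df


def plot_mean_volumes(df: pd.DataFrame, path, angles=(0.0, 45.0)) -> None:
    """Unstyled bar chart of mean overlap volume by tibial position and
    diameter at the given flexion angles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(angles), figsize=(5 * len(angles), 4), squeeze=False)
    for ax, angle in zip(axes[0], angles):
        sub = df[df["flexion_angle"] == angle]
        if sub.empty:
            continue
        agg = aggregate(sub, ["tibial_position", "diameter"])
        positions = ["AM", "central", "PL"]
        width = 0.35
        x = np.arange(len(positions))
        for k, d in enumerate(sorted(agg["diameter"].unique())):
            vals = [
                agg[(agg["tibial_position"] == p) & (agg["diameter"] == d)]["mean"]
                .squeeze()
                for p in positions
            ]
            vals = [float(v) if np.ndim(v) == 0 else 0.0 for v in vals]
            ax.bar(x + (k - 0.5) * width, vals, width, label=f"{d:g} mm")
        ax.set_xticks(x, positions)
        ax.set_xlabel("tibial position")
        ax.set_ylabel("mean overlap volume (mm³)")
        ax.set_title(f"{angle:g}° flexion")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


__all__ = [
    "FactorialDesign",
    "RECORD_COLUMNS",
    "run_knee",
    "run_population",
    "records_to_dataframe",
    "aggregate",
    "extension_table",
    "write_records_csv",
    "read_records_csv",
    "plot_mean_volumes",
]
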