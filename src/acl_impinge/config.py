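"""Run configuration: the factorial design plus numerical knobs, loadable
from YAML, and the versioned footprint-fraction table."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .mesh_core import DEFAULT_SPACING


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    femoral_positions: tuple = ("AM", "central", "PL")
    tibial_positions: tuple = ("AM", "central", "PL")
    diameters: tuple = (7.0, 9.0)  # mm
    flexion_angles: tuple = (0.0, 45.0, 90.0, 120.0)  # degrees
    spacing: float = DEFAULT_SPACING  # voxel edge, mm
    cap_depth: float = 0.0  # axial probe truncation at each end, mm
    clip_at_insertion: bool = True  # clip probe at the femoral wall plane
    femoral_depth_from: str = "posterior"  # quadrant depth convention
    n_segments: int = 128  # graft tessellation
    seed: int = 0  # population / synthetic-data seed

    def __post_init__(self):
        for name in ("femoral_positions", "tibial_positions", "diameters",
                     "flexion_angles"):
            value = tuple(getattr(self, name))
            if not value:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, value)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.femoral_depth_from not in ("posterior", "anterior"):
            raise ValueError("femoral_depth_from must be 'posterior' or 'anterior'")


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys raise."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def load_fraction_table() -> dict:
    """The packaged footprint-fraction table as
    {(side, bundle): (frac_1, frac_2)} plus the depth convention."""
    text = (
        resources.files("acl_impinge").joinpath("data/footprint_fractions.yaml")
    ).read_text()
    raw = yaml.safe_load(text)
    table = {}
    for bundle, d in raw["femur"].items():
        table[("femur", bundle)] = (float(d["height"]), float(d["depth"]))
    for bundle, d in raw["tibia"].items():
        table[("tibia", bundle)] = (float(d["depth"]), float(d["width"]))
    return {
        "fractions": table,
        "femoral_depth_from": raw.get("femoral_depth_from", "posterior"),
        "version": raw.get("version"),
    }


__all__ = ["RunConfig", "load_config", "save_config", "load_fraction_table"]
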