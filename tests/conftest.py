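import numpy as np
import pandas as pd
import pytest
import trimesh

from acl_impinge.experiment import run_knee
from acl_impinge.mesh_core import SurfaceMesh
from acl_impinge.synthetic_knee import generate_knee


def as_surface_mesh(tm: trimesh.Trimesh, label: str = "other") -> SurfaceMesh:
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), label)


def make_records_frame(volumes, fem, tib, knee=None, angle=0.0, diameter=9.0):
    """Hand-built record table for stats tests."""
    n = len(volumes)
    return pd.DataFrame(
        {
            "knee_id": knee if knee is not None else [f"k{i}" for i in range(n)],
            "flexion_angle": angle,
            "femoral_position": fem,
            "tibial_position": tib,
            "diameter": diameter,
            "volume": volumes,
            "spacing": 0.5,
        }
    )


@pytest.fixture(scope="session")
def default_knee():
    return generate_knee()


@pytest.fixture(scope="session")
def one_knee_run(default_knee):
    """Full default factorial on the default knee (shared: ~half a minute)."""
    records, failures = run_knee(default_knee)
    return records, failures


@pytest.fixture
def unit_cube():
    box = trimesh.creation.box(extents=[1.0, 1.0, 1.0])
    box.apply_translation([0.5, 0.5, 0.5])
    return as_surface_mesh(box)
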