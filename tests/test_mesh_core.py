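"""Mesh kernel: I/O, transforms, signed volume, voxelization, Boolean
intersection volume, and convex half-space clipping."""

import numpy as np
import pytest
import trimesh

from conftest import as_surface_mesh

from acl_impinge._kernels import parity_inside
from acl_impinge.errors import MeshError, WatertightError
from acl_impinge.mesh_core import (
    RigidTransform,
    SurfaceMesh,
    apply_transform,
    enclosed_volume,
    inside_points,
    intersection_volume,
    read_stl,
    slice_halfspace,
    validate_mesh,
    voxelize,
    write_stl,
)


def random_rigid(seed=0):
    rng = np.random.default_rng(seed)
    return RigidTransform.about_axis(
        rng.normal(size=3), rng.normal(size=3), float(rng.uniform(10, 170))
    )


# ---------------------------------------------------------------------------
# STL I/O


def test_read_stl_unit_cube(tmp_path, unit_cube):
    path = tmp_path / "cube.stl"
    write_stl(unit_cube, path)
    mesh = read_stl(path, label="femur")
    assert len(mesh.vertices) == 8  # per-facet duplicates merged
    assert len(mesh.faces) == 12
    assert mesh.label == "femur"
    assert enclosed_volume(mesh) == pytest.approx(1.0, rel=1e-12)


def test_read_stl_missing_file(tmp_path):
    with pytest.raises(IOError):
        read_stl(tmp_path / "nope.stl")


def test_read_stl_open_mesh_reports_boundary_edges(tmp_path, unit_cube):
    open_mesh = SurfaceMesh(unit_cube.vertices, unit_cube.faces[:-1])
    path = tmp_path / "open.stl"
    open_mesh.trimesh.export(str(path))
    with pytest.raises(WatertightError) as err:
        read_stl(path)
    # one deleted triangle leaves exactly 3 boundary edges
    assert err.value.open_edges == 3
    assert "3 open edges" in str(err.value)


# ---------------------------------------------------------------------------
# transforms


def test_identity_transform_is_noop(unit_cube):
    out = apply_transform(unit_cube, RigidTransform.identity())
    np.testing.assert_allclose(out.vertices, unit_cube.vertices)
    np.testing.assert_array_equal(out.faces, unit_cube.faces)


def test_rigid_transform_preserves_volume(unit_cube):
    t = RigidTransform.about_axis([0, 0, 0], [0, 0, 1], 90.0)
    assert enclosed_volume(apply_transform(unit_cube, t)) == pytest.approx(
        1.0, rel=1e-9
    )
    t2 = random_rigid(3)
    assert enclosed_volume(apply_transform(unit_cube, t2)) == pytest.approx(
        1.0, rel=1e-9
    )


def test_transform_roundtrip(unit_cube):
    t = random_rigid(7)
    back = apply_transform(apply_transform(unit_cube, t), t.inverse())
    assert np.abs(back.vertices - unit_cube.vertices).max() < 1e-6


def test_reflection_rejected():
    with pytest.raises(MeshError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


# ---------------------------------------------------------------------------
# enclosed volume


@pytest.mark.parametrize(
    "builder, expected, rel",
    [
        (lambda: trimesh.creation.box(extents=[1, 1, 1]), 1.0, 1e-12),
        (
            lambda: trimesh.creation.icosphere(subdivisions=4, radius=5.0),
            4.0 / 3.0 * np.pi * 125.0,
            0.005,
        ),
        (
            lambda: trimesh.creation.cylinder(
                radius=4.5, segment=[[0, 0, 0], [0, 0, 30]], sections=256
            ),
            np.pi * 4.5**2 * 30,
            0.002,
        ),
    ],
    ids=["cube", "icosphere", "cylinder"],
)
def test_enclosed_volume_closed_forms(builder, expected, rel):
    mesh = as_surface_mesh(builder())
    assert enclosed_volume(mesh) == pytest.approx(expected, rel=rel)


def test_enclosed_volume_rejects_open_mesh(unit_cube):
    open_mesh = SurfaceMesh(unit_cube.vertices, unit_cube.faces[:-1])
    with pytest.raises(WatertightError):
        enclosed_volume(open_mesh)


def test_inverted_orientation_rejected(unit_cube):
    flipped = SurfaceMesh(unit_cube.vertices, unit_cube.faces[:, ::-1])
    with pytest.raises(MeshError):
        validate_mesh(flipped)


# ---------------------------------------------------------------------------
# voxelization


def test_voxelize_unit_cube(unit_cube):
    grid = voxelize(unit_cube, spacing=0.1)
    assert grid.volume == pytest.approx(1.0, rel=0.03)


def test_voxelize_sphere():
    sph = as_surface_mesh(trimesh.creation.icosphere(subdivisions=4, radius=5.0))
    grid = voxelize(sph, spacing=0.2)
    assert grid.volume == pytest.approx(4.0 / 3.0 * np.pi * 125.0, rel=0.01)


def test_voxelize_too_coarse_warns():
    tiny = as_surface_mesh(trimesh.creation.icosphere(subdivisions=1, radius=0.05))
    with pytest.warns(UserWarning, match="too coarse"):
        grid = voxelize(tiny, spacing=1.0)
    assert not grid.occupancy.any()


# ---------------------------------------------------------------------------
# intersection volume


def test_disjoint_aabbs_short_circuit(unit_cube):
    far = apply_transform(unit_cube, RigidTransform(np.eye(3), np.array([5.0, 0, 0])))
    assert intersection_volume(unit_cube, far, 0.5) == 0.0


def test_self_intersection_is_own_volume(unit_cube):
    assert intersection_volume(unit_cube, unit_cube, 0.1) == pytest.approx(
        1.0, rel=0.03
    )


def test_cylinder_halfspace_closed_form():
    # half-space z < 0 realized as a large box
    cyl = as_surface_mesh(
        trimesh.creation.cylinder(
            radius=3.5, segment=[[0, 0, -12], [0, 0, 12]], sections=256
        )
    )
    box = trimesh.creation.box(extents=[40, 40, 24])
    box.apply_translation([0, 0, -12])
    half = np.pi * 3.5**2 * 12
    assert intersection_volume(cyl, as_surface_mesh(box), 0.25) == pytest.approx(
        half, rel=0.01
    )


def test_cylinder_slab_closed_form():
    cyl = as_surface_mesh(
        trimesh.creation.cylinder(
            radius=4.5, segment=[[0, 0, -15], [0, 0, 15]], sections=256
        )
    )
    slab = as_surface_mesh(trimesh.creation.box(extents=[40, 40, 10]))
    assert intersection_volume(cyl, slab, 0.25) == pytest.approx(
        np.pi * 4.5**2 * 10, rel=0.01
    )


def test_intersection_symmetry_exact():
    cyl = as_surface_mesh(
        trimesh.creation.cylinder(
            radius=3.5, segment=[[0.3, -0.2, -15], [0.3, -0.2, 15]], sections=64
        )
    )
    slab = as_surface_mesh(trimesh.creation.box(extents=[30, 30, 8]))
    assert intersection_volume(cyl, slab, 0.5) == intersection_volume(slab, cyl, 0.5)


def test_monotone_under_nested_supersets():
    slab = as_surface_mesh(trimesh.creation.box(extents=[30, 30, 9]))
    vols = []
    for radius in (2.0, 3.0, 4.0, 5.0):
        cyl = as_surface_mesh(
            trimesh.creation.cylinder(
                radius=radius, segment=[[0, 0, -12], [0, 0, 12]], sections=128
            )
        )
        vols.append(intersection_volume(slab, cyl, 0.5))
    assert all(a <= b for a, b in zip(vols, vols[1:]))


def test_rigid_invariance_of_intersection():
    cyl = as_surface_mesh(
        trimesh.creation.cylinder(
            radius=4.5, segment=[[0, 0, -15], [0, 0, 15]], sections=128
        )
    )
    slab = as_surface_mesh(trimesh.creation.box(extents=[40, 40, 10]))
    v0 = intersection_volume(cyl, slab, 0.5)
    t = random_rigid(11)
    v1 = intersection_volume(apply_transform(cyl, t), apply_transform(slab, t), 0.5)
    # both estimates carry O(spacing) discretization error
    assert v1 == pytest.approx(v0, rel=0.03)


def test_winding_number_matches_parity_oracle(default_knee):
    rng = np.random.default_rng(5)
    for mesh in (
        as_surface_mesh(
            trimesh.creation.cylinder(
                radius=4.0, segment=[[0, 0, 0], [3, 4, 20]], sections=64
            )
        ),
        default_knee.femur,
    ):
        pts = rng.uniform(mesh.bounds[0] - 2, mesh.bounds[1] + 2, size=(250, 3))
        np.testing.assert_array_equal(
            inside_points(mesh, pts), parity_inside(pts, mesh.triangles)
        )


# ---------------------------------------------------------------------------
# convex half-space clipping


def test_slice_halfspace_closed_form():
    cyl = as_surface_mesh(
        trimesh.creation.cylinder(
            radius=4.5, segment=[[0, 0, 0], [0, 0, 30]], sections=128
        )
    )
    full = enclosed_volume(cyl)
    kept = slice_halfspace(cyl, [0, 0, 10], [0, 0, -1])  # keep z <= 10
    validate_mesh(kept)
    assert enclosed_volume(kept) == pytest.approx(full / 3.0, rel=1e-6)


def test_slice_halfspace_through_cap_center():
    # plane through an end-cap centre vertex: the hard case for cap closure
    cyl = as_surface_mesh(
        trimesh.creation.cylinder(
            radius=4.5, segment=[[0, 0, 0], [0, 0, 30]], sections=128
        )
    )
    kept = slice_halfspace(cyl, [0, 0, 0], [1, 0, 1])
    validate_mesh(kept)
    assert 0 < enclosed_volume(kept) < enclosed_volume(cyl)


def test_slice_halfspace_noop_and_empty(unit_cube):
    out = slice_halfspace(unit_cube, [0, 0, -1], [0, 0, 1])
    assert enclosed_volume(out) == pytest.approx(1.0)
    with pytest.raises(MeshError):
        slice_halfspace(unit_cube, [0, 0, 2], [0, 0, 1])
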