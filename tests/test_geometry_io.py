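import numpy as np
import pytest
import trimesh

from rootshape.geometry_io import (
    LabelVolume,
    TriangleMesh,
    extract_isosurface,
    mesh_properties,
    rasterize_mesh,
    read_mesh,
    read_volume,
    resample_volume,
    threshold_segment,
    vertex_normals,
    write_mesh,
    write_volume,
)
from rootshape._geom import SurfaceDistanceQuery

TETRA = TriangleMesh(
    vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
    faces=[[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]],
)


@pytest.mark.parametrize("fmt", ["ply", "stl", "obj", "vtp"])
def test_mesh_roundtrip_preserves_geometry(tmp_path, fmt):
    path = tmp_path / f"tet.{fmt}"
    write_mesh(TETRA, path)
    back = read_mesh(path)
    # STL stores a triangle soup; welding restores shared vertices
    assert back.n_vertices == 4
    assert back.n_faces == 4
    orig = np.array(sorted(map(tuple, TETRA.vertices)))
    got = np.array(sorted(map(tuple, back.vertices)))
    np.testing.assert_allclose(got, orig, atol=1e-6)


@pytest.mark.parametrize("fmt", ["ply", "vtp"])
def test_vertex_channel_roundtrip(tmp_path, fmt, icosphere3_r2):
    mesh = icosphere3_r2.copy()
    mesh.point_data["signed_distance"] = np.linspace(-1, 1, mesh.n_vertices)
    path = tmp_path / f"sphere.{fmt}"
    write_mesh(mesh, path)
    back = read_mesh(path)
    np.testing.assert_allclose(
        back.point_data["signed_distance"],
        mesh.point_data["signed_distance"],
        atol=1e-6,
    )


def test_stl_welding_restores_closed_topology(tmp_path, icosphere3_r2):
    path = tmp_path / "sphere.stl"
    write_mesh(icosphere3_r2, path)
    back = read_mesh(path)
    assert back.n_vertices == icosphere3_r2.n_vertices
    assert back.euler_characteristic() == 2
    assert back.is_watertight()


def test_resample_identity_is_voxel_exact():
    vol = LabelVolume(np.ones((5, 6, 7), np.uint8), (0.4, 0.4, 0.4))
    out = resample_volume(vol, 0.4)
    np.testing.assert_array_equal(out.voxels, vol.voxels)


def test_resample_preserves_cube_volume():
    # 8 mm cube sampled at 0.4 mm -> 20 voxels per side, 512 mm^3
    vol = LabelVolume(np.ones((20, 20, 20), np.uint8), (0.4, 0.4, 0.4))
    out = resample_volume(vol, 0.3)
    assert out.foreground_volume() == pytest.approx(512.0, rel=0.05)
    np.testing.assert_array_equal(np.unique(out.voxels), [1])


def test_resample_preserves_sphere_volume():
    sph = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
    vol = rasterize_mesh(TriangleMesh.from_trimesh(sph), 0.4)
    out = resample_volume(vol, 0.3)
    analytic = 4.0 / 3.0 * np.pi * 125.0
    assert out.foreground_volume() == pytest.approx(analytic, rel=0.03)


def test_threshold_segment_recovers_mask(rng):
    truth = np.zeros((40, 40, 40), bool)
    truth[8:30, 10:28, 12:26] = True
    intensity = np.where(truth, 1000.0, 200.0) + rng.normal(0, 50, truth.shape)
    seg = threshold_segment(intensity, 600, 1400)
    inter = np.logical_and(seg.voxels > 0, truth).sum()
    dice = 2 * inter / (seg.voxels.sum() + truth.sum())
    assert dice >= 0.98


def test_threshold_segment_empty_window_errors():
    with pytest.raises(ValueError, match="no foreground"):
        threshold_segment(np.zeros((4, 4, 4)), 10, 20)


def test_threshold_segment_keeps_largest_component():
    intensity = np.zeros((20, 20, 20))
    intensity[2:10, 2:10, 2:10] = 100.0  # 512 voxels
    intensity[15:17, 15:17, 15:18] = 100.0  # 10-ish voxels, separate
    seg = threshold_segment(intensity, 50, 150)
    assert seg.voxels[16, 16, 16] == 0
    assert seg.voxels[5, 5, 5] == 1
    assert seg.n_components() == 1


def test_isosurface_sphere_area():
    sph = trimesh.creation.icosphere(subdivisions=4, radius=6.0)
    vol = rasterize_mesh(TriangleMesh.from_trimesh(sph), 0.3)
    surf = extract_isosurface(vol)
    props = mesh_properties(surf)
    assert props.surface_area == pytest.approx(4 * np.pi * 36, rel=0.02)
    assert surf.is_genus_zero()


def test_isosurface_single_voxel():
    vol = LabelVolume(np.ones((1, 1, 1), np.uint8), (0.3, 0.3, 0.3))
    surf = extract_isosurface(vol, smooth_iterations=0)
    props = mesh_properties(surf)
    # marching cubes turns one voxel into the octahedron through the
    # half-spacing crossings: volume (4/3) (s/2)^3
    assert props.enclosed_volume == pytest.approx(4 / 3 * 0.15**3, rel=0.01)
    assert surf.is_watertight()


def test_isosurface_empty_volume_errors():
    with pytest.raises(ValueError, match="empty"):
        extract_isosurface(LabelVolume(np.zeros((4, 4, 4), np.uint8), (1, 1, 1)))


def test_rasterize_sphere_volume():
    sph = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
    vol = rasterize_mesh(TriangleMesh.from_trimesh(sph), 0.3)
    analytic = 4.0 / 3.0 * np.pi * 125.0
    assert vol.foreground_volume() == pytest.approx(analytic, rel=0.03)


def test_rasterize_spacing_too_large_warns(icosphere3_r2):
    with pytest.warns(UserWarning, match="exceeds"):
        vol = rasterize_mesh(icosphere3_r2, 50.0)
    assert vol.voxels.sum() == 0


def test_rasterize_extract_roundtrip_on_tooth(template_tooth):
    vol = rasterize_mesh(template_tooth, 0.3)
    surf = extract_isosurface(vol)
    query = SurfaceDistanceQuery(template_tooth.vertices, template_tooth.faces)
    d, _, _ = query.query(surf.vertices)
    assert d.mean() < 0.3


def test_volume_consistency_isosurface_vs_voxel_count(template_tooth):
    vol = rasterize_mesh(template_tooth, 0.3)
    assert vol.voxels.sum() >= 1000
    surf = extract_isosurface(vol)
    props = mesh_properties(surf)
    assert props.enclosed_volume == pytest.approx(vol.foreground_volume(), rel=0.05)


def test_mesh_properties_cube():
    box = TriangleMesh.from_trimesh(trimesh.creation.box(extents=(1, 1, 1)))
    props = mesh_properties(box)
    assert props.surface_area == pytest.approx(6.0)
    assert props.enclosed_volume == pytest.approx(1.0)
    # inward orientation must not flip the reported volume sign
    inverted = TriangleMesh(box.vertices, box.faces[:, ::-1])
    assert mesh_properties(inverted).enclosed_volume == pytest.approx(1.0)


def test_mesh_properties_icosphere_analytic():
    sph = TriangleMesh.from_trimesh(trimesh.creation.icosphere(subdivisions=4, radius=2.0))
    props = mesh_properties(sph)
    assert props.surface_area == pytest.approx(16 * np.pi, rel=0.01)
    assert props.enclosed_volume == pytest.approx(32 / 3 * np.pi, rel=0.01)


def test_mesh_properties_open_mesh_has_no_volume():
    open_mesh = TriangleMesh(TETRA.vertices, TETRA.faces[:3])
    assert mesh_properties(open_mesh).enclosed_volume is None


def test_vertex_normals_sphere_radial(icosphere4):
    normals = vertex_normals(icosphere4)
    radial = icosphere4.vertices / np.linalg.norm(
        icosphere4.vertices, axis=1, keepdims=True
    )
    ang = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", normals, radial), -1, 1)))
    assert ang.max() < 2.0


def test_vertex_normals_flat_patch_and_antisymmetry():
    patch = TriangleMesh(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], [[0, 1, 2], [0, 2, 3]]
    )
    n = vertex_normals(patch)
    np.testing.assert_allclose(n, np.tile([0, 0, 1.0], (4, 1)), atol=1e-12)
    flipped = TriangleMesh(patch.vertices, patch.faces[:, ::-1])
    np.testing.assert_allclose(vertex_normals(flipped), -n, atol=1e-12)


@pytest.mark.parametrize("suffix", ["nrrd", "nii.gz"])
def test_volume_io_roundtrip(tmp_path, suffix):
    vox = np.zeros((6, 7, 8), np.uint8)
    vox[2:4, 3:5, 1:6] = 1
    vol = LabelVolume(vox, (0.3, 0.3, 0.4), origin=(1.0, -2.0, 0.5))
    path = tmp_path / f"label.{suffix}"
    write_volume(vol, path)
    back = read_volume(path)
    np.testing.assert_array_equal(back.voxels, vol.voxels)
    np.testing.assert_allclose(back.spacing, vol.spacing, atol=1e-6)
    np.testing.assert_allclose(back.origin, vol.origin, atol=1e-6)
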