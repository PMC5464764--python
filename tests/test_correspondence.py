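import numpy as np
import pytest
import trimesh

from rootshape._geom import kabsch
from rootshape.correspondence import (
    PointDistributionModel,
    canonicalize_parameterization,
    correspond,
    evaluate_pdm,
    fit_spharm,
    icosphere_faces,
    icosphere_sampling,
    read_pdm,
    spherical_parameterization,
    write_pdm,
)
from rootshape.geometry_io import TriangleMesh
from rootshape.synthetic import (
    APEX_DIRECTION,
    MESIAL_DIRECTION,
    ToothParams,
    generate_tooth,
)


@pytest.mark.parametrize("level,expected", [(1, 12), (4, 162), (10, 1002)])
def test_icosahedral_sampling_counts(level, expected):
    pts = icosphere_sampling(level)
    assert len(pts) == expected
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)


def test_icosahedral_sampling_is_deterministic_and_closed():
    a = icosphere_sampling(5)
    b = icosphere_sampling(5)
    np.testing.assert_array_equal(a, b)
    mesh = TriangleMesh(icosphere_sampling(5), icosphere_faces(5))
    assert mesh.is_genus_zero()
    assert mesh.to_trimesh().volume > 0  # outward orientation


def test_sphere_self_map_accuracy(icosphere4):
    smap = spherical_parameterization(icosphere4)
    u = smap.unit_directions
    v = icosphere4.vertices / np.linalg.norm(icosphere4.vertices, axis=1, keepdims=True)
    R, _ = kabsch(v, u)
    err = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", v @ R.T, u), -1, 1)))
    assert err.max() < 5.0
    assert not smap.flipped_triangles(icosphere4.faces).any()


def test_prolate_ellipsoid_poles_at_long_axis_extremes():
    base = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    mesh = TriangleMesh(base.vertices * np.array([4.0, 4.0, 13.0]), base.faces)
    smap = spherical_parameterization(mesh)
    poles_z = sorted(abs(mesh.vertices[i, 2]) for i in (smap.north, smap.south))
    assert poles_z[0] > 12.0  # both poles near the +-13 mm extremes


def test_torus_is_rejected():
    torus = trimesh.creation.torus(major_radius=5.0, minor_radius=1.5)
    with pytest.raises(ValueError, match="sphere-topology"):
        spherical_parameterization(TriangleMesh.from_trimesh(torus))


def test_sphere_spharm_energy_is_first_degree(icosphere3_r2):
    # a sphere of radius r centred at the origin has coordinate channels
    # that are pure degree-1 harmonics with total norm r*sqrt(4*pi)
    smap = spherical_parameterization(icosphere3_r2)
    coeffs = fit_spharm(icosphere3_r2, smap, degree=8)
    energy = coeffs.degree_energy()
    assert energy[1] / energy.sum() > 0.99
    assert np.sqrt(energy[1]) == pytest.approx(2.0 * np.sqrt(4 * np.pi), rel=0.01)


def test_translated_sphere_centroid_recovery(icosphere3_r2):
    center = np.array([1.0, -2.0, 0.5])
    mesh = TriangleMesh(icosphere3_r2.vertices + center, icosphere3_r2.faces)
    smap = spherical_parameterization(mesh)
    coeffs = fit_spharm(mesh, smap, degree=8)
    pdm = evaluate_pdm(coeffs, level=10)
    np.testing.assert_allclose(pdm.points.mean(axis=0), center, atol=0.15)


def test_tooth_spharm_residual(template_tooth):
    smap = spherical_parameterization(template_tooth)
    coeffs = fit_spharm(template_tooth, smap, degree=12)
    assert coeffs.rms_residual < 0.25


def test_underdetermined_fit_errors():
    tetra = TriangleMesh(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
        [[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]],
    )
    import rootshape.correspondence as C

    smap = C.SphericalMap(
        theta=np.array([0.0, np.pi / 2, np.pi / 2, np.pi]),
        phi=np.array([0.0, 0.0, np.pi, 0.0]),
        north=0,
        south=3,
    )
    with pytest.raises(ValueError, match="underdetermined"):
        fit_spharm(tetra, smap, degree=12)


def test_residual_decreases_with_degree(template_tooth):
    smap = spherical_parameterization(template_tooth)
    residuals = [fit_spharm(template_tooth, smap, degree=L).rms_residual for L in (4, 8, 12)]
    assert residuals[0] > residuals[1] > residuals[2]


def test_canonical_ellipsoid_geometry():
    base = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    mesh = TriangleMesh(base.vertices * np.array([13.0, 4.0, 3.5]), base.faces)
    smap = spherical_parameterization(mesh)
    coeffs = fit_spharm(mesh, smap, degree=10)
    canon = canonicalize_parameterization(coeffs, apex_direction=(1, 0, 0))
    pdm = evaluate_pdm(canon, level=10)
    bbox = pdm.points.max(axis=0) - pdm.points.min(axis=0)
    np.testing.assert_allclose(bbox, [26.0, 8.0, 7.0], rtol=0.03)


def test_correspondence_is_deterministic(template_tooth):
    a = correspond(template_tooth, APEX_DIRECTION, MESIAL_DIRECTION)
    b = correspond(template_tooth, APEX_DIRECTION, MESIAL_DIRECTION)
    np.testing.assert_array_equal(a.points, b.points)


def test_homology_under_rigid_transform(template_pdm, template_tooth):
    # a rigidly moved copy must yield the rigidly moved PDM
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec([0.3, -0.2, 0.4]).as_matrix()
    t = np.array([5.0, -3.0, 2.0])
    moved = TriangleMesh(template_tooth.vertices @ R.T + t, template_tooth.faces)
    pdm = correspond(moved, R @ APEX_DIRECTION, R @ MESIAL_DIRECTION)
    expected = template_pdm.points @ R.T + t
    err = np.linalg.norm(pdm.points - expected, axis=1)
    assert err.mean() < 0.3


def test_noisy_twin_correspondence_stability():
    pdms = [
        correspond(
            generate_tooth(ToothParams(noise_sigma=0.05, seed=s)),
            APEX_DIRECTION,
            MESIAL_DIRECTION,
        )
        for s in (1, 2)
    ]
    d = np.linalg.norm(pdms[0].points - pdms[1].points, axis=1)
    assert d.mean() < 0.3


def test_evaluate_pdm_sphere_and_level(icosphere4):
    mesh = TriangleMesh(icosphere4.vertices * 2.0, icosphere4.faces)
    smap = spherical_parameterization(mesh)
    coeffs = fit_spharm(mesh, smap, degree=12)
    pdm = evaluate_pdm(coeffs, level=10)
    assert pdm.n_points == 1002
    radii = np.linalg.norm(pdm.points - pdm.points.mean(axis=0), axis=1)
    np.testing.assert_allclose(radii, 2.0, rtol=0.005)


def test_pdm_mesh_is_watertight(template_pdm):
    assert template_pdm.to_mesh().is_genus_zero()


def test_pdm_text_roundtrip(tmp_path, template_pdm):
    path = tmp_path / "tooth.pdm"
    write_pdm(template_pdm, path)
    header = path.read_text().splitlines()[0]
    assert header == "n=1002 level=10"
    back = read_pdm(path)
    np.testing.assert_array_equal(back.points, template_pdm.points)
    assert back.level == 10


def test_pdm_point_count_validation():
    with pytest.raises(ValueError, match="1002"):
        PointDistributionModel(np.zeros((100, 3)), level=10)
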