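import numpy as np
import pytest

from rootshape.correspondence import PointDistributionModel, icosphere_sampling
from rootshape.morphometry import (
    diverging_rgb,
    mean_shape,
    median_shape,
    pdm_normals,
    render_overlay,
    signed_distance_map,
    vector_differences,
)


def _sphere_pdm(radius, level=10, center=(0.0, 0.0, 0.0)):
    pts = icosphere_sampling(level) * radius + np.asarray(center)
    return PointDistributionModel(pts, level=level)


def test_mean_of_identical_shapes(template_pdm):
    out = mean_shape([template_pdm, template_pdm.copy(), template_pdm.copy()])
    np.testing.assert_allclose(out.points, template_pdm.points, atol=1e-12)


def test_mean_of_concentric_spheres_is_middle_sphere():
    mean = mean_shape([_sphere_pdm(9.0), _sphere_pdm(11.0)])
    radii = np.linalg.norm(mean.points, axis=1)
    np.testing.assert_allclose(radii, 10.0, atol=1e-9)


def test_mean_approaches_template_under_noise(rng):
    sigma, n = 0.05, 20
    base = _sphere_pdm(10.0).points
    cohort = [
        PointDistributionModel(base + rng.normal(0, sigma, base.shape), level=10)
        for _ in range(n)
    ]
    mean = mean_shape(cohort)
    err = np.linalg.norm(mean.points - base, axis=1)
    bound = 3 * sigma / np.sqrt(n)
    assert (err <= bound * np.sqrt(3)).mean() >= 0.95


def test_mean_minimizes_sum_of_squares(rng):
    # brute-force check on a 2-shape toy cohort: no candidate beats the mean
    a = _sphere_pdm(9.0).points
    b = _sphere_pdm(11.0).points
    mean = mean_shape([_sphere_pdm(9.0), _sphere_pdm(11.0)]).points

    def ssd(c):
        return ((a - c) ** 2).sum() + ((b - c) ** 2).sum()

    best = ssd(mean)
    for _ in range(50):
        candidate = mean + rng.normal(0, 0.3, mean.shape)
        assert ssd(candidate) >= best


def test_median_shape_is_robust_to_minority():
    cohort = [_sphere_pdm(10.0) for _ in range(6)] + [_sphere_pdm(14.0) for _ in range(3)]
    med = median_shape(cohort)
    np.testing.assert_allclose(np.linalg.norm(med.points, axis=1), 10.0, atol=1e-9)


def test_mean_warns_when_not_aligned():
    with pytest.warns(UserWarning, match="aligned"):
        mean_shape([_sphere_pdm(10.0), _sphere_pdm(10.0, center=(40, 0, 0))])


def test_vector_differences_basic(template_pdm):
    assert np.all(vector_differences(template_pdm, template_pdm) == 0)
    shifted = template_pdm.copy()
    shifted.points = shifted.points + [1.0, 0.0, 0.0]
    d = vector_differences(shifted, template_pdm)
    np.testing.assert_allclose(d, np.tile([1.0, 0, 0], (1002, 1)))


def test_vector_differences_sphere_radial():
    d = vector_differences(_sphere_pdm(10.5), _sphere_pdm(10.0))
    np.testing.assert_allclose(np.linalg.norm(d, axis=1), 0.5, atol=1e-9)
    dirs = d / np.linalg.norm(d, axis=1, keepdims=True)
    radial = icosphere_sampling(10)
    np.testing.assert_allclose(dirs, radial, atol=1e-9)


def test_count_mismatch_errors(template_pdm):
    small = PointDistributionModel(np.zeros((162, 3)), level=4)
    with pytest.raises(ValueError, match="mismatch"):
        vector_differences(template_pdm, small)


@pytest.mark.parametrize("r,expected", [(10.5, 0.5), (9.5, -0.5)])
def test_signed_distance_sphere(r, expected):
    sdm = signed_distance_map(_sphere_pdm(r), _sphere_pdm(10.0))
    np.testing.assert_allclose(sdm, expected, atol=0.01)


def test_signed_distance_zero_for_identical(template_pdm):
    np.testing.assert_array_equal(
        signed_distance_map(template_pdm, template_pdm), 0.0
    )


def test_signed_distance_magnitude_and_sign_flip(template_pdm, rng):
    other = template_pdm.copy()
    other.points = other.points + rng.normal(0, 0.1, other.points.shape)
    normals = pdm_normals(template_pdm)
    sdm = signed_distance_map(other, template_pdm, normals)
    mags = np.linalg.norm(other.points - template_pdm.points, axis=1)
    np.testing.assert_allclose(np.abs(sdm), mags, atol=1e-12)
    flipped = signed_distance_map(other, template_pdm, -normals)
    np.testing.assert_allclose(flipped, -sdm, atol=1e-12)


def test_colormap_endpoints_and_monotonicity():
    rgb = diverging_rgb(np.array([0.0, -1.5, -2.0, 1.5, 0.75]), 1.5)
    np.testing.assert_array_equal(rgb[0], [255, 255, 255])  # zero -> white
    np.testing.assert_array_equal(rgb[1], [0, 0, 255])  # -limit -> blue
    np.testing.assert_array_equal(rgb[2], [0, 0, 255])  # clamped
    np.testing.assert_array_equal(rgb[3], [255, 0, 0])  # +limit -> red
    assert abs(int(rgb[4][1]) - 127) <= 1  # half-saturated red
    values = np.linspace(-2, 2, 101)
    ramp = diverging_rgb(values, 1.5).astype(int)
    redness = ramp[:, 0].astype(int) - ramp[:, 2].astype(int)
    assert np.all(np.diff(redness) >= 0)


def test_render_overlay_channels(template_pdm):
    sdm = np.linspace(-2, 2, template_pdm.n_points)
    mesh = render_overlay(sdm, template_pdm, scale_limit=1.5)
    assert set(mesh.point_data) >= {"signed_distance", "rgb"}
    np.testing.assert_array_equal(mesh.point_data["signed_distance"], sdm)
    with pytest.raises(ValueError):
        render_overlay(sdm, template_pdm, scale_limit=0.0)
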