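"""Cross-section extraction, polar contour segmentation, centerline
refinement, and robust radius smoothing."""

import numpy as np
import pytest

from clotseg import (
    Centerline,
    ContourParams,
    LumenContour,
    contours_along_centerline,
    extract_cross_section,
    radius_profile,
    refine_centerline,
    segment_lumen_contour,
    smooth_radius,
)

TANGENT_Y = np.array([0.0, 1.0, 0.0])


@pytest.fixture(scope="module")
def params():
    return ContourParams()


def _tube_patch(phantom, center, tangent=TANGENT_Y, resolution=0.25, extent=24.0):
    return extract_cross_section(phantom.image, center, tangent, extent, resolution)


def test_cross_section_shows_true_disc(patent_phantom, params):
    """Patch orthogonal to the tube axis: thresholded disc area ~ pi r^2."""
    patch = _tube_patch(patent_phantom, center=(7.0, 0.0, 0.0), extent=16.0)
    area = (patch.values > 145.0).sum() * patch.resolution_mm**2
    # half-voxel edge placement of the interpolated level set
    assert area == pytest.approx(np.pi * 3.0**2, rel=0.10)
    assert not patch.out_of_bounds
    # the wide default patch does leave the volume and says so
    assert _tube_patch(patent_phantom, center=(7.0, 0.0, 0.0)).out_of_bounds


def test_cross_section_center_displacement(patent_phantom):
    """Moving the plane origin 1 mm off-axis moves the disc 1 mm in-plane."""
    on = _tube_patch(patent_phantom, center=(7.0, 0.0, 0.0))
    off = _tube_patch(patent_phantom, center=(7.0, 0.0, 1.0))

    def disc_centroid(p):
        m = p.values > 145.0
        ij = np.argwhere(m).mean(axis=0)
        half = (np.asarray(p.values.shape) - 1) / 2.0
        return (ij - half) * p.resolution_mm

    shift = disc_centroid(off) - disc_centroid(on)
    assert np.linalg.norm(shift) == pytest.approx(1.0, abs=0.15)


def test_tangent_reversal_preserves_radius(patent_phantom, params):
    a = _tube_patch(patent_phantom, (7.0, 0.0, 0.0), TANGENT_Y)
    b = _tube_patch(patent_phantom, (7.0, 0.0, 0.0), -TANGENT_Y)
    ca = segment_lumen_contour(a, params, 250.0)
    cb = segment_lumen_contour(b, params, 250.0)
    assert ca.polar_radii.mean() == pytest.approx(cb.polar_radii.mean(), abs=1e-6)


def test_contour_recovers_disc_radius(thin_tube_phantom, params):
    """Noise-free 2 mm disc (250 HU on 40 HU): radius to the patch
    resolution."""
    patch = _tube_patch(thin_tube_phantom, (7.0, 10.0, 0.0))
    c = segment_lumen_contour(patch, params, 250.0)
    assert c.reliable
    assert c.polar_radii.mean() == pytest.approx(2.0, abs=params.resolution_mm)


def test_contour_unreliable_without_lumen(straight_phantom, params):
    """A section through the thrombus has no contrast disc."""
    # occlusion spans segment arc 12-22, tube runs y=-20..20 -> thrombus center y=-3
    patch = _tube_patch(straight_phantom, (-7.0, -3.0, 0.0))
    c = segment_lumen_contour(patch, params, 250.0)
    assert not c.reliable


def test_calcification_leaves_far_angles_unchanged(params):
    from clotseg import generate_phantom, tube_phantom_spec

    clean = generate_phantom(tube_phantom_spec(occlusion_start_mm=None))
    spotted = generate_phantom(tube_phantom_spec(
        occlusion_start_mm=None, calcifications=[((10.0, 0.0, 0.0), 1.2, 700.0)]
    ))
    pc = _tube_patch(clean, (7.0, 0.0, 0.0))
    ps = _tube_patch(spotted, (7.0, 0.0, 0.0))
    cc = segment_lumen_contour(pc, params, 250.0)
    cs = segment_lumen_contour(ps, params, 250.0)
    # angles whose rays point away from the spot (the spot sits along +u or
    # +/-v depending on the frame; compare the half furthest from it)
    spot_dir = np.array([10.0, 0.0, 0.0]) - pc.center
    ray_dirs = (np.outer(np.cos(cc.angles), pc.u) + np.outer(np.sin(cc.angles), pc.v))
    away = ray_dirs @ spot_dir < 0
    np.testing.assert_allclose(
        cs.polar_radii[away], cc.polar_radii[away], atol=params.resolution_mm
    )


def test_center_of_mass_recovers_displaced_disc(patent_phantom, params):
    """Patch centered 1 mm off-axis: the centroid lands back on the axis."""
    patch = _tube_patch(patent_phantom, (7.0, 0.0, 1.0))
    c = segment_lumen_contour(patch, params, 250.0)
    assert np.linalg.norm(c.center_of_mass - np.array([7.0, 0.0, 0.0])) <= 0.3


def test_refine_centerline_reduces_axis_distance(patent_phantom, params):
    """An input curve offset 1 mm off-axis refines toward the true axis."""
    ys = np.arange(-14.0, 14.5, 0.5)
    offset_pts = np.column_stack([np.full_like(ys, 8.0), ys, np.zeros_like(ys)])
    contours = contours_along_centerline(
        patent_phantom.image, Centerline(offset_pts), params, 250.0
    )
    refined = refine_centerline(contours)
    true_axis = np.array([7.0, 0.0, 0.0])
    d_in = np.abs(offset_pts[:, 0] - 7.0).mean()
    d_out = np.linalg.norm(refined.points[:, [0, 2]] - true_axis[[0, 2]], axis=1).mean()
    assert d_out < d_in
    assert d_out < 0.3


def test_refined_centerline_is_fixed_point(patent_phantom, params):
    """Contours already centered on the axis: refinement changes nothing
    beyond the contour-resolution scale."""
    ys = np.arange(-14.0, 14.5, 0.5)
    axis_pts = np.column_stack([np.full_like(ys, 7.0), ys, np.zeros_like(ys)])
    contours = contours_along_centerline(
        patent_phantom.image, Centerline(axis_pts), params, 250.0
    )
    refined = refine_centerline(contours)
    assert len(refined) == len(axis_pts)
    np.testing.assert_allclose(refined.points, axis_pts, atol=0.15)


def test_single_reliable_contour_degenerate():
    c = LumenContour(
        plane_origin=np.zeros(3), plane_normal=TANGENT_Y,
        u=np.array([1.0, 0, 0]), v=np.array([0, 0, 1.0]),
        angles=np.zeros(1), polar_radii=np.ones(1),
        center_of_mass=np.zeros(3), reliable=True,
    )
    out = refine_centerline([c])
    assert out.degenerate


def _circle_contour(radius, K=32, center=np.zeros(3)):
    angles = np.linspace(0, 2 * np.pi, K, endpoint=False)
    return LumenContour(
        plane_origin=center, plane_normal=TANGENT_Y,
        u=np.array([1.0, 0, 0]), v=np.array([0, 0, 1.0]),
        angles=angles, polar_radii=np.full(K, float(radius)) if np.isscalar(radius) else radius,
        center_of_mass=center, reliable=True,
    )


def test_radius_profile_circle_exact():
    assert radius_profile([_circle_contour(2.0)])[0] == pytest.approx(2.0, abs=1e-12)


def test_radius_profile_ellipse_matches_polygon_oracle():
    """Mean center-to-boundary distance of a 2 x 3 mm ellipse against a
    dense polygonal oracle."""
    a, b = 3.0, 2.0
    K = 32
    angles = np.linspace(0, 2 * np.pi, K, endpoint=False)
    r = a * b / np.sqrt((b * np.cos(angles)) ** 2 + (a * np.sin(angles)) ** 2)
    got = radius_profile([_circle_contour(r)])[0]
    dense = np.linspace(0, 2 * np.pi, 200001)
    oracle = np.mean(a * b / np.sqrt((b * np.cos(dense)) ** 2 + (a * np.sin(dense)) ** 2))
    assert got == pytest.approx(oracle, abs=2e-3)


def test_radius_profile_single_doubled_angle():
    K = 32
    r = np.full(K, 2.0)
    r[5] = 4.0
    base = radius_profile([_circle_contour(np.full(K, 2.0))])[0]
    spiked = radius_profile([_circle_contour(r)])[0]
    assert spiked - base == pytest.approx(2.0 / K, abs=1e-12)


def test_radius_profile_zero_for_unreliable():
    c = _circle_contour(2.0)
    c.reliable = False
    assert radius_profile([c])[0] == 0.0


def test_smooth_radius_constant_fixed_point():
    r = np.full(30, 2.0)
    np.testing.assert_allclose(smooth_radius(r), r, atol=1e-12)


def test_smooth_radius_suppresses_spike_only():
    r = np.full(30, 2.0)
    r[15] = 4.0
    out = smooth_radius(r, iterations=2, sigma_radius=0.5, spacing_mm=0.5)
    assert abs(out[15] - 2.0) < abs(out[15] - 4.0)
    others = np.delete(out, 15)
    assert np.abs(others - 2.0).max() < 0.1


def test_smooth_radius_iterations_compose():
    rng = np.random.default_rng(0)
    r = 2.0 + 0.05 * rng.standard_normal(40)
    once_twice = smooth_radius(smooth_radius(r, iterations=1), iterations=1)
    twice = smooth_radius(r, iterations=2)
    np.testing.assert_allclose(once_twice, twice, atol=1e-12)


def test_smooth_radius_preserves_mean_of_clean_profile():
    rng = np.random.default_rng(1)
    r = 2.5 + 0.04 * rng.standard_normal(60)
    out = smooth_radius(r)
    assert abs(out.mean() - r.mean()) / r.mean() < 0.01


def test_smooth_radius_preserves_step_edge():
    """A genuine lumen->thrombus step must not be blurred into the
    sub-threshold band (edge-preservation of the robust weights)."""
    r = np.concatenate([np.full(20, 3.0), np.zeros(20)])
    out = smooth_radius(r)
    assert out[18] > 2.5 and out[21] < 0.1


def test_contour_params_validation():
    with pytest.raises(ValueError):
        ContourParams(sigma_inside=-1.0)
    with pytest.raises(ValueError):
        ContourParams(fraction_outside=1.5)
    with pytest.raises(ValueError):
        ContourParams(n_angles=8)
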