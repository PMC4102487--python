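"""Tubular masking, adaptive thresholds, region growing, morphology,
length/volume measurement."""

from collections import deque

import numpy as np
import pytest
from scipy import ndimage

from clotseg import (
    Centerline,
    ImageVolume,
    OcclusionExtent,
    ThresholdPair,
    build_tubular_mask,
    compute_thresholds,
    measure,
    morph_open,
    region_grow,
)


def _straight_cl(length=30.0, step=0.5, radius=None):
    ys = np.arange(0.0, length + step / 2, step)
    pts = np.column_stack([np.full_like(ys, 10.0), ys, np.full_like(ys, 10.0)])
    radii = None if radius is None else np.full(len(ys), radius)
    return Centerline(pts, radii=radii)


def _grid(shape=(40, 70, 40), spacing=0.5, fill=0.0):
    return ImageVolume(np.full(shape, fill, dtype=np.float32), (spacing,) * 3)


def test_tubular_mask_cylinder_volume():
    """10 mm extent of a 2 mm-radius tube, no dilation: voxel volume within
    one lateral voxel layer of pi r^2 L."""
    grid = _grid()
    cl = _straight_cl()
    ext = OcclusionExtent(10.0, 20.0)
    mask = build_tubular_mask(grid, cl, np.full(len(cl), 2.0), ext, dilation_voxels=0)
    vol = mask.data.sum() * grid.voxel_volume
    assert abs(vol - np.pi * 4.0 * 10.0) < 2 * np.pi * 2.0 * 10.0 * 0.5


def test_tubular_mask_dilation_grows_boundary_shell():
    grid = _grid()
    cl = _straight_cl()
    ext = OcclusionExtent(10.0, 20.0)
    base = build_tubular_mask(grid, cl, np.full(len(cl), 2.0), ext, dilation_voxels=0)
    dil = build_tubular_mask(grid, cl, np.full(len(cl), 2.0), ext, dilation_voxels=1)
    assert dil.data.sum() > base.data.sum()
    assert np.all(dil.data[base.data])  # monotone growth
    shell = ndimage.binary_dilation(base.data, np.ones((3, 3, 3), bool))
    assert np.all(shell[dil.data])  # growth confined to the 1-voxel shell


def test_tubular_mask_empty_extent():
    grid = _grid()
    cl = _straight_cl()
    mask = build_tubular_mask(grid, cl, np.full(len(cl), 2.0), OcclusionExtent.none_found())
    assert not mask.data.any()


def test_thresholds_follow_published_formulas():
    """t_max = contralateral mean - SD; t_min = occluded extent min + SD."""
    img = _grid(shape=(24, 24, 8), spacing=1.0)
    # contralateral samples 170/230/170/230 -> mean 200, sd 30 -> t_max 170
    for i, v in enumerate([170.0, 230.0, 170.0, 230.0]):
        img.data[4 + i, 4, 4] = v
    con = Centerline([[4 + i, 4, 4] for i in range(4)])
    # occluded samples inside the extent: 40/60 -> min 40, sd 10 -> t_min 50
    img.data[12, 2:8, 4] = [40.0, 60.0, 40.0, 60.0, 40.0, 60.0]
    occ = Centerline([[12, 2 + i, 4] for i in range(6)])
    ext = OcclusionExtent(0.5, 4.5)  # two 1-mm steps inside -> samples at s=3,4
    th = compute_thresholds(img, con, occ, ext)
    assert th.t_max == pytest.approx(170.0)
    assert th.contralateral_sd == pytest.approx(30.0)
    assert th.t_min == pytest.approx(50.0)
    assert not th.degenerate


def test_thresholds_zero_sd_edge():
    img = _grid(shape=(16, 16, 8), spacing=1.0, fill=250.0)
    con = Centerline([[4, 4, 4], [4, 8, 4]])
    occ = Centerline([[10, 2 + i, 4] for i in range(6)])
    img.data[10] = 45.0
    th = compute_thresholds(img, con, occ, OcclusionExtent(0.5, 4.5))
    assert th.t_max == pytest.approx(250.0)  # sd = 0
    assert th.t_min == pytest.approx(45.0)


def test_thresholds_degenerate_flagged():
    assert ThresholdPair(t_min=200.0, t_max=100.0).degenerate
    assert not ThresholdPair(t_min=50.0, t_max=170.0).degenerate


def _flood_fill_oracle(candidate, seed):
    """Independent BFS flood fill over 26-neighbors."""
    out = np.zeros_like(candidate)
    if not candidate[seed]:
        return out
    q = deque([seed])
    out[seed] = True
    offsets = [o for o in np.ndindex((3, 3, 3)) if o != (1, 1, 1)]
    shape = candidate.shape
    while q:
        cur = q.popleft()
        for o in offsets:
            nb = tuple(np.asarray(cur) + np.asarray(o) - 1)
            if all(0 <= nb[a] < shape[a] for a in range(3)):
                if candidate[nb] and not out[nb]:
                    out[nb] = True
                    q.append(nb)
    return out


def test_region_grow_matches_flood_fill_oracle(rng):
    img = ImageVolume(rng.uniform(0.0, 100.0, size=(12, 12, 12)).astype(np.float32), (1.0,) * 3)
    mask = ImageVolume(np.zeros((12, 12, 12), bool), (1.0,) * 3)
    mask.data[2:10, 2:10, 2:10] = True
    th = ThresholdPair(t_min=45.0, t_max=55.0)
    img.data[5, 5, 5] = 50.0  # guarantee a growable seed
    grown, flags = region_grow(img, np.array([5.0, 5.0, 5.0]), mask, th)
    candidate = mask.data & (img.data >= 45.0 - 1e-6) & (img.data <= 55.0 + 1e-6)
    oracle = _flood_fill_oracle(candidate, (5, 5, 5))
    assert np.array_equal(grown.data, oracle)
    assert not flags


def test_region_grow_uniform_block():
    img = _grid(shape=(16, 16, 16), spacing=1.0, fill=50.0)
    mask = ImageVolume(np.zeros((16, 16, 16), bool), (1.0,) * 3)
    mask.data[4:12, 4:12, 4:12] = True
    grown, _ = region_grow(img, np.array([8.0, 8.0, 8.0]), mask,
                           ThresholdPair(45.0, 55.0))
    assert np.array_equal(grown.data, mask.data)


def test_region_grow_only_seeded_blob():
    """Two thrombus-intensity blobs separated by a contrast gap: only the
    seeded one is returned (verified against connected components)."""
    img = _grid(shape=(30, 30, 10), spacing=1.0, fill=50.0)
    img.data[:, 14:16, :] = 250.0  # contrast bridge splits the mask
    mask = ImageVolume(np.zeros((30, 30, 10), bool), (1.0,) * 3)
    mask.data[10:20, 5:25, 3:7] = True
    grown, _ = region_grow(img, np.array([15.0, 8.0, 5.0]), mask,
                           ThresholdPair(45.0, 55.0))
    labels, _ = ndimage.label(mask.data & (img.data < 100), np.ones((3, 3, 3)))
    assert np.array_equal(grown.data, labels == labels[15, 8, 5])
    assert grown.data[15, 8, 5] and not grown.data[15, 20, 5]


def test_region_grow_seed_recovery_and_failure():
    img = _grid(shape=(16, 16, 16), spacing=1.0, fill=50.0)
    img.data[8, 4, 8] = 200.0  # seed voxel itself out of range
    mask = ImageVolume(np.ones((16, 16, 16), bool), (1.0,) * 3)
    th = ThresholdPair(45.0, 55.0)
    recovery = np.array([[8.0, 5.0, 8.0], [8.0, 6.0, 8.0]])
    grown, flags = region_grow(img, np.array([8.0, 4.0, 8.0]), mask, th,
                               recovery_points=recovery)
    assert grown.data.any() and any("recovered" in f for f in flags)
    # no recovery available -> empty with failure flag
    grown2, flags2 = region_grow(img, np.array([8.0, 4.0, 8.0]), mask,
                                 ThresholdPair(190.0, 195.0))
    assert not grown2.data.any() and "seed-outside-thresholds" in flags2


def test_region_grow_single_connected_component():
    img = _grid(shape=(16, 16, 16), spacing=1.0, fill=50.0)
    mask = ImageVolume(np.ones((16, 16, 16), bool), (1.0,) * 3)
    grown, _ = region_grow(img, np.array([8.0, 8.0, 8.0]), mask, ThresholdPair(45.0, 55.0))
    _, n = ndimage.label(grown.data, np.ones((3, 3, 3)))
    assert n == 1


def test_morph_open_identities():
    solid = ImageVolume(np.zeros((16, 16, 16), bool), (1.0,) * 3)
    solid.data[3:13, 3:13, 3:13] = True
    assert np.array_equal(morph_open(solid, 1).data, solid.data)  # large solid unchanged
    lone = ImageVolume(np.zeros((10, 10, 10), bool), (1.0,) * 3)
    lone.data[5, 5, 5] = True
    assert not morph_open(lone, 1).data.any()  # isolated voxel removed


def test_morph_open_idempotent(rng):
    m = ImageVolume(rng.random((20, 20, 20)) > 0.4, (1.0,) * 3)
    once = morph_open(m, 1)
    twice = morph_open(once, 1)
    assert np.array_equal(once.data, twice.data)


def test_measure_volume_is_exact_voxel_count():
    mask = ImageVolume(np.zeros((20, 20, 20), bool), (0.5,) * 3)
    mask.data[5:10, 5:9, 5:10] = True  # 100 voxels
    cl = Centerline([[2.5, 0.0, 2.5], [2.5, 9.5, 2.5]])
    _, vol, _ = measure(mask, cl)
    assert vol == 100 * 0.125


def test_measure_cylinder_length():
    grid = _grid()
    cl = _straight_cl(radius=2.0)
    ext = OcclusionExtent(10.0, 20.0)
    mask = build_tubular_mask(grid, cl, np.full(len(cl), 2.0), ext, dilation_voxels=0)
    length, _, _ = measure(mask, cl)
    assert length == pytest.approx(10.0, abs=0.5)


def test_measure_curved_arc_not_chord():
    """Quarter circle of 20 mm radius: the projected length is the
    ~31.4 mm arc, not the 28.3 mm chord."""
    theta = np.linspace(0, np.pi / 2, 80)
    pts = np.column_stack([
        25.0 + 20.0 * np.cos(theta), 25.0 + 20.0 * np.sin(theta), np.full_like(theta, 10.0)
    ])
    cl = Centerline(pts)
    grid = ImageVolume(np.zeros((120, 120, 40), bool), (0.5,) * 3)
    from scipy.spatial import cKDTree

    idx = np.indices(grid.shape).reshape(3, -1).T * 0.5
    d, _ = cKDTree(cl.resample(0.2).points).query(idx, workers=-1)
    grid.data[tuple((idx[d <= 1.5] * 2).astype(int).T)] = True
    length, _, _ = measure(grid, cl)
    arc = np.pi / 2 * 20.0
    assert length == pytest.approx(arc, abs=1.0)
    assert length > 29.0  # clearly not the chord


def test_measure_empty_mask():
    mask = ImageVolume(np.zeros((5, 5, 5), bool), (1.0,) * 3)
    length, vol, flags = measure(mask, _straight_cl(4.0, 1.0))
    assert (length, vol) == (0.0, 0.0) and "empty-mask" in flags


def test_measurements_shift_equivariant():
    """Adding a global HU offset and recomputing thresholds leaves the
    grown mask unchanged (the formulas are shift-equivariant)."""
    img = _grid(shape=(40, 40, 40), spacing=0.5, fill=40.0)
    cl_occ = _straight_cl(length=15.0)  # runs at x = z = 10 mm, inside the grid
    cl_con = Centerline(cl_occ.points + np.array([5.0, 0, 0]))
    idx = np.indices(img.shape).reshape(3, -1).T * 0.5
    from scipy.spatial import cKDTree

    d, _ = cKDTree(cl_occ.resample(0.2).points).query(idx, workers=-1)
    tube_sel = d <= 2.0
    img.data[tuple((idx[tube_sel] * 2).astype(int).T)] = 45.0
    dc, _ = cKDTree(cl_con.resample(0.2).points).query(idx, workers=-1)
    img.data[tuple((idx[dc <= 2.0] * 2).astype(int).T)] = 250.0
    ext = OcclusionExtent(2.0, 13.0)
    mask = build_tubular_mask(img, cl_occ, np.full(len(cl_occ), 2.0), ext, 1)

    def run(image):
        th = compute_thresholds(image, cl_con, cl_occ, ext)
        grown, _ = region_grow(image, cl_occ.point_at(2.5), mask, th)
        return th, grown

    th0, g0 = run(img)
    th1, g1 = run(img.like(img.data + 100.0))
    assert th1.t_min == pytest.approx(th0.t_min + 100.0)
    assert th1.t_max == pytest.approx(th0.t_max + 100.0)
    assert np.array_equal(g0.data, g1.data)
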