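"""Thrombus segmentation and measurement.

A tube around the occluded-side centerline — carrying the contralateral
radius profile, restricted to the detected occlusion extent and dilated
by one voxel — masks out surrounding tissue and contrast-enhanced lumen.
Within it, seeded region growing collects 26-connected voxels between two
adaptive thresholds: the upper one from the contralateral centerline
intensities (mean − SD), the lower one from the occluded centerline
intensities inside the estimated thrombus (min + SD).  A morphological
opening smooths the result, and length/volume are measured from the mask:
volume as voxel count × voxel volume, length as the arc-length span of
the mask extremities projected onto the centerline.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import Centerline, ImageVolume, OcclusionExtent, ThresholdPair

__all__ = [
    "build_tubular_mask",
    "compute_thresholds",
    "region_grow",
    "morph_open",
    "measure",
]

_CUBE26 = np.ones((3, 3, 3), dtype=bool)


def build_tubular_mask(
    grid: ImageVolume,
    cl_occluded: Centerline,
    radii_contralateral: np.ndarray,
    extent: OcclusionExtent,
    dilation_voxels: int = 1,
) -> ImageVolume:
    """Tube around the occluded centerline with the contralateral radius,
    restricted to the occlusion extent and dilated by ``dilation_voxels``
    (cubic 2n+1 kernel)."""
    empty = grid.like(np.zeros(grid.shape, dtype=bool))
    if extent is None or extent.empty:
        empty.data = empty.data  # explicit empty mask
        return empty
    radii = np.asarray(radii_contralateral, dtype=float)
    if len(radii) != len(cl_occluded):
        raise ValueError("need one contralateral radius per occluded centerline point")
    s = cl_occluded.arc_length
    sel = (s >= extent.proximal_s) & (s <= extent.distal_s)
    if sel.sum() < 1:
        return empty
    in_pts = cl_occluded.points[sel]

    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    rmax = max(radii[sel].max(), spacing.max())
    lo = np.maximum(np.floor((in_pts.min(axis=0) - rmax - origin) / spacing).astype(int) - 1, 0)
    hi = np.minimum(
        np.ceil((in_pts.max(axis=0) + rmax - origin) / spacing).astype(int) + 2,
        np.asarray(grid.shape),
    )
    mask = np.zeros(grid.shape, dtype=bool)
    if np.all(lo < hi):
        grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
        idx = np.stack([g.ravel() for g in grids], axis=1)
        centers = origin + idx * spacing
        # project onto the whole centerline so the tube is cut flat at the
        # extent ends (no spherical caps past proximal_s / distal_s)
        dist, nearest = cKDTree(cl_occluded.points).query(centers, workers=-1)
        inside = (dist <= radii[nearest]) & sel[nearest]
        mask[tuple(idx[inside].T)] = True
    if dilation_voxels > 0:
        k = 2 * dilation_voxels + 1
        mask = ndimage.binary_dilation(mask, structure=np.ones((k, k, k), dtype=bool))
        # the mask ranges from the proximal to the distal occlusion location:
        # keep the dilation transverse, clip it back longitudinally
        idx = np.argwhere(mask)
        centers = origin + idx * spacing
        _, nearest = cKDTree(cl_occluded.points).query(centers, workers=-1)
        mask[tuple(idx[~sel[nearest]].T)] = False
    return grid.like(mask)


def compute_thresholds(
    image: ImageVolume,
    cl_contralateral: Centerline,
    cl_occluded: Centerline,
    extent: OcclusionExtent,
) -> ThresholdPair:
    """Adaptive thresholds from trilinearly sampled centerline intensities.

    t_max = mean − SD over the whole contralateral centerline;
    t_min = min + SD over the occluded centerline restricted to the
    detected occlusion.  t_min > t_max is flagged degenerate so the
    pipeline reports a failure instead of silently growing nothing.
    """
    if extent is None or extent.empty:
        raise ValueError("occlusion extent must be non-empty to derive thresholds")
    hu_con = image.sample(cl_contralateral.points)
    s = cl_occluded.arc_length
    # sample two profile steps inside the extent: the endpoints are only
    # localized to one sample and interface sections blend thrombus with
    # lumen, which would contaminate the statistics
    step = float(np.median(np.diff(s))) if len(s) > 1 else 0.0
    sel = (s >= extent.proximal_s + 2 * step) & (s <= extent.distal_s - 2 * step)
    if not sel.any():
        sel = (s >= extent.proximal_s + step) & (s <= extent.distal_s - step)
    if not sel.any():
        sel = (s > extent.proximal_s) & (s < extent.distal_s)
    if not sel.any():
        sel = (s >= extent.proximal_s) & (s <= extent.distal_s)
    if not sel.any():
        raise ValueError("occluded centerline has no samples inside the extent")
    hu_occ = image.sample(cl_occluded.points[sel])
    c_mean, c_sd = float(np.mean(hu_con)), float(np.std(hu_con))
    o_min, o_sd = float(np.min(hu_occ)), float(np.std(hu_occ))
    return ThresholdPair(
        t_min=o_min + o_sd,
        t_max=c_mean - c_sd,
        contralateral_mean=c_mean,
        contralateral_sd=c_sd,
        occluded_min=o_min,
        occluded_sd=o_sd,
    )


def region_grow(
    image: ImageVolume,
    seed: np.ndarray,
    mask: ImageVolume,
    thresholds: ThresholdPair,
    recovery_points: np.ndarray | None = None,
) -> tuple[ImageVolume, list[str]]:
    """26-connected component of in-mask, in-threshold voxels at the seed.

    If the seed voxel itself falls outside the intensity window (or the
    mask), successive ``recovery_points`` (centerline samples up to ~2 mm
    distal) are tried; if all fail an empty result is returned with a
    failure flag.
    """
    if thresholds.degenerate:
        raise ValueError("degenerate thresholds: t_min > t_max")
    tol = 1e-6  # float guard so exactly-threshold voxels are kept
    candidate = (
        mask.data
        & (image.data >= thresholds.t_min - tol)
        & (image.data <= thresholds.t_max + tol)
    )
    flags: list[str] = []

    trial = np.atleast_2d(seed)
    if recovery_points is not None and len(recovery_points):
        trial = np.vstack([trial, np.atleast_2d(recovery_points)])
    seed_idx = None
    for i, p in enumerate(trial):
        ijk = tuple(np.round(image.world_to_index(p)).astype(int))
        if all(0 <= ijk[a] < image.shape[a] for a in range(3)) and candidate[ijk]:
            seed_idx = ijk
            if i > 0:
                flags.append(f"seed-recovered-at-sample-{i}")
            break
    if seed_idx is None:
        flags.append("seed-outside-thresholds")
        return image.like(np.zeros(image.shape, dtype=bool)), flags

    labels, _ = ndimage.label(candidate, structure=_CUBE26)
    grown = labels == labels[seed_idx]
    return image.like(grown), flags


def morph_open(mask: ImageVolume, kernel_n: int = 1) -> ImageVolume:
    """Opening (erosion then dilation) with a cubic 2n+1 structuring
    element; smooths the thrombus surface and removes small islands."""
    if kernel_n < 1:
        return mask.like(mask.data.astype(bool))
    k = 2 * kernel_n + 1
    opened = ndimage.binary_opening(
        mask.data.astype(bool), structure=np.ones((k, k, k), dtype=bool)
    )
    return mask.like(opened)


def measure(
    mask: ImageVolume, cl_occluded: Centerline
) -> tuple[float, float, list[str]]:
    """(length_mm, volume_mm3) of the thrombus mask.

    Volume is exact voxel counting; length projects every mask voxel to
    its nearest centerline point and spans the projected arc lengths, so
    curved thrombi measure arc length rather than chord length.
    """
    n = int(mask.data.sum())
    if n == 0:
        return 0.0, 0.0, ["empty-mask"]
    volume = n * mask.voxel_volume
    idx = np.argwhere(mask.data)
    centers = mask.index_to_world(idx)
    _, nearest = cKDTree(cl_occluded.points).query(centers, workers=-1)
    s = cl_occluded.arc_length[nearest]
    return float(s.max() - s.min()), float(volume), []
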