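"""Synthetic CTA phantoms: symmetric bifurcating vessel trees with a
contrast-enhanced lumen, an occluding thrombus segment, soft-tissue
background, Gaussian noise and optional calcifications.

The phantom emulates the imaging situation the segmentation pipeline is
built for: a proximal intracranial occlusion whose thrombus (< 80 HU) is
nearly isointense with soft tissue, while the patent contralateral artery
carries contrast-enhanced lumen (~150-300 HU).  Every phantom ships its
ground truth (masks, centerlines, thrombus length and volume, symmetry
plane, suggested seed points), so each pipeline stage can be scored
against a known answer.

Conventions: the occluded side is "left" (negative side of the symmetry
plane normal), the contralateral side is "right".  The optional smooth
asymmetry warp is applied to the occluded side only, so the mirrored
contralateral centerline deviates from the true occluded-side geometry by
at most ``asymmetry_warp_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .core import Centerline, ImageVolume, SeedPair, SymmetryPlane

__all__ = [
    "VesselSegment",
    "PhantomSpec",
    "PhantomResult",
    "make_symmetric_tree",
    "generate_phantom",
    "default_phantom_spec",
    "tube_phantom_spec",
]


@dataclass
class VesselSegment:
    """One vessel branch: an ordered polyline with a per-point radius."""

    segment_id: str
    points: np.ndarray  # (M, 3) world mm
    radii: np.ndarray  # (M,) mm
    side: str = "left"  # "left" (occluded) or "right" (contralateral)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if len(self.radii) == 1:
            self.radii = np.full(len(self.points), self.radii[0])
        if len(self.radii) != len(self.points):
            raise ValueError(f"segment {self.segment_id}: radii/points length mismatch")
        if np.any(self.radii <= 0):
            raise ValueError(f"segment {self.segment_id}: radii must be positive")

    @property
    def arc_length(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class PhantomSpec:
    """Full description of one synthetic case.

    ``occlusion`` is ``(segment_id, start_mm, end_mm)`` in arc length on
    that segment, or ``None`` for a patent (non-occluded) phantom.
    Default intensities follow clinical CTA: thrombus below 80 HU, lumen
    in the 150-300 HU contrast-enhanced range; values outside those bands
    are allowed but flagged.
    """

    volume_shape: tuple[int, int, int]
    voxel_spacing: tuple[float, float, float]
    tree: list[VesselSegment]
    symmetry_plane: SymmetryPlane
    left_path: list[str]
    right_path: list[str]
    lumen_hu: float = 250.0
    thrombus_hu: float = 45.0
    background_hu: float = 40.0
    occlusion: tuple[str, float, float] | None = None
    noise_sd: float = 0.0
    calcifications: list[tuple[np.ndarray, float, float]] = field(default_factory=list)
    asymmetry_warp_mm: float = 0.0
    partial_volume_blur: bool = False
    rng_seed: int = 0

    def intensity_flags(self) -> list[str]:
        flags = []
        if not self.thrombus_hu < 80:
            flags.append("thrombus-hu-not-below-80")
        if not 150 <= self.lumen_hu <= 300:
            flags.append("lumen-hu-outside-150-300")
        return flags

    def segment(self, segment_id: str) -> VesselSegment:
        for seg in self.tree:
            if seg.segment_id == segment_id:
                return seg
        raise KeyError(f"no segment named {segment_id!r}")


@dataclass
class PhantomResult:
    """Rendered phantom plus its ground truth."""

    image: ImageVolume
    lumen_mask_left: ImageVolume
    lumen_mask_right: ImageVolume
    thrombus_mask: ImageVolume
    true_centerlines: dict  # side -> Centerline (seeded path, with radii)
    true_length_mm: float
    true_volume_mm3: float
    symmetry_plane: SymmetryPlane
    seeds: SeedPair
    true_occlusion_path_interval: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# tree construction


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def make_symmetric_tree(
    trunk: VesselSegment,
    branch_angles_deg: list[float],
    mirror_plane: SymmetryPlane,
    branch_length_mm: float = 12.0,
    branch_radius_scale: float = 0.7,
) -> tuple[list[VesselSegment], list[str], list[str]]:
    """Build a left tree (trunk + terminal branches) and its exact mirror.

    Branches leave the trunk end in the plane spanned by the trunk tangent
    and the in-plane direction orthogonal to the mirror normal, rotated by
    the given angles.  Returns ``(segments, left_path_ids, right_path_ids)``
    where the paths are the seeded routes (trunk then first branch).
    """
    segs: list[VesselSegment] = []
    trunk = VesselSegment(trunk.segment_id, trunk.points, trunk.radii, side="left")
    segs.append(trunk)

    left_ids = [trunk.segment_id]
    tangent = _unit(trunk.points[-1] - trunk.points[-2])
    # in-plane bending axis: component of the mirror normal removed
    lateral = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(lateral, tangent)) > 0.9:
        lateral = np.array([0.0, 1.0, 0.0])
    lateral = _unit(np.cross(tangent, _unit(np.cross(lateral, tangent))))
    for i, ang in enumerate(branch_angles_deg):
        a = np.deg2rad(ang)
        direction = _unit(np.cos(a) * tangent + np.sin(a) * lateral)
        n_pts = 8
        ts = np.linspace(0.0, branch_length_mm, n_pts)
        pts = trunk.points[-1] + np.outer(ts, direction)
        radii = np.full(n_pts, branch_radius_scale * trunk.radii[-1])
        seg = VesselSegment(f"{trunk.segment_id}b{i}", pts, radii, side="left")
        segs.append(seg)
        if i == 0:
            left_ids.append(seg.segment_id)

    right: list[VesselSegment] = []
    for seg in segs:
        right.append(
            VesselSegment(
                "R" + seg.segment_id,
                mirror_plane.reflect(seg.points),
                seg.radii.copy(),
                side="right",
            )
        )
    right_ids = ["R" + sid for sid in left_ids]
    return segs + right, left_ids, right_ids


# ---------------------------------------------------------------------------
# warping (occluded-side asymmetry)


def _smooth_displacement(points: np.ndarray, magnitude_mm: float, rng) -> np.ndarray:
    """Smooth pseudo-random displacement field, max norm == magnitude."""
    if magnitude_mm <= 0 or len(points) == 0:
        return np.zeros_like(points)
    disp = np.zeros_like(points, dtype=float)
    for axis in range(3):
        # superpose two long-wavelength sinusoids per axis
        for _ in range(2):
            k = rng.normal(size=3)
            k = k / np.linalg.norm(k) * (2 * np.pi / rng.uniform(25.0, 60.0))
            phase = rng.uniform(0, 2 * np.pi)
            disp[:, axis] += rng.uniform(0.5, 1.0) * np.sin(points @ k + phase)
    norms = np.linalg.norm(disp, axis=1)
    peak = norms.max()
    if peak > 0:
        disp *= magnitude_mm / peak
    return disp


# ---------------------------------------------------------------------------
# rasterization


def _dense_path(points: np.ndarray, radii: np.ndarray, step: float):
    """Linearly interpolated samples at <= ``step`` spacing along the polyline."""
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))])
    total = s[-1]
    n = max(int(np.ceil(total / step)), 1)
    s_new = np.linspace(0.0, total, n + 1)
    pts = np.column_stack([np.interp(s_new, s, points[:, a]) for a in range(3)])
    rad = np.interp(s_new, s, radii)
    return pts, rad, s_new


def _segment_voxels(spec: PhantomSpec, seg: VesselSegment, origin: np.ndarray):
    """Voxels inside the tube: (indices flat-arrays, nearest-sample arc length).

    A voxel belongs to the vessel when its center lies within the local
    radius of the polyline, sampled at <= 0.25 * min(spacing).
    """
    spacing = np.asarray(spec.voxel_spacing)
    shape = np.asarray(spec.volume_shape)
    step = 0.25 * spacing.min()
    pts, rad, s = _dense_path(seg.points, seg.radii, step)

    rmax = rad.max()
    lo = np.maximum(np.floor((pts.min(axis=0) - rmax - origin) / spacing).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((pts.max(axis=0) + rmax - origin) / spacing).astype(int) + 2, shape)
    if np.any(lo >= hi):
        empty = np.array([], dtype=int)
        return (empty, empty, empty), empty.astype(float)

    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    centers = origin + idx * spacing
    tree = cKDTree(pts)
    dist, nearest = tree.query(centers, workers=-1)
    inside = dist <= rad[nearest]
    idx = idx[inside]
    return (idx[:, 0], idx[:, 1], idx[:, 2]), s[nearest[inside]]


def _validate_bounds(spec: PhantomSpec, origin: np.ndarray) -> None:
    spacing = np.asarray(spec.voxel_spacing)
    hi = origin + (np.asarray(spec.volume_shape) - 1) * spacing
    for seg in spec.tree:
        if np.any(seg.points < origin) or np.any(seg.points > hi):
            raise ValueError(
                f"segment {seg.segment_id!r} has polyline points outside the volume bounds"
            )


def _volume_origin(spec: PhantomSpec) -> np.ndarray:
    """Grid centered on the symmetry-plane point (plane between voxels)."""
    spacing = np.asarray(spec.voxel_spacing)
    extent = (np.asarray(spec.volume_shape) - 1) * spacing
    return np.asarray(spec.symmetry_plane.point) - extent / 2.0


# ---------------------------------------------------------------------------
# main generator


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Render the phantom volume and assemble its ground truth.

    Deterministic given ``spec.rng_seed``: the noise realization and the
    asymmetry warp are the only stochastic elements and both draw from one
    seeded generator.  Masks never depend on the noise.
    """
    rng = np.random.default_rng(spec.rng_seed)
    origin = _volume_origin(spec)
    spacing = np.asarray(spec.voxel_spacing)
    flags = spec.intensity_flags()

    # occluded-side asymmetry warp (shared smooth field across segments)
    tree = []
    left_pts_all = np.concatenate(
        [s.points for s in spec.tree if s.side == "left"], axis=0
    ) if any(s.side == "left" for s in spec.tree) else np.zeros((0, 3))
    warp_rng = np.random.default_rng(spec.rng_seed + 1)
    # probe the field on the undisplaced points to fix the normalization
    probe_disp = _smooth_displacement(left_pts_all, spec.asymmetry_warp_mm, warp_rng)
    offset = 0
    for seg in spec.tree:
        if seg.side == "left" and spec.asymmetry_warp_mm > 0:
            d = probe_disp[offset : offset + len(seg.points)]
            offset += len(seg.points)
            tree.append(VesselSegment(seg.segment_id, seg.points + d, seg.radii, seg.side))
        else:
            if seg.side == "left":
                offset += len(seg.points)
            tree.append(seg)
    warped = PhantomSpec(
        volume_shape=spec.volume_shape,
        voxel_spacing=spec.voxel_spacing,
        tree=tree,
        symmetry_plane=spec.symmetry_plane,
        left_path=spec.left_path,
        right_path=spec.right_path,
        occlusion=spec.occlusion,
    )
    _validate_bounds(warped, origin)

    shape = tuple(spec.volume_shape)
    image = np.full(shape, spec.background_hu, dtype=np.float32)
    lumen_left = np.zeros(shape, dtype=bool)
    lumen_right = np.zeros(shape, dtype=bool)
    thrombus = np.zeros(shape, dtype=bool)

    occ_seg, occ_s0, occ_s1 = (None, 0.0, 0.0)
    if spec.occlusion is not None:
        occ_seg, occ_s0, occ_s1 = spec.occlusion
        seg = warped.segment(occ_seg)
        total = seg.arc_length[-1]
        if not (0.0 <= occ_s0 < occ_s1 <= total + 1e-9):
            raise ValueError(
                f"occlusion interval [{occ_s0}, {occ_s1}] outside segment "
                f"{occ_seg!r} arc length [0, {total:.2f}]"
            )

    for seg in tree:
        voxels, arc = _segment_voxels(warped, seg, origin)
        if seg.side == "left":
            lumen_left[voxels] = True
        else:
            lumen_right[voxels] = True
        if seg.segment_id == occ_seg:
            in_occ = (arc >= occ_s0) & (arc <= occ_s1)
            thrombus[tuple(v[in_occ] for v in voxels)] = True

    lumen_left &= ~thrombus  # thrombus replaces lumen: masks stay disjoint
    lumen_right &= ~thrombus
    image[lumen_left | lumen_right] = spec.lumen_hu
    image[thrombus] = spec.thrombus_hu

    for point, radius, hu in spec.calcifications:
        point = np.asarray(point, dtype=float)
        lo = np.maximum(np.floor((point - radius - origin) / spacing).astype(int) - 1, 0)
        hi = np.minimum(np.ceil((point + radius - origin) / spacing).astype(int) + 2, shape)
        grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
        idx = np.stack([g.ravel() for g in grids], axis=1)
        centers = origin + idx * spacing
        sel = np.linalg.norm(centers - point, axis=1) <= radius
        image[tuple(idx[sel].T)] = hu

    if spec.partial_volume_blur:
        image = gaussian_filter(image, sigma=0.5)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    vol = ImageVolume(image.astype(np.float32), tuple(spacing), tuple(origin))
    mask = lambda m: ImageVolume(m, tuple(spacing), tuple(origin))  # noqa: E731

    # ground-truth centerlines along the seeded paths (post-warp geometry)
    centerlines = {}
    occ_interval = None
    for side, ids in (("left", spec.left_path), ("right", spec.right_path)):
        pts_list, rad_list = [], []
        base = 0.0
        for sid in ids:
            seg = warped.segment(sid)
            p, r, s = _dense_path(seg.points, seg.radii, 0.25 * spacing.min())
            if pts_list:
                p, r, s = p[1:], r[1:], s[1:]
            if sid == occ_seg and spec.occlusion is not None:
                occ_interval = (base + occ_s0, base + occ_s1)
            base += s[-1] if len(s) else 0.0
            pts_list.append(p)
            rad_list.append(r)
        pts = np.concatenate(pts_list, axis=0)
        rad = np.concatenate(rad_list)
        centerlines[side] = Centerline(pts, radii=rad)

    true_volume = float(thrombus.sum()) * vol.voxel_volume
    true_length = float(occ_s1 - occ_s0) if spec.occlusion is not None else 0.0

    cl_right = centerlines["right"]
    inset = min(2.0, 0.1 * cl_right.length)
    seeds = SeedPair(
        proximal=cl_right.point_at(inset),
        distal=cl_right.point_at(cl_right.length - inset),
        side_label="contralateral",
    )

    return PhantomResult(
        image=vol,
        lumen_mask_left=mask(lumen_left),
        lumen_mask_right=mask(lumen_right),
        thrombus_mask=mask(thrombus),
        true_centerlines=centerlines,
        true_length_mm=true_length,
        true_volume_mm3=true_volume,
        symmetry_plane=spec.symmetry_plane,
        seeds=seeds,
        true_occlusion_path_interval=occ_interval,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# stock geometries


def tube_phantom_spec(
    tube_length_mm: float = 40.0,
    radius_mm: float = 3.0,
    occlusion_start_mm: float | None = 15.0,
    occlusion_length_mm: float = 10.0,
    side_offset_mm: float = 7.0,
    voxel_spacing: float | tuple[float, float, float] = 0.5,
    curved: bool = False,
    bend_radius_mm: float = 60.0,
    noise_sd: float = 0.0,
    asymmetry_warp_mm: float = 0.0,
    calcifications: list | None = None,
    lumen_hu: float = 250.0,
    thrombus_hu: float = 45.0,
    background_hu: float = 40.0,
    margin_mm: float = 6.0,
    partial_volume_blur: bool = False,
    rng_seed: int = 0,
) -> PhantomSpec:
    """Single straight (or gently curved) tube per side — the workhorse
    geometry for stage-level accuracy checks.

    The two tubes run along +y at x = ±``side_offset_mm``; the mirror plane
    is x = 0.  ``occlusion_start_mm=None`` yields a patent phantom.
    """
    if np.isscalar(voxel_spacing):
        voxel_spacing = (float(voxel_spacing),) * 3
    n_pts = max(int(tube_length_mm / 2.0), 8)
    t = np.linspace(0.0, tube_length_mm, n_pts)
    y = t - tube_length_mm / 2.0
    if curved:
        # circular arc in the x-y plane, bending away from the midline
        theta = t / bend_radius_mm
        arc_x = bend_radius_mm * (1 - np.cos(theta))
        arc_y = bend_radius_mm * np.sin(theta) - tube_length_mm / 2.0
        pts = np.column_stack([-side_offset_mm - arc_x, arc_y, np.zeros(n_pts)])
    else:
        pts = np.column_stack([np.full(n_pts, -side_offset_mm), y, np.zeros(n_pts)])
    plane = SymmetryPlane(point=(0.0, 0.0, 0.0), normal=(1.0, 0.0, 0.0))
    left = VesselSegment("L0", pts, np.full(n_pts, radius_mm), side="left")
    right = VesselSegment("RL0", plane.reflect(pts), np.full(n_pts, radius_mm), side="right")

    span = np.concatenate([left.points, right.points], axis=0)
    pad = radius_mm + margin_mm + asymmetry_warp_mm
    extent = span.max(axis=0) - span.min(axis=0) + 2 * pad
    shape = tuple(int(np.ceil(e / s)) + 1 for e, s in zip(extent, voxel_spacing))

    occlusion = None
    if occlusion_start_mm is not None:
        occlusion = ("L0", float(occlusion_start_mm), float(occlusion_start_mm + occlusion_length_mm))

    return PhantomSpec(
        volume_shape=shape,
        voxel_spacing=voxel_spacing,
        tree=[left, right],
        symmetry_plane=plane,
        left_path=["L0"],
        right_path=["RL0"],
        lumen_hu=lumen_hu,
        thrombus_hu=thrombus_hu,
        background_hu=background_hu,
        occlusion=occlusion,
        noise_sd=noise_sd,
        calcifications=calcifications or [],
        asymmetry_warp_mm=asymmetry_warp_mm,
        partial_volume_blur=partial_volume_blur,
        rng_seed=rng_seed,
    )


def default_phantom_spec(
    occlusion_start_mm: float | None = 15.0,
    occlusion_length_mm: float = 10.0,
    noise_sd: float = 0.0,
    asymmetry_warp_mm: float = 0.0,
    rng_seed: int = 0,
    **kwargs,
) -> PhantomSpec:
    """M1-like default geometry: 3 mm-radius, 40 mm trunk with one terminal
    bifurcation per side, mirrored about the mid-sagittal plane x = 0."""
    spacing = kwargs.pop("voxel_spacing", 0.5)
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    side = kwargs.pop("side_offset_mm", 7.0)
    radius = kwargs.pop("radius_mm", 3.0)
    trunk_len = kwargs.pop("trunk_length_mm", 40.0)
    if kwargs:
        raise TypeError(f"unknown options: {sorted(kwargs)}")

    n = 20
    pts = np.column_stack(
        [np.full(n, -side), np.linspace(-trunk_len / 2, trunk_len / 2, n), np.zeros(n)]
    )
    plane = SymmetryPlane(point=(0.0, 0.0, 0.0), normal=(1.0, 0.0, 0.0))
    trunk = VesselSegment("L0", pts, np.full(n, radius), side="left")
    tree, left_path, right_path = make_symmetric_tree(
        trunk, branch_angles_deg=[35.0, -35.0], mirror_plane=plane
    )

    span = np.concatenate([s.points for s in tree], axis=0)
    pad = radius + 6.0 + asymmetry_warp_mm
    extent = span.max(axis=0) - span.min(axis=0) + 2 * pad
    shape = tuple(int(np.ceil(e / s)) + 1 for e, s in zip(extent, spacing))

    occlusion = None
    if occlusion_start_mm is not None:
        occlusion = ("L0", float(occlusion_start_mm), float(occlusion_start_mm + occlusion_length_mm))

    return PhantomSpec(
        volume_shape=shape,
        voxel_spacing=spacing,
        tree=tree,
        symmetry_plane=plane,
        left_path=left_path,
        right_path=right_path,
        occlusion=occlusion,
        noise_sd=noise_sd,
        asymmetry_warp_mm=asymmetry_warp_mm,
        rng_seed=rng_seed,
    )
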