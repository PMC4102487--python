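"""Core geometric containers shared by every pipeline stage.

All geometry lives in world millimetres.  An :class:`ImageVolume` is an
axis-aligned scalar grid (Hounsfield units for CTA data, but the same
container carries vesselness, cost and binary masks); a :class:`Centerline`
is an ordered polyline with cumulative arc length and an optional per-point
radius profile.  Voxel indices are 0-based and map to world coordinates as
``world = origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "ImageVolume",
    "Centerline",
    "SymmetryPlane",
    "SeedPair",
    "OcclusionExtent",
    "ThresholdPair",
    "ThrombusResult",
]


@dataclass
class ImageVolume:
    """3D scalar grid with voxel spacing (mm) and world origin (mm).

    ``data`` is indexed ``[i, j, k]`` along the world x/y/z axes.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index for world-mm points."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains_world(self, pts: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(self.world_to_index(pts))
        hi = np.asarray(self.shape) - 1
        ok = np.all((idx >= 0) & (idx <= hi), axis=1)
        return ok if ok.size > 1 else bool(ok[0])

    def sample(self, pts: np.ndarray, *, fill: float = 0.0, order: int = 1) -> np.ndarray:
        """Trilinear interpolation of the volume at world-mm points."""
        idx = np.atleast_2d(self.world_to_index(pts))
        return map_coordinates(
            self.data.astype(float), idx.T, order=order, mode="constant", cval=fill
        )

    def like(self, data: np.ndarray) -> "ImageVolume":
        """New volume with the same grid carrying ``data``."""
        return ImageVolume(data, self.spacing, self.origin)


def _cumulative_arc_length(points: np.ndarray) -> np.ndarray:
    if len(points) < 2:
        return np.zeros(len(points))
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class Centerline:
    """Ordered world-mm polyline, proximal end first.

    ``arc_length`` is the cumulative distance from the proximal end;
    ``radii`` (when present) is the per-point lumen radius in mm.
    """

    points: np.ndarray
    radii: np.ndarray | None = None
    degenerate: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("centerline points must be (N, 3)")
        if len(self.points) < 2 and not self.degenerate:
            self.degenerate = True
            self.flags.append("fewer-than-2-points")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
            if len(self.radii) != len(self.points):
                raise ValueError("radii must have one value per centerline point")

    @property
    def arc_length(self) -> np.ndarray:
        return _cumulative_arc_length(self.points)

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def __len__(self) -> int:
        return len(self.points)

    def tangents(self) -> np.ndarray:
        """Unit tangents by central differences along the polyline."""
        t = np.gradient(self.points, axis=0)
        n = np.linalg.norm(t, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return t / n

    def resample(self, step_mm: float) -> "Centerline":
        """Uniform arc-length resampling at ``step_mm`` (endpoints kept)."""
        s = self.arc_length
        if self.length == 0:
            return replace(self, radii=None)
        n = max(int(round(self.length / step_mm)), 1)
        s_new = np.linspace(0.0, self.length, n + 1)
        pts = np.column_stack([np.interp(s_new, s, self.points[:, a]) for a in range(3)])
        radii = None if self.radii is None else np.interp(s_new, s, self.radii)
        return Centerline(pts, radii=radii, flags=list(self.flags))

    def smooth(self, window: int = 3) -> "Centerline":
        """Small moving-average smoothing of the point coordinates."""
        if window <= 1 or len(self) < 3:
            return self
        k = np.ones(window) / window
        pts = self.points.copy()
        inner = np.column_stack(
            [np.convolve(self.points[:, a], k, mode="same") for a in range(3)]
        )
        pts[1:-1] = inner[1:-1]  # pin the seed endpoints
        return Centerline(pts, radii=self.radii, flags=list(self.flags))

    def point_at(self, s: float) -> np.ndarray:
        """Point at arc-length position ``s`` (clamped, linear interpolation)."""
        sl = self.arc_length
        return np.array([np.interp(s, sl, self.points[:, a]) for a in range(3)])


@dataclass
class SymmetryPlane:
    """Mid-sagittal mirror plane: a point on the plane and its unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise ValueError("plane normal must be nonzero")
        self.normal = self.normal / n

    def reflect(self, pts: np.ndarray) -> np.ndarray:
        """Mirror points through the plane (exact involution)."""
        pts = np.asarray(pts, dtype=float)
        d = (pts - self.point) @ self.normal
        return pts - 2.0 * np.multiply.outer(d, self.normal)


@dataclass
class SeedPair:
    """Manually placed proximal/distal seeds on the contralateral artery."""

    proximal: np.ndarray
    distal: np.ndarray
    side_label: str = "contralateral"

    def __post_init__(self) -> None:
        self.proximal = np.asarray(self.proximal, dtype=float)
        self.distal = np.asarray(self.distal, dtype=float)
        if np.allclose(self.proximal, self.distal):
            raise ValueError("proximal and distal seeds must be distinct")


@dataclass
class OcclusionExtent:
    """Arc-length interval of the detected occlusion on the occluded-side
    centerline; ``distal_is_vasculature_end`` marks poor retrograde filling
    (the sub-threshold run reached the end of the tracked vasculature)."""

    proximal_s: float
    distal_s: float
    distal_is_vasculature_end: bool = False
    ratio_threshold: float = 0.05
    empty: bool = False

    def __post_init__(self) -> None:
        if not self.empty and not self.proximal_s < self.distal_s:
            raise ValueError("occlusion extent requires proximal_s < distal_s")

    @property
    def length(self) -> float:
        return 0.0 if self.empty else self.distal_s - self.proximal_s

    @classmethod
    def none_found(cls, ratio_threshold: float = 0.05) -> "OcclusionExtent":
        return cls(0.0, 0.0, empty=True, ratio_threshold=ratio_threshold)


@dataclass
class ThresholdPair:
    """Adaptive region-growing thresholds (HU).

    t_max = mean(HU on contralateral centerline) − SD of the same samples;
    t_min = min(HU on occluded centerline inside the occlusion) + SD of those
    samples.  ``degenerate`` flags t_min > t_max (growing impossible).
    """

    t_min: float
    t_max: float
    contralateral_mean: float = float("nan")
    contralateral_sd: float = float("nan")
    occluded_min: float = float("nan")
    occluded_sd: float = float("nan")

    @property
    def degenerate(self) -> bool:
        return not self.t_min <= self.t_max


@dataclass
class ThrombusResult:
    """Final segmentation: binary mask plus derived measurements."""

    mask: ImageVolume
    length_mm: float
    volume_mm3: float
    thresholds: ThresholdPair | None = None
    seed_point: np.ndarray | None = None
    extent: OcclusionExtent | None = None
    status: str = "ok"
    flags: list[str] = field(default_factory=list)
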