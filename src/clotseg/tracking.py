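"""Multiscale vesselness filtering and minimal-cost-path tracking.

The contralateral artery is traced between two manually placed seed
points: a Frangi-type tubularity score is computed over a log-uniform
scale range, inverted into a cost image, and the minimum-cumulative-cost
path between the seeds is extracted on the 26-connected voxel grid.

The Hessian scale space is built with spacing-aware Gaussian derivatives
(per-axis sigma in voxels = sigma_mm / spacing_mm) so anisotropic CTA
grids are handled correctly; responses are gamma-normalized (sigma^2)
across scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.graph import MCP_Geometric

from .core import Centerline, ImageVolume, SeedPair

__all__ = [
    "VesselnessParams",
    "vesselness",
    "cost_image",
    "optimal_path",
    "smooth_path",
]


@dataclass
class VesselnessParams:
    """Scale range (mm) and Frangi sensitivity constants.

    ``c=None`` sets the structureness scale to half the maximum Hessian
    norm of the image at each scale (the filter's conventional default).
    """

    sigma_low: float = 1.0
    sigma_up: float = 3.5
    n_scales: int = 5
    alpha: float = 0.5
    beta: float = 0.5
    c: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.sigma_low <= self.sigma_up:
            raise ValueError("require 0 < sigma_low <= sigma_up")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")

    def sigmas(self) -> np.ndarray:
        """Log-uniform scale samples from sigma_low to sigma_up (mm)."""
        if self.n_scales == 1 or self.sigma_low == self.sigma_up:
            return np.array([self.sigma_low])
        return np.geomspace(self.sigma_low, self.sigma_up, self.n_scales)


def _hessian_eigenvalues(data: np.ndarray, sigma_vox: np.ndarray) -> np.ndarray:
    """Eigenvalues of the gamma-normalized Gaussian Hessian, sorted by |.|."""
    H = np.empty(data.shape + (3, 3), dtype=np.float32)
    for i in range(3):
        for j in range(i, 3):
            order = [0, 0, 0]
            order[i] += 1
            order[j] += 1
            d = gaussian_filter(data, sigma=sigma_vox, order=order)
            H[..., i, j] = d
            H[..., j, i] = d
    lam = np.linalg.eigvalsh(H)  # ascending by value
    order = np.argsort(np.abs(lam), axis=-1)
    return np.take_along_axis(lam, order, axis=-1)


def vesselness(image: ImageVolume, params: VesselnessParams) -> ImageVolume:
    """Per-voxel bright-tube vesselness in [0, 1], maximum over scales.

    A constant image has no structure anywhere and yields an all-zero
    response rather than an error.
    """
    # mean-center: derivatives are shift-invariant, and the discrete
    # second-derivative kernel's nonzero sum would otherwise leak the DC
    # level into the Hessian of flat regions
    data = image.data.astype(np.float64)
    data -= data.mean()
    spacing = np.asarray(image.spacing)
    best = np.zeros(data.shape, dtype=np.float32)
    a2 = 2.0 * params.alpha**2
    b2 = 2.0 * params.beta**2
    # numerical floor: Hessian magnitudes at or below this are "no structure"
    structure_floor = 1e-8 * max(1.0, float(np.ptp(data)))

    for sigma in params.sigmas():
        sig_vox = sigma / spacing
        lam = _hessian_eigenvalues(data, sig_vox) * sigma**2  # gamma = 2
        l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
        S2 = np.sum(lam**2, axis=-1)
        if params.c is None:
            c = 0.5 * np.sqrt(S2.max())
        else:
            c = params.c
        if c <= structure_floor:
            continue  # constant (or numerically constant) image at this scale
        with np.errstate(divide="ignore", invalid="ignore"):
            Ra2 = np.where(l3 != 0, (l2 / l3) ** 2, 0.0)
            Rb2 = np.where(l2 * l3 != 0, l1**2 / np.abs(l2 * l3), 0.0)
            v = (
                (1.0 - np.exp(-Ra2 / a2))
                * np.exp(-Rb2 / b2)
                * (1.0 - np.exp(-S2 / (2.0 * c**2)))
            )
        v = np.where((l2 < 0) & (l3 < 0), v, 0.0)  # bright tubes only
        np.maximum(best, v.astype(np.float32), out=best)
    return image.like(np.clip(best, 0.0, 1.0))


def cost_image(vesselness_vol: ImageVolume, epsilon: float = 1e-3) -> ImageVolume:
    """Cost = 1 / (vesselness + epsilon): strictly positive and finite."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return vesselness_vol.like(1.0 / (vesselness_vol.data.astype(float) + epsilon))


def optimal_path(cost: ImageVolume, seeds: SeedPair) -> Centerline:
    """Minimum-cumulative-cost voxel path between the two seeds.

    Edges connect 26-neighbors; the edge weight is the mean of the two
    endpoint costs times the Euclidean step length in mm, so the path cost
    approximates the line integral of the cost image.  The path is
    returned proximal-first in world mm.
    """
    for name, pt in (("proximal", seeds.proximal), ("distal", seeds.distal)):
        if not cost.contains_world(pt):
            raise ValueError(f"{name} seed {pt} lies outside the volume")
    start = tuple(np.round(cost.world_to_index(seeds.proximal)).astype(int))
    end = tuple(np.round(cost.world_to_index(seeds.distal)).astype(int))
    if start == end:
        return Centerline(
            cost.index_to_world(np.array([start], dtype=float)),
            degenerate=True,
            flags=["identical-seeds"],
        )
    mcp = MCP_Geometric(cost.data.astype(float), sampling=cost.spacing, fully_connected=True)
    mcp.find_costs([start], [end])
    path_idx = np.asarray(mcp.traceback(end), dtype=float)
    points = cost.index_to_world(path_idx)
    return Centerline(points)


def smooth_path(path: Centerline, step_mm: float = 0.5, window: int = 3) -> Centerline:
    """Resample the raw voxel path at uniform arc length and apply a small
    moving average, giving smoothly varying tangents for cross sections."""
    if path.degenerate:
        return path
    return path.resample(step_mm).smooth(window=window)
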