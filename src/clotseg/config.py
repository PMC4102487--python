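"""Pipeline configuration: every published segmentation parameter with its
default value, overridable individually, round-trippable through YAML."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .contralateral import RegistrationParams
from .lumen import ContourParams
from .tracking import VesselnessParams

__all__ = [
    "RadiusSmoothingParams",
    "MorphologyParams",
    "PipelineConfig",
]


@dataclass
class RadiusSmoothingParams:
    """Weighted Gaussian smoothing of radius profiles (passes, mm)."""

    iterations: int = 2
    sigma_radius: float = 0.5


@dataclass
class MorphologyParams:
    """Structuring-element half-widths n (kernel side 2n+1 voxels)."""

    opening_n: int = 1
    dilation_n: int = 1


@dataclass
class PipelineConfig:
    """All tunables of the segmentation pipeline.

    The defaults are the published operating point: vesselness scales
    1.0-3.5 mm; contour kernels 20/20 HU with radial regularization
    0.75 / 0.5 / 2 mm; radius smoothing 2 passes of 0.5 mm; B-spline grid
    2 mm with 32 grey-level bins; morphology opening n=1 and dilation
    n=1; occlusion radius-ratio 0.05; growing seed offset 0.5 mm.
    """

    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    contour: ContourParams = field(default_factory=ContourParams)
    radius_smoothing: RadiusSmoothingParams = field(default_factory=RadiusSmoothingParams)
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    occlusion_ratio: float = 0.05
    grow_seed_offset_mm: float = 0.5
    grow_recovery_mm: float = 2.0
    cost_epsilon: float = 1e-3
    path_step_mm: float = 0.5
    tracking_roi_margin_mm: float = 10.0
    rng_seed: int = 0

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        nested = {
            "vesselness": VesselnessParams,
            "contour": ContourParams,
            "radius_smoothing": RadiusSmoothingParams,
            "registration": RegistrationParams,
            "morphology": MorphologyParams,
        }
        for key, typ in nested.items():
            if key in d:
                val = d.pop(key)
                kwargs[key] = typ(**val) if isinstance(val, dict) else val
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def override(self, **updates) -> "PipelineConfig":
        """New config with top-level fields replaced."""
        return dataclasses.replace(self, **updates)
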