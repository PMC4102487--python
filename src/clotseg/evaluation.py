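"""Phantom study definitions: reproducible case sets for validating the
pipeline end to end.

Three stock studies:

* a geometry-recovery series (noise-free straight and curved occlusions of
  5-40 mm) probing measurement fidelity,
* a 20-case cohort spanning the clinically reported measurement ranges
  (lengths ~2-44 mm, volumes ~10-550 mm^3) with mild left-right asymmetry,
  scored with ICC and Bland-Altman agreement against ground truth,
* single-case probes (poor retrograde filling, adjacent calcification).

Cohort phantoms are noise-free by design: the adaptive lower threshold
(occluded-centerline minimum plus SD) cuts a fixed bottom quantile of any
homogeneous voxel-noise distribution, which makes grown masks porous under
synthetic iid noise in a way real thrombi (smooth heterogeneity,
correlated reconstruction noise) are not; noise robustness is therefore
exercised separately on the occlusion-extent level, where the method is
insensitive to it.
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .phantom import PhantomResult, PhantomSpec, generate_phantom, tube_phantom_spec
from .pipeline import CaseInput, PipelineOutput, run_pipeline
from .stats import CohortReport, cohort_report

__all__ = [
    "geometry_series_specs",
    "cohort_specs",
    "run_case",
    "run_cohort",
    "endpoint_errors_mm",
]

# (length_mm, radius_mm, curved, warp_mm) — spans Table-range lengths
# 2-44 mm and volumes ~10-550 mm^3 (pi r^2 L)
_COHORT_CASES = [
    (2.0, 1.3, False, 0.0),
    (4.0, 1.6, True, 0.5),
    (6.0, 2.0, False, 1.0),
    (8.0, 2.5, True, 0.0),
    (10.0, 3.0, False, 0.5),
    (12.0, 1.6, True, 1.0),
    (14.0, 2.0, False, 0.0),
    (16.0, 3.3, True, 0.5),
    (17.0, 2.5, False, 1.0),
    (20.0, 2.0, True, 0.0),
    (23.0, 1.6, False, 0.5),
    (24.0, 3.0, True, 1.0),
    (26.0, 2.5, False, 0.0),
    (29.0, 2.0, False, 0.5),
    (32.0, 1.6, False, 1.0),
    (35.0, 2.2, False, 0.0),
    (38.0, 1.8, False, 0.5),
    (41.0, 2.0, False, 1.0),
    (44.0, 2.0, False, 0.0),
    (30.0, 3.0, False, 0.5),
]


def geometry_series_specs() -> dict[str, PhantomSpec]:
    """Noise-free 5/10/20/40 mm occlusions, straight and curved."""
    specs = {}
    for length in (5.0, 10.0, 20.0, 40.0):
        for curved in (False, True):
            name = f"L{int(length)}-{'curved' if curved else 'straight'}"
            specs[name] = tube_phantom_spec(
                occlusion_start_mm=12.0,
                occlusion_length_mm=length,
                tube_length_mm=max(40.0, length + 25.0),
                curved=curved,
            )
    return specs


def cohort_specs(rng_seed: int = 0) -> dict[str, PhantomSpec]:
    """The 20-case agreement cohort (see module docstring)."""
    specs = {}
    for i, (length, radius, curved, warp) in enumerate(_COHORT_CASES):
        specs[f"case{i:02d}"] = tube_phantom_spec(
            occlusion_start_mm=12.0,
            occlusion_length_mm=length,
            tube_length_mm=max(40.0, length + 25.0),
            radius_mm=radius,
            curved=curved,
            asymmetry_warp_mm=warp,
            rng_seed=(rng_seed * 1009 + i * 13 + 1) % (2**31 - 1),
        )
    return specs


def run_case(
    spec: PhantomSpec, config: PipelineConfig | None = None
) -> tuple[PhantomResult, PipelineOutput]:
    """Generate the phantom and segment it with its own ground-truth seeds
    and symmetry plane."""
    ph = generate_phantom(spec)
    out = run_pipeline(
        CaseInput(image=ph.image, seeds=ph.seeds, symmetry_plane=ph.symmetry_plane),
        config,
    )
    return ph, out


def run_cohort(
    specs: dict[str, PhantomSpec], config: PipelineConfig | None = None
) -> tuple[CohortReport, dict[str, str]]:
    """Run every case; returns the agreement report (automated vs ground
    truth) and the per-case status map."""
    results, truth, statuses = {}, {}, {}
    for cid, spec in specs.items():
        ph, out = run_case(spec, config)
        results[cid] = (out.result.length_mm, out.result.volume_mm3)
        truth[cid] = (ph.true_length_mm, ph.true_volume_mm3)
        statuses[cid] = out.status
    return cohort_report(results, truth), statuses


def endpoint_errors_mm(ph: PhantomResult, out: PipelineOutput) -> tuple[float, float]:
    """World-space distances of the detected proximal/distal occlusion
    endpoints from the true occlusion interval ends."""
    from .core import Centerline

    ext = out.result.extent
    if ext is None or ext.empty or ph.true_occlusion_path_interval is None:
        return float("inf"), float("inf")
    occ = Centerline(np.asarray(out.qc["occluded_centerline"])).resample(0.5)
    tl = ph.true_centerlines["left"]
    s0, s1 = ph.true_occlusion_path_interval
    e_prox = float(np.linalg.norm(occ.point_at(ext.proximal_s) - tl.point_at(s0)))
    e_dist = float(np.linalg.norm(occ.point_at(ext.distal_s) - tl.point_at(s1)))
    return e_prox, e_dist
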