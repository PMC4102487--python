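"""End-to-end orchestration: tracking -> lumen -> contralateral mapping ->
occlusion detection -> thrombus segmentation -> measurement.

Every stage logs its parameters, timing and flags; degenerate stages turn
into a ``failed:<stage>`` (or ``no-occlusion``) status with partial QC
outputs rather than an exception, mirroring per-case success accounting
in a cohort run.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .contralateral import (
    detect_occlusion,
    estimate_symmetry_plane,
    mirror_centerline,
    refine_by_registration,
)
from .core import (
    Centerline,
    ImageVolume,
    OcclusionExtent,
    SeedPair,
    SymmetryPlane,
    ThresholdPair,
    ThrombusResult,
)
from .io import load_volume, save_volume
from .lumen import contours_along_centerline, radius_profile, refine_centerline, smooth_radius
from .thrombus import build_tubular_mask, compute_thresholds, measure, morph_open, region_grow
from .tracking import cost_image, optimal_path, smooth_path, vesselness

__all__ = ["CaseInput", "PipelineOutput", "run_pipeline"]


@dataclass
class CaseInput:
    """One case: the CTA volume, the two contralateral seeds, and the
    symmetry plane (or "estimate" to derive it from the volume)."""

    image: ImageVolume | str | Path
    seeds: SeedPair
    symmetry_plane: SymmetryPlane | str = "estimate"
    output_dir: str | Path | None = None
    case_id: str = "case"


@dataclass
class PipelineOutput:
    result: ThrombusResult
    status: str
    qc: dict
    log: list = field(default_factory=list)

    @property
    def report(self) -> dict:
        r = self.result
        rep = {
            "status": self.status,
            "length_mm": float(r.length_mm),
            "volume_mm3": float(r.volume_mm3),
            "flags": sorted(set(r.flags)),
        }
        if r.thresholds is not None:
            t = r.thresholds
            rep["thresholds"] = {
                "t_min": t.t_min, "t_max": t.t_max,
                "contralateral_mean": t.contralateral_mean,
                "contralateral_sd": t.contralateral_sd,
                "occluded_min": t.occluded_min, "occluded_sd": t.occluded_sd,
            }
        if r.extent is not None and not r.extent.empty:
            rep["extent"] = {
                "proximal_s": r.extent.proximal_s,
                "distal_s": r.extent.distal_s,
                "distal_is_vasculature_end": r.extent.distal_is_vasculature_end,
            }
        return rep


def _log(log: list, stage: str, t0: float, **info) -> None:
    log.append({"stage": stage, "seconds": round(time.perf_counter() - t0, 3), **info})


def _segment_side(
    image: ImageVolume,
    init_cl: Centerline,
    config: PipelineConfig,
    expected_intensity: float,
    keep_unreliable: bool,
) -> tuple[Centerline, float]:
    """Contours along the initial curve, one center-of-mass refinement
    pass, then contours + robust-smoothed radii on the refined curve.
    Returns the centerline (radii attached) and the reliable fraction."""
    cp = config.contour
    cl0 = init_cl.resample(cp.section_spacing)
    contours1 = contours_along_centerline(image, cl0, cp, expected_intensity)
    refined = refine_centerline(contours1, keep_unreliable_origin=keep_unreliable)
    if refined.degenerate:
        return refined, 0.0
    refined = refined.resample(cp.section_spacing)
    contours2 = contours_along_centerline(image, refined, cp, expected_intensity)
    final = refine_centerline(contours2, keep_unreliable_origin=True)
    radii = radius_profile(contours2)
    radii = smooth_radius(
        radii,
        iterations=config.radius_smoothing.iterations,
        sigma_radius=config.radius_smoothing.sigma_radius,
        spacing_mm=cp.section_spacing,
    )
    frac = sum(c.reliable for c in contours2) / max(len(contours2), 1)
    return Centerline(final.points, radii=radii, flags=list(final.flags)), frac


def _empty_result(image: ImageVolume, status_flags: list[str],
                  thresholds: ThresholdPair | None = None,
                  extent: OcclusionExtent | None = None) -> ThrombusResult:
    return ThrombusResult(
        mask=image.like(np.zeros(image.shape, dtype=bool)),
        length_mm=0.0, volume_mm3=0.0,
        thresholds=thresholds, extent=extent, flags=status_flags,
    )


def run_pipeline(case: CaseInput, config: PipelineConfig | None = None) -> PipelineOutput:
    """Run the full segmentation on one case.

    Deterministic: the only stochastic element (registration metric
    sampling) draws from ``config.rng_seed``, so identical case + config
    + seed reproduce bit-identical reports.
    """
    config = config or PipelineConfig()
    log: list = []
    qc: dict = {"case_id": case.case_id}

    image = case.image if isinstance(case.image, ImageVolume) else load_volume(case.image)

    t0 = time.perf_counter()
    if isinstance(case.symmetry_plane, SymmetryPlane):
        plane = case.symmetry_plane
    else:
        plane = estimate_symmetry_plane(image)
        qc["symmetry_plane_estimated"] = True
    qc["symmetry_plane"] = {"point": plane.point.tolist(), "normal": plane.normal.tolist()}
    _log(log, "symmetry-plane", t0)

    # -- step 1a: vesselness cost + minimal path on the contralateral side
    t0 = time.perf_counter()
    roi = _crop_around_seeds(image, case.seeds, config.tracking_roi_margin_mm)
    vmap = vesselness(roi, config.vesselness)
    cost = cost_image(vmap, config.cost_epsilon)
    raw_path = optimal_path(cost, case.seeds)
    if raw_path.degenerate:
        _log(log, "tracking", t0, flags=raw_path.flags)
        return PipelineOutput(_empty_result(image, raw_path.flags), "failed:tracking", qc, log)
    path = smooth_path(raw_path, step_mm=config.path_step_mm)
    qc["tracked_path"] = path.points.tolist()
    _log(log, "tracking", t0, n_points=len(path))

    # -- step 1b: contralateral lumen segmentation
    t0 = time.perf_counter()
    expected = float(np.median(image.sample(path.points)))
    qc["expected_lumen_hu"] = expected
    cl_con, frac_con = _segment_side(image, path, config, expected, keep_unreliable=False)
    _log(log, "lumen-contralateral", t0, reliable_fraction=round(frac_con, 3))
    if cl_con.degenerate:
        return PipelineOutput(_empty_result(image, cl_con.flags), "failed:lumen", qc, log)
    qc["contralateral_centerline"] = cl_con.points.tolist()
    qc["contralateral_radii"] = cl_con.radii.tolist()

    # -- step 2: mirror + deformable refinement + occluded-side lumen
    t0 = time.perf_counter()
    mirrored = mirror_centerline(cl_con, plane)
    registered = refine_by_registration(
        image, mirrored, plane, config.registration, rng_seed=config.rng_seed
    )
    qc["mirrored_centerline"] = mirrored.points.tolist()
    qc["registered_centerline"] = registered.points.tolist()
    _log(log, "mirror-register", t0, flags=registered.flags)

    t0 = time.perf_counter()
    cl_occ, frac_occ = _segment_side(image, registered, config, expected, keep_unreliable=True)
    _log(log, "lumen-occluded", t0, reliable_fraction=round(frac_occ, 3))
    if cl_occ.degenerate:
        return PipelineOutput(_empty_result(image, cl_occ.flags), "failed:lumen-occluded", qc, log)
    qc["occluded_centerline"] = cl_occ.points.tolist()
    qc["occluded_radii"] = cl_occ.radii.tolist()

    # -- occlusion detection on positionwise-resampled radius profiles
    t0 = time.perf_counter()
    con_rs = cl_con.resample(config.path_step_mm)
    occ_rs = cl_occ.resample(config.path_step_mm)
    n = min(len(con_rs), len(occ_rs))
    extent = detect_occlusion(
        occ_rs.radii[:n], con_rs.radii[:n],
        ratio_threshold=config.occlusion_ratio,
        arc_positions=occ_rs.arc_length[:n],
    )
    _log(log, "detect-occlusion", t0, empty=extent.empty,
         distal_is_vasculature_end=extent.distal_is_vasculature_end)
    if extent.empty:
        out = PipelineOutput(
            _empty_result(image, ["no-subthreshold-radius"], extent=extent),
            "no-occlusion", qc, log,
        )
        _write_outputs(case, out)
        return out
    qc["extent"] = {"proximal_s": extent.proximal_s, "distal_s": extent.distal_s,
                    "distal_is_vasculature_end": extent.distal_is_vasculature_end}

    # -- step 3: tubular mask, thresholds, region growing, measurement
    t0 = time.perf_counter()
    occ_trunc = Centerline(occ_rs.points[:n], radii=occ_rs.radii[:n])
    tube = build_tubular_mask(
        image, occ_trunc, con_rs.radii[:n], extent,
        dilation_voxels=config.morphology.dilation_n,
    )
    thresholds = compute_thresholds(image, con_rs, occ_trunc, extent)
    _log(log, "thresholds", t0, t_min=thresholds.t_min, t_max=thresholds.t_max)
    if thresholds.degenerate:
        out = PipelineOutput(
            _empty_result(image, ["degenerate-thresholds"], thresholds, extent),
            "failed:thresholds", qc, log,
        )
        _write_outputs(case, out)
        return out

    t0 = time.perf_counter()
    seed_s = extent.proximal_s + config.grow_seed_offset_mm
    seed_pt = occ_trunc.point_at(seed_s)
    recovery = np.array([
        occ_trunc.point_at(seed_s + d)
        for d in np.arange(0.25, config.grow_recovery_mm + 1e-9, 0.25)
    ])
    grown, gflags = region_grow(image, seed_pt, tube, thresholds, recovery_points=recovery)
    opened = morph_open(grown, config.morphology.opening_n)
    length, volume, mflags = measure(opened, occ_rs)
    _log(log, "grow-measure", t0, length_mm=length, volume_mm3=volume,
         flags=gflags + mflags)

    flags = gflags + mflags + (["distal-is-vasculature-end"] if extent.distal_is_vasculature_end else [])
    if opened.data.any():
        status = "ok"
    elif grown.data.any():
        status = "failed:morphology"  # opening annihilated a porous mask
    else:
        status = "failed:region-grow"
    result = ThrombusResult(
        mask=opened, length_mm=length, volume_mm3=volume,
        thresholds=thresholds, seed_point=seed_pt, extent=extent,
        status=status, flags=flags,
    )
    out = PipelineOutput(result, status, qc, log)
    _write_outputs(case, out)
    return out


def _crop_around_seeds(image: ImageVolume, seeds: SeedPair, margin_mm: float) -> ImageVolume:
    """Subvolume bounding both seeds plus a margin (world coords kept)."""
    lo_w = np.minimum(seeds.proximal, seeds.distal) - margin_mm
    hi_w = np.maximum(seeds.proximal, seeds.distal) + margin_mm
    lo = np.maximum(np.floor(image.world_to_index(lo_w)).astype(int), 0)
    hi = np.minimum(np.ceil(image.world_to_index(hi_w)).astype(int) + 1,
                    np.asarray(image.shape))
    sub = image.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return ImageVolume(np.ascontiguousarray(sub), image.spacing,
                       tuple(image.index_to_world(lo)))


def _write_outputs(case: CaseInput, out: PipelineOutput) -> None:
    if case.output_dir is None:
        return
    outdir = Path(case.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_volume(out.result.mask, outdir / "thrombus_mask.nii.gz")
    (outdir / "report.json").write_text(
        json.dumps({"case_id": case.case_id, **out.report}, indent=2, sort_keys=True)
    )
    (outdir / "qc.json").write_text(json.dumps(out.qc, indent=2, sort_keys=True))
    (outdir / "log.json").write_text(json.dumps(out.log, indent=2, sort_keys=True))
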