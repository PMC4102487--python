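"""Volume and sidecar I/O.

Volumes are read and written through SimpleITK (NIfTI ``.nii``/``.nii.gz``
and MetaImage ``.mha``/``.mhd``).  Internally everything is axis-aligned:
arrays are indexed (x, y, z) with ``world = origin + index * spacing`` in
mm.  Axis-permuted/flipped acquisitions are normalized on load; truly
oblique direction matrices are rejected with a diagnosis rather than
silently mis-measured.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .core import ImageVolume, SeedPair, SymmetryPlane

__all__ = [
    "load_volume",
    "save_volume",
    "load_sidecar",
    "save_sidecar",
    "write_phantom",
]

_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def load_volume(path) -> ImageVolume:
    """Read a NIfTI or MetaImage volume into the internal convention."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise ValueError(f"unreadable volume {path.name}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(
            f"{path.name}: expected a 3D volume, got {img.GetDimension()}D"
        )
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        if np.allclose(np.abs(direction) @ np.abs(direction.T), np.eye(3), atol=1e-6):
            img = sitk.DICOMOrient(img, "LPS")  # identity direction in ITK space
            direction = np.asarray(img.GetDirection()).reshape(3, 3)
        if not np.allclose(direction, np.eye(3), atol=1e-6):
            raise ValueError(
                f"{path.name}: oblique direction matrix not supported; "
                "resample to an axis-aligned grid first"
            )
    spacing = img.GetSpacing()
    if min(spacing) <= 0:
        raise ValueError(f"{path.name}: non-positive voxel spacing {spacing}")
    data = sitk.GetArrayFromImage(img).T  # (z,y,x) -> (x,y,z)
    return ImageVolume(np.ascontiguousarray(data), tuple(spacing), tuple(img.GetOrigin()))


def save_volume(vol: ImageVolume, path) -> Path:
    """Write a volume as NIfTI or MetaImage (chosen by suffix)."""
    path = Path(path)
    if not any(str(path).endswith(s) for s in _SUFFIXES):
        raise ValueError(f"unsupported volume suffix for {path.name}; use {_SUFFIXES}")
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
    return path


# ---------------------------------------------------------------------------
# JSON sidecars (seeds, symmetry plane, phantom ground truth)


def save_sidecar(path, seeds: SeedPair | None = None,
                 plane: SymmetryPlane | None = None, extra: dict | None = None) -> Path:
    payload: dict = dict(extra or {})
    if seeds is not None:
        payload["seeds"] = {
            "proximal": list(map(float, seeds.proximal)),
            "distal": list(map(float, seeds.distal)),
            "side_label": seeds.side_label,
        }
    if plane is not None:
        payload["symmetry_plane"] = {
            "point": list(map(float, plane.point)),
            "normal": list(map(float, plane.normal)),
        }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def load_sidecar(path) -> dict:
    """Parse a sidecar; returns a dict with 'seeds'/'symmetry_plane'
    rebuilt into their domain types when present."""
    payload = json.loads(Path(path).read_text())
    out = dict(payload)
    if "seeds" in payload:
        s = payload["seeds"]
        out["seeds"] = SeedPair(s["proximal"], s["distal"],
                                s.get("side_label", "contralateral"))
    if "symmetry_plane" in payload:
        p = payload["symmetry_plane"]
        out["symmetry_plane"] = SymmetryPlane(p["point"], p["normal"])
    return out


def write_phantom(result, outdir, fmt: str = "nii.gz") -> dict:
    """Write a phantom's image, masks, and ground-truth sidecar.

    Returns the mapping of written file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": save_volume(result.image, outdir / f"image.{fmt}"),
        "thrombus_mask": save_volume(result.thrombus_mask, outdir / f"thrombus_mask.{fmt}"),
        "lumen_mask_left": save_volume(result.lumen_mask_left, outdir / f"lumen_left.{fmt}"),
        "lumen_mask_right": save_volume(result.lumen_mask_right, outdir / f"lumen_right.{fmt}"),
    }
    truth = {
        "true_length_mm": float(result.true_length_mm),
        "true_volume_mm3": float(result.true_volume_mm3),
        "true_centerlines": {
            side: cl.points.tolist() for side, cl in result.true_centerlines.items()
        },
        "flags": list(result.flags),
    }
    paths["sidecar"] = save_sidecar(
        outdir / "ground_truth.json",
        seeds=result.seeds,
        plane=result.symmetry_plane,
        extra=truth,
    )
    return paths
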