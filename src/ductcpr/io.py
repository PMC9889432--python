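"""NIfTI, JSON and PNG I/O for volumes, masks, centerlines and CPR images.

Only axis-aligned NIfTI affines are supported (diagonal scaling plus
translation): the pipeline's world convention is ``world = origin +
index * spacing``, declared once and used everywhere.  Files with
rotated or sheared affines raise an explicit unsupported-orientation
error rather than being silently reinterpreted.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .grid import SegmentationMask, Volume3D
from .path import CenterlinePath


class UnsupportedOrientationError(ValueError):
    """NIfTI affine is not axis-aligned."""


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _check_axis_aligned(affine: np.ndarray, path) -> None:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.any(np.abs(off_diag) > 1e-6) or np.any(np.diag(rot) <= 0):
        raise UnsupportedOrientationError(
            f"{path}: only axis-aligned, positively-oriented affines are supported"
        )


def write_volume(volume: Volume3D, path) -> None:
    img = nib.Nifti1Image(
        np.asarray(volume.data, dtype=np.float32),
        _affine(volume.spacing_mm, volume.origin_mm),
    )
    nib.save(img, str(path))


def read_volume(path) -> Volume3D:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
        affine = img.affine
        data = np.asarray(img.dataobj, dtype=np.float32)
    except UnsupportedOrientationError:
        raise
    except Exception as exc:  # malformed header, truncated file, ...
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    _check_axis_aligned(affine, path)
    return Volume3D(data, tuple(np.diag(affine)[:3]), tuple(affine[:3, 3]))


def write_mask(mask: SegmentationMask, path) -> None:
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _affine(mask.spacing_mm, mask.origin_mm)
    )
    nib.save(img, str(path))


def read_mask(path) -> SegmentationMask:
    vol = read_volume(path)
    return SegmentationMask(vol.data > 0.5, vol.spacing_mm, vol.origin_mm)


def write_centerline_json(path_obj: CenterlinePath, path, extra: dict | None = None) -> None:
    d = path_obj.to_dict()
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2))


def read_centerline_json(path) -> CenterlinePath:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such centerline file: {path}")
    return CenterlinePath.from_dict(json.loads(path.read_text()))


def write_centerline_tsv(path_obj: CenterlinePath, mask_or_volume, path) -> None:
    """BED-like TSV of nearest voxel indices along the centerline."""
    idx = np.rint(mask_or_volume.world_to_index(path_obj.points)).astype(int)
    lines = ["#i\tj\tk\tsource"]
    for (i, j, k), src in zip(idx, path_obj.source):
        lines.append(f"{i}\t{j}\t{k}\t{src}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_cpr_png(cpr, path, window_hu: float = 400.0, level_hu: float = 50.0) -> None:
    """8-bit window/level rendering; the window is recorded in a sidecar."""
    lo, hi = level_hu - window_hu / 2, level_hu + window_hu / 2
    arr = np.clip((cpr.pixels - lo) / (hi - lo), 0.0, 1.0)
    Image.fromarray((arr * 255).astype(np.uint8)).save(str(path))
    Path(str(path) + ".json").write_text(
        json.dumps(
            {
                "window_hu": window_hu,
                "level_hu": level_hu,
                "row_spacing_mm": cpr.row_spacing_mm,
                "col_spacing_mm": cpr.col_spacing_mm,
                "frame_mode": cpr.frame_mode,
            },
            indent=2,
        )
    )


def write_cpr_nifti(cpr, path) -> None:
    img = nib.Nifti1Image(
        cpr.pixels[:, :, None].astype(np.float32),
        _affine((cpr.row_spacing_mm, cpr.col_spacing_mm, 1.0), (0, 0, 0)),
    )
    nib.save(img, str(path))
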