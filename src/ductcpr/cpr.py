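"""Curved planar reconstruction along a centerline, and MPD length.

A CPR image displays the whole winding course of the main pancreatic
duct in a single 2D image: each row resamples the volume along a lateral
line through one centerline point.  Two sweep conventions are provided:

* ``straightened`` — the lateral direction is the normal of a
  rotation-minimizing frame transported along the curve (no twist at
  inflections), so the duct is unrolled onto a straight axis;
* ``projected`` — the lateral direction is a fixed user direction
  orthogonalized against the local tangent, i.e. the curve is swept past
  a fixed viewing direction.  For a straight centerline this degenerates
  to an ordinary planar reformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .grid import Volume3D
from .path import CenterlinePath, DegeneratePathError, SOURCE_DUCT

PAD_HU = -1000.0  # CT air; fills samples that fall outside the volume


@dataclass
class CPRImage:
    pixels: np.ndarray                 # (rows = arc length, cols = lateral offset)
    row_spacing_mm: float
    col_spacing_mm: float
    frame_mode: str
    world_map: np.ndarray              # (rows, cols, 3) world mm of each sample
    pad_value: float = PAD_HU

    @property
    def center_col(self) -> int:
        return self.pixels.shape[1] // 2


@dataclass
class LengthMeasurement:
    total_mm: float
    per_segment_mm: list[float]

    @property
    def n_segments(self) -> int:
        return len(self.per_segment_mm)


def build_frames(
    path: CenterlinePath,
    initial_normal=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal (tangent, normal, binormal) frames at every path point.

    Tangents come from central differences; normals are transported by
    the double-reflection rotation-minimizing scheme, which avoids the
    twist the Frenet frame develops at curvature sign changes.
    """
    pts = path.points
    if len(pts) < 3:
        raise DegeneratePathError("build_frames needs >= 3 points")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(steps == 0):
        raise ValueError("coincident consecutive points")

    t = np.gradient(pts, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)

    # initial normal: caller-supplied, else world axis least aligned
    # with the first tangent; orthogonalized against it either way
    e = (
        np.asarray(initial_normal, dtype=float)
        if initial_normal is not None
        else np.eye(3)[int(np.argmin(np.abs(t[0])))]
    )
    n0 = e - np.dot(e, t[0]) * t[0]
    nrm = np.linalg.norm(n0)
    if nrm < 1e-9:
        raise ValueError("initial normal is parallel to the first tangent")
    n0 = n0 / nrm

    n = np.empty_like(t)
    n[0] = n0
    for i in range(len(pts) - 1):
        v1 = pts[i + 1] - pts[i]
        c1 = np.dot(v1, v1)
        r_l = n[i] - (2.0 / c1) * np.dot(v1, n[i]) * v1
        t_l = t[i] - (2.0 / c1) * np.dot(v1, t[i]) * v1
        v2 = t[i + 1] - t_l
        c2 = np.dot(v2, v2)
        ni = r_l if c2 < 1e-30 else r_l - (2.0 / c2) * np.dot(v2, r_l) * v2
        ni = ni - np.dot(ni, t[i + 1]) * t[i + 1]
        n[i + 1] = ni / np.linalg.norm(ni)
    b = np.cross(t, n)
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    return t, n, b


def generate_cpr(
    volume: Volume3D,
    path: CenterlinePath,
    lateral_halfwidth_mm: float = 20.0,
    sample_spacing_mm: float = 0.5,
    frame_mode: str = "straightened",
    projection_direction=(0.0, 1.0, 0.0),
    pad_value: float = PAD_HU,
    initial_normal=None,
) -> CPRImage:
    """Resample the volume into a single 2D CPR image along the path.

    Rows step along arc length at ``sample_spacing_mm``; columns step
    laterally over ±``lateral_halfwidth_mm``.  Intensities are trilinear
    interpolations; samples outside the volume take ``pad_value``.  The
    center column reproduces the centerline samples exactly.
    """
    if len(path) < 2 or path.total_length_mm <= 0:
        raise DegeneratePathError("generate_cpr needs a non-degenerate path")
    if lateral_halfwidth_mm <= 0 or sample_spacing_mm <= 0:
        raise ValueError("halfwidth and sample spacing must be positive")
    if frame_mode not in ("straightened", "projected"):
        raise ValueError(f"unknown frame_mode {frame_mode!r}")

    rows_path = path.resample(sample_spacing_mm)
    t, n, _ = build_frames(rows_path, initial_normal=initial_normal)

    if frame_mode == "straightened":
        lateral = n
    else:
        v = np.asarray(projection_direction, dtype=float)
        if np.linalg.norm(v) == 0:
            raise ValueError("projection_direction must be nonzero")
        v = v / np.linalg.norm(v)
        lateral = v[None, :] - (t @ v)[:, None] * t
        norms = np.linalg.norm(lateral, axis=1, keepdims=True)
        if np.any(norms < 1e-9):
            raise ValueError("projection_direction parallel to the path tangent")
        lateral = lateral / norms

    n_half = int(np.floor(lateral_halfwidth_mm / sample_spacing_mm))
    offsets = np.arange(-n_half, n_half + 1) * sample_spacing_mm
    world = (
        rows_path.points[:, None, :] + offsets[None, :, None] * lateral[:, None, :]
    )  # (R, C, 3)
    idx = volume.world_to_index(world.reshape(-1, 3)).T  # (3, R*C)
    pixels = map_coordinates(
        volume.data.astype(np.float64), idx, order=1, mode="constant", cval=pad_value
    ).reshape(world.shape[:2])
    return CPRImage(
        pixels=pixels,
        row_spacing_mm=float(sample_spacing_mm),
        col_spacing_mm=float(sample_spacing_mm),
        frame_mode=frame_mode,
        world_map=world,
        pad_value=pad_value,
    )


def measure_mpd_length(path: CenterlinePath) -> LengthMeasurement:
    """Total MPD length as the sum of per-segment polyline lengths.

    Segments are delimited by ``segment_breaks`` (duct interruptions);
    within each segment, leading/trailing fallback points are trimmed so
    only the duct course is measured.  A path with no duct-labeled points
    (pure pancreas-center fallback) counts as one whole segment.  When a
    tumor divides the duct, the sum of all segments is the total length.
    """
    if len(path) < 2:
        raise DegeneratePathError("measure_mpd_length needs >= 2 points")
    s = path.arc_length_mm
    is_duct = path.source == SOURCE_DUCT
    bounds = [0, *path.segment_breaks, len(path)]
    per_segment: list[float] = []
    any_duct = bool(is_duct.any())
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            continue
        if any_duct:
            inside = np.flatnonzero(is_duct[lo:hi])
            if inside.size < 2:
                continue
            a, b = lo + inside[0], lo + inside[-1]
        else:
            a, b = lo, hi - 1
        length = float(s[b] - s[a])
        if length > 0:
            per_segment.append(length)
    if not per_segment:
        per_segment = [float(s[-1] - s[0])]
    return LengthMeasurement(total_mm=float(sum(per_segment)), per_segment_mm=per_segment)
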