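"""Ordered 3D polylines with arc-length parameterization.

:class:`CenterlinePath` is the pipeline's central object: the phantom
generator emits one as ground truth, the centerline detector produces one
from masks, and the CPR/length stages consume one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SOURCE_DUCT = "duct"
SOURCE_FALLBACK = "fallback"


class DegeneratePathError(ValueError):
    """Path has fewer than 2 distinct points."""


@dataclass
class CenterlinePath:
    """Ordered world-coordinate polyline along the main pancreatic duct.

    Parameters
    ----------
    points
        (N, 3) world coordinates in mm, ordered head to tail (or tail to
        head; orientation is the caller's convention).
    source
        Per-point provenance label, ``"duct"`` where the point lies inside
        the segmented duct lumen and ``"fallback"`` where it was routed
        through the pancreas-center rule instead.
    segment_breaks
        Indices into ``points`` marking where the duct course is
        interrupted (e.g. by a tumor); each break index starts a new
        segment.
    """

    points: np.ndarray
    source: np.ndarray | None = None
    segment_breaks: tuple[int, ...] = ()

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")
        if self.source is None:
            self.source = np.full(len(self.points), SOURCE_DUCT, dtype=object)
        else:
            self.source = np.asarray(self.source, dtype=object)
            if len(self.source) != len(self.points):
                raise ValueError("source labels must match point count")
        self.segment_breaks = tuple(int(b) for b in self.segment_breaks)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def arc_length_mm(self) -> np.ndarray:
        """Cumulative arc length (mm), nondecreasing, starting at 0."""
        if len(self.points) == 1:
            return np.zeros(1)
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def total_length_mm(self) -> float:
        return float(self.arc_length_mm[-1])

    def resample(self, step_mm: float) -> "CenterlinePath":
        """Uniform arc-length resampling by linear interpolation."""
        if len(self.points) < 2:
            raise DegeneratePathError("cannot resample a path with < 2 points")
        s = self.arc_length_mm
        total = s[-1]
        if total <= 0:
            raise DegeneratePathError("path has zero length")
        n = max(2, int(np.ceil(total / step_mm)) + 1)
        s_new = np.linspace(0.0, total, n)
        pts = np.column_stack([np.interp(s_new, s, self.points[:, d]) for d in range(3)])
        # carry labels of the nearest original point
        nearest = np.searchsorted(s, s_new, side="left").clip(0, len(s) - 1)
        return CenterlinePath(pts, self.source[nearest])

    def to_dict(self) -> dict:
        return {
            "points_mm": self.points.tolist(),
            "source": self.source.tolist(),
            "segment_breaks": list(self.segment_breaks),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CenterlinePath":
        return cls(
            np.asarray(d["points_mm"], dtype=float),
            np.asarray(d["source"], dtype=object),
            tuple(d.get("segment_breaks", ())),
        )
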