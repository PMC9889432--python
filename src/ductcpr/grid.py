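"""Voxel-grid containers shared by every pipeline stage.

The package uses a single, explicit geometry convention:

* arrays are indexed ``[i, j, k]`` along world axes ``(x, y, z)``;
* voxel *centers* sit at ``world = origin + index * spacing`` (axis-aligned
  affines only, 0-based indices);
* spacings are per-axis millimetres and may be anisotropic (e.g. high
  in-plane resolution with thicker slices, as on contrast-enhanced
  pancreatic CT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridMismatchError(ValueError):
    """Two grid objects do not share shape/spacing/origin."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable signal."""


def _as_triple(x) -> tuple[float, float, float]:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"expected 3 components, got {arr.size}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class Volume3D:
    """Scalar voxel grid with anisotropic spacing and world origin.

    Intensities are HU-like floats (water 0, air about -1000).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        self.spacing_mm = _as_triple(self.spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices (..., 3) to world mm."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates (..., 3) to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def same_grid(self, other: "Volume3D | SegmentationMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


@dataclass
class SegmentationMask:
    """Binary voxel mask sharing a :class:`Volume3D` grid."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.data.ndim}")
        self.spacing_mm = _as_triple(self.spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def same_grid(self, other: "Volume3D | SegmentationMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def like(self, data: np.ndarray) -> "SegmentationMask":
        """New mask with the same grid but different voxel data."""
        return SegmentationMask(data, self.spacing_mm, self.origin_mm)


def require_same_grid(a, b, what: str = "inputs") -> None:
    if not a.same_grid(b):
        raise GridMismatchError(
            f"{what} must share one grid: "
            f"{a.shape}/{a.spacing_mm} vs {b.shape}/{b.spacing_mm}"
        )
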