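"""Core domain containers shared across the package.

Conventions used everywhere in :mod:`bladresp`:

* volumes are 3D arrays indexed ``(z, y, x)``, 0-based;
* physical spacing is ``(slice_thickness, row, col)`` in millimetres;
* boxes are half-open per-axis voxel intervals ``[lo, hi)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np


class ResponseLabel(Enum):
    """Pathologic outcome of a lesion pair after neoadjuvant chemotherapy.

    ``COMPLETE`` means post-treatment pathologic stage T0 (no residual
    tumor); ``NON_COMPLETE`` is any residual tumor (stage > T0).
    """

    COMPLETE = "complete"
    NON_COMPLETE = "non_complete"

    @property
    def is_complete(self) -> bool:
        return self is ResponseLabel.COMPLETE


@dataclass(frozen=True)
class RegionBox:
    """Axis-aligned voxel box, half-open ``[lo, hi)`` on each of (z, y, x)."""

    lo: Tuple[int, int, int]
    hi: Tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.lo) != 3 or len(self.hi) != 3:
            raise ValueError("RegionBox needs 3 axes (z, y, x)")
        for a, b in zip(self.lo, self.hi):
            if not (int(a) < int(b)):
                raise ValueError(f"box must satisfy lo < hi per axis, got {self.lo}..{self.hi}")
        object.__setattr__(self, "lo", tuple(int(v) for v in self.lo))
        object.__setattr__(self, "hi", tuple(int(v) for v in self.hi))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    @property
    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def contains_box(self, other: "RegionBox") -> bool:
        return all(sl <= ol and oh <= sh
                   for sl, sh, ol, oh in zip(self.lo, self.hi, other.lo, other.hi))

    def within_grid(self, shape: Sequence[int]) -> bool:
        return all(0 <= l and h <= s for l, h, s in zip(self.lo, self.hi, shape))

    @staticmethod
    def from_mask(mask: np.ndarray, margin: Sequence[int] = (0, 0, 0)) -> "RegionBox":
        """Tight bounding box of the nonzero voxels, padded by ``margin``
        and clipped to the grid."""
        if not mask.any():
            raise ValueError("cannot build a box from an empty mask")
        lo, hi = [], []
        for ax, m in zip(range(3), margin):
            proj = np.any(mask, axis=tuple(a for a in range(3) if a != ax))
            idx = np.flatnonzero(proj)
            lo.append(max(0, int(idx[0]) - int(m)))
            hi.append(min(mask.shape[ax], int(idx[-1]) + 1 + int(m)))
        return RegionBox(tuple(lo), tuple(hi))


@dataclass
class CTVolume:
    """A 3D CT intensity grid with anisotropic physical spacing.

    ``intensities`` is ``(z, y, x)``; ``spacing_mm`` is
    ``(slice_thickness, row_spacing, col_spacing)``.
    """

    intensities: np.ndarray
    spacing_mm: Tuple[float, float, float]
    origin_mm: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(f"CTVolume requires a 3D grid, got ndim={self.intensities.ndim}")
        if self.intensities.size == 0:
            raise ValueError("CTVolume grid is empty")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing_mm}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def crop(self, box: RegionBox) -> np.ndarray:
        if not box.within_grid(self.shape):
            raise ValueError(f"box {box.lo}..{box.hi} outside grid {self.shape}")
        return self.intensities[box.slices]


@dataclass
class SegmentationMask:
    """Binary lesion mask confined to a :class:`RegionBox` of a volume.

    ``data`` has the box's shape; voxel ``(z, y, x)`` of the mask maps to
    voxel ``box.lo + (z, y, x)`` of the parent volume.
    """

    data: np.ndarray
    box: RegionBox

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.box.shape:
            raise ValueError(f"mask shape {self.data.shape} != box shape {self.box.shape}")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def volume_mm3(self, spacing_mm: Sequence[float]) -> float:
        return self.n_voxels * float(np.prod(spacing_mm))

    def to_full_grid(self, shape: Sequence[int]) -> np.ndarray:
        """Embed the box-local mask into a full-size grid of ``shape``."""
        full = np.zeros(tuple(shape), dtype=bool)
        full[self.box.slices] = self.data
        return full

    @staticmethod
    def from_full_grid(full: np.ndarray, box: RegionBox) -> "SegmentationMask":
        return SegmentationMask(full[box.slices].copy(), box)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


@dataclass
class FeatureVector:
    """Ordered, named real-valued radiomics features.

    ``bank_id`` identifies the feature bank ("SL", "ROI", "SL_pct_change");
    vectors from the same bank share names and order.
    """

    names: Tuple[str, ...]
    values: np.ndarray
    bank_id: str

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.names) != self.values.size:
            raise ValueError("names and values must be 1D and the same length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite (apply sentinel policy upstream)")

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def same_bank(self, other: "FeatureVector") -> bool:
        return self.bank_id == other.bank_id and self.names == other.names
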