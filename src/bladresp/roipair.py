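"""Lesion ROI extraction and pre/post paired-ROI construction.

From every slice of a segmented lesion, 32-row × 16-column patches are
extracted on a stride grid, keeping windows whose footprint is (mostly)
covered by the lesion; a lesion smaller than the window on a slice yields a
single patch centred at the lesion centroid. Pre- and post-treatment
patches of the same lesion are then pasted side-by-side (pre on the left)
into 32×32 paired ROIs that carry the pathology-derived response label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .types import CTVolume, ResponseLabel, SegmentationMask

ROI_ROWS = 32
ROI_COLS = 16

_STAGE_RE = re.compile(r"^T(?:0|A|IS|[1-4][AB]?)$")


def label_from_stage(post_stage: str) -> ResponseLabel:
    """Map a post-treatment pathologic T stage to the binary response label.

    Stage T0 (no residual tumor) is a complete response; any other valid
    stage (Ta, Tis, T1–T4 and their a/b sub-stages) is non-complete.
    """
    stage = str(post_stage).strip().upper()
    if not _STAGE_RE.match(stage):
        raise ValueError(f"unknown pathologic T stage: {post_stage!r}")
    return ResponseLabel.COMPLETE if stage == "T0" else ResponseLabel.NON_COMPLETE


@dataclass
class LesionROI:
    """One 32×16 intensity patch from a single slice of one lesion."""

    patch: np.ndarray
    lesion_id: str
    timepoint: str          # "pre" | "post"
    slice_index: int
    anchor: Tuple[int, int]  # (row, col) of the patch origin in the slice

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=float)
        if self.patch.shape != (ROI_ROWS, ROI_COLS):
            raise ValueError(f"ROI patch must be {ROI_ROWS}x{ROI_COLS}, "
                             f"got {self.patch.shape}")
        if self.timepoint not in ("pre", "post"):
            raise ValueError(f"timepoint must be 'pre' or 'post', got {self.timepoint!r}")


@dataclass
class PairedROI:
    """A 32×32 patch: pre-treatment left half, post-treatment right half."""

    patch: np.ndarray
    pre_source: LesionROI
    post_source: LesionROI
    label: ResponseLabel

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=float)
        if self.patch.shape != (ROI_ROWS, 2 * ROI_COLS):
            raise ValueError("paired ROI must be 32x32")

    @property
    def pre_half(self) -> np.ndarray:
        return self.patch[:, :ROI_COLS]

    @property
    def post_half(self) -> np.ndarray:
        return self.patch[:, ROI_COLS:]


def _clip_anchor(center: float, size: int, limit: int) -> int:
    a = int(round(center - size / 2.0))
    return max(0, min(a, limit - size))


def extract_rois(vol: CTVolume, mask: SegmentationMask, stride: int = 8,
                 coverage: float = 0.75, lesion_id: str = "lesion",
                 timepoint: str = "pre") -> List[LesionROI]:
    """Extract 32×16 ROIs from every slice with lesion pixels.

    On each slice, stride-spaced windows fully inside the slice are kept
    when at least ``coverage`` of the window footprint lies within the
    lesion mask. If no window qualifies on a slice (lesion smaller than
    the ROI there), a single ROI centred at the lesion centroid of that
    slice is extracted instead (clipped to the slice bounds).
    """
    if mask.is_empty:
        raise ValueError("empty mask")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    full = mask.to_full_grid(vol.shape)
    nrows, ncols = vol.shape[1], vol.shape[2]
    if nrows < ROI_ROWS or ncols < ROI_COLS:
        raise ValueError("volume slices smaller than the ROI size")

    rois: List[LesionROI] = []
    for z in range(vol.shape[0]):
        sl_mask = full[z]
        n_pix = int(sl_mask.sum())
        if n_pix == 0:
            continue
        ys, xs = np.nonzero(sl_mask)
        found = []
        r0, r1 = int(ys.min()), int(ys.max())
        c0, c1 = int(xs.min()), int(xs.max())
        # stride lattice anchored at the slice's lesion bounding box
        row_anchors = range(r0, min(r1 + 1, nrows - ROI_ROWS + 1), stride)
        col_anchors = range(c0, min(c1 + 1, ncols - ROI_COLS + 1), stride)
        area = ROI_ROWS * ROI_COLS
        for r, c in product(row_anchors, col_anchors):
            inside = sl_mask[r:r + ROI_ROWS, c:c + ROI_COLS].sum()
            if inside >= coverage * area:
                found.append((r, c))
        if not found:
            r = _clip_anchor(float(ys.mean()), ROI_ROWS, nrows)
            c = _clip_anchor(float(xs.mean()), ROI_COLS, ncols)
            found = [(r, c)]
        for r, c in found:
            rois.append(LesionROI(
                patch=vol.intensities[z, r:r + ROI_ROWS, c:c + ROI_COLS].copy(),
                lesion_id=lesion_id, timepoint=timepoint,
                slice_index=z, anchor=(r, c)))
    return rois


def pair_rois(pre: Sequence[LesionROI], post: Sequence[LesionROI],
              label: ResponseLabel, max_pairs: Optional[int] = None,
              seed: int = 0) -> List[PairedROI]:
    """Combine pre/post ROIs of one lesion into labeled 32×32 paired ROIs.

    All Cartesian combinations are formed; when ``max_pairs`` is given and
    smaller, a seeded uniform subsample (without replacement) is kept.
    """
    if not pre or not post:
        raise ValueError("pre and post ROI lists must be nonempty")
    n = len(pre) * len(post)
    idx = np.arange(n)
    if max_pairs is not None and max_pairs < n:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=max_pairs, replace=False))
    out: List[PairedROI] = []
    for k in idx:
        i, j = divmod(int(k), len(post))
        patch = np.hstack([pre[i].patch, post[j].patch])
        out.append(PairedROI(patch=patch, pre_source=pre[i],
                             post_source=post[j], label=label))
    return out
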