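"""Auto-Initialized Cascaded Level Sets (AI-CALS) lesion segmentation.

Segments a bladder lesion inside a user-drawn 3D box in three stages:

1. **Preprocessing** — Gaussian smoothing plus anisotropic diffusion, then
   derivative filters for the gradient magnitude / vector fields, and a
   rank transform of the gradient magnitude (scaled to [0, 1]).
2. **Initial surface** — gray-level thresholding of the smoothed region
   (mean ± 3·SD band), morphological dilation (spherical element, radius 2
   voxels), 3D flood fill, matching erosion, and extraction of the largest
   connected component.
3. **Level-set refinement** — the initial surface is propagated toward the
   lesion boundary by a cascade of a 3D geodesic active contour followed by
   per-slice 2D geodesic active contours. The speed image is a sigmoid
   edge-stopping function of the gradient-magnitude rank, so propagation
   stalls on the strongest edges in the box regardless of absolute contrast.

The whole chain is deterministic: no randomness anywhere.

Notes on conventions: the threshold statistics are taken over a central
core of the box rather than the full box — the user box is drawn around
the lesion, so its centre is lesion tissue, and full-box statistics would
put essentially every voxel inside a mean ± 3·SD band. Intensities are
standardized (zero mean, unit variance over the box) before the nonlinear
diffusion so the preprocessing behaves identically across CT intensity
scales; the smoothed image is mapped back to the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.stats import rankdata

from .types import CTVolume, RegionBox, SegmentationMask


@dataclass
class SegmentationOptions:
    """Tunables of the three AI-CALS stages (all deterministic)."""

    gaussian_sigma_mm: float = 1.0      # physical smoothing scale, per axis
    diffusion_iters: int = 5
    diffusion_conductance: float = 1.0
    threshold_core_fraction: float = 0.3  # central fraction of the box used for mean/SD
    morph_radius_vox: int = 2
    n3d: int = 60
    n2d: int = 30
    propagation: float = 0.4
    curvature: float = 0.6
    advection: float = 2.0
    speed_sigmoid_center: float = 0.8   # grad-rank level treated as "edge"
    speed_sigmoid_width: float = 0.05
    face_touch_guard: float = 0.5       # divergence guard threshold


@dataclass
class PreprocessedRegion:
    """Outputs of stage 1, all on the box grid.

    ``grad_vec`` is shaped ``(3, *box_shape)`` ordered (z, y, x);
    ``grad_rank`` holds the empirical rank of the gradient magnitude within
    the box, scaled to [0, 1] (ties averaged, constant regions map to 0).
    """

    smoothed: np.ndarray
    grad_mag: np.ndarray
    grad_vec: np.ndarray
    grad_rank: np.ndarray
    spacing_mm: Tuple[float, float, float]
    box: RegionBox


def _ball(radius: int) -> np.ndarray:
    """Spherical (voxel-unit) structuring element of the given radius."""
    ax = np.arange(-radius, radius + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return (zz ** 2 + yy ** 2 + xx ** 2) <= radius ** 2


def preprocess(vol: CTVolume, box: RegionBox,
               opts: Optional[SegmentationOptions] = None) -> PreprocessedRegion:
    """Stage 1: smooth, diffuse, and build gradient + gradient-rank fields."""
    opts = opts or SegmentationOptions()
    if not box.within_grid(vol.shape):
        raise ValueError(f"box {box.lo}..{box.hi} outside volume grid {vol.shape}")
    if any(s < 5 for s in box.shape):
        raise ValueError(f"box {box.shape} smaller than the filter support (5 voxels)")

    region = vol.crop(box).astype(float)

    mu, sd = float(region.mean()), float(region.std())
    norm = (region - mu) / sd if sd > 1e-12 else np.zeros_like(region)

    sigma_vox = [opts.gaussian_sigma_mm / s for s in vol.spacing_mm]
    sm = ndimage.gaussian_filter(norm, sigma=sigma_vox, mode="nearest")
    if opts.diffusion_iters > 0:
        img = sitk.GetImageFromArray(sm.astype(np.float64))
        img = sitk.GradientAnisotropicDiffusion(
            img, timeStep=0.03, conductanceParameter=opts.diffusion_conductance,
            numberOfIterations=int(opts.diffusion_iters))
        sm = sitk.GetArrayFromImage(img)

    grad = np.gradient(sm, *vol.spacing_mm)          # list of 3 arrays (z, y, x)
    grad_vec = np.stack(grad, axis=0)
    grad_mag = np.sqrt(np.sum(grad_vec ** 2, axis=0))

    if grad_mag.max() - grad_mag.min() < 1e-15:
        grad_rank = np.zeros_like(grad_mag)
    else:
        flat = rankdata(grad_mag.ravel(), method="average")
        grad_rank = ((flat - 1.0) / (flat.size - 1.0)).reshape(grad_mag.shape)

    smoothed = sm * sd + mu if sd > 1e-12 else np.full_like(sm, mu)
    return PreprocessedRegion(smoothed=smoothed, grad_mag=grad_mag,
                              grad_vec=grad_vec, grad_rank=grad_rank,
                              spacing_mm=vol.spacing_mm, box=box)


def morphological_cleanup(obj: np.ndarray, radius: int = 2) -> np.ndarray:
    """Dilation (spherical element), 3D flood fill, matching erosion.

    Connects neighbouring components and closes internal holes; leaves an
    already-solid convex object unchanged.
    """
    ball = _ball(radius)
    out = ndimage.binary_dilation(obj, structure=ball)
    out = ndimage.binary_fill_holes(out)
    return ndimage.binary_erosion(out, structure=ball, border_value=1)


def initial_surface(preproc: PreprocessedRegion,
                    box: Optional[RegionBox] = None,
                    opts: Optional[SegmentationOptions] = None) -> SegmentationMask:
    """Stage 2: gray-level threshold band, then dilate → flood fill → erode.

    The average and SD defining the ± 3·SD object band are estimated
    robustly (median and MAD-derived sigma) over the central core of the
    box (``threshold_core_fraction`` of each axis): the user box is drawn
    around the lesion, so its core is lesion tissue, and robust estimates
    keep partial-volume and neighbouring-tissue voxels from inflating the
    band. A zero spread (flat region) degenerates to labeling the whole
    box as object. Returns the largest 26-connected component.
    """
    opts = opts or SegmentationOptions()
    box = box or preproc.box
    sm = preproc.smoothed

    core = tuple(
        slice(int(round(n * (1 - opts.threshold_core_fraction) / 2)),
              max(int(round(n * (1 + opts.threshold_core_fraction) / 2)),
                  int(round(n * (1 - opts.threshold_core_fraction) / 2)) + 1))
        for n in sm.shape)
    vals = sm[core]
    mu = float(np.median(vals))
    sd = 1.4826 * float(np.median(np.abs(vals - mu)))  # robust sigma
    if sd == 0.0 and float(vals.std()) > 0:
        sd = float(vals.std())

    obj = np.abs(sm - mu) <= 3.0 * sd
    if not obj.any():
        raise ValueError("empty object region after thresholding")

    obj = morphological_cleanup(obj, opts.morph_radius_vox)
    if not obj.any():
        raise ValueError("object region vanished during morphological cleanup")

    labels, n = ndimage.label(obj, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        obj = labels == (int(np.argmax(sizes)) + 1)
    return SegmentationMask(obj, box)


def _speed_image(grad_rank: np.ndarray, opts: SegmentationOptions) -> np.ndarray:
    """Sigmoid edge-stopping function: ≈1 in flat regions, →0 on top-ranked edges."""
    z = (grad_rank - opts.speed_sigmoid_center) / opts.speed_sigmoid_width
    return 1.0 / (1.0 + np.exp(np.clip(z, -60, 60)))


def _gac(mask: np.ndarray, speed: np.ndarray, spacing_xyz, n_iter: int,
         opts: SegmentationOptions) -> np.ndarray:
    """One geodesic-active-contour run (2D or 3D) seeded from ``mask``."""
    init = sitk.GetImageFromArray(mask.astype(np.uint8))
    init.SetSpacing(spacing_xyz)
    phi = sitk.SignedMaurerDistanceMap(init, insideIsPositive=False,
                                       squaredDistance=False, useImageSpacing=True)
    phi = sitk.Cast(phi, sitk.sitkFloat32)
    feat = sitk.GetImageFromArray(speed.astype(np.float32))
    feat.SetSpacing(spacing_xyz)
    f = sitk.GeodesicActiveContourLevelSetImageFilter()
    f.SetPropagationScaling(opts.propagation)
    f.SetCurvatureScaling(opts.curvature)
    f.SetAdvectionScaling(opts.advection)
    f.SetMaximumRMSError(1e-10)
    f.SetNumberOfIterations(int(n_iter))
    out = f.Execute(phi, feat)
    return sitk.GetArrayFromImage(out) < 0


def _touches_faces(mask: np.ndarray, threshold: float) -> bool:
    faces = [mask[0], mask[-1], mask[:, 0], mask[:, -1], mask[:, :, 0], mask[:, :, -1]]
    covered = sum(int(f.sum()) for f in faces)
    total = sum(f.size for f in faces)
    return covered >= threshold * total


def levelset_refine(init: SegmentationMask, preproc: PreprocessedRegion,
                    opts: Optional[SegmentationOptions] = None) -> SegmentationMask:
    """Stage 3: cascade of a 3D then per-slice 2D geodesic active contours.

    With ``n3d = n2d = 0`` the initialization is returned unchanged. If the
    evolving mask ever covers ≥ ``face_touch_guard`` of the box faces the
    cascade stops with a warning (divergence guard).
    """
    opts = opts or SegmentationOptions()
    if init.is_empty:
        raise ValueError("initial segmentation is empty")
    if opts.n3d == 0 and opts.n2d == 0:
        return SegmentationMask(init.data.copy(), init.box)

    sz, sy, sx = preproc.spacing_mm
    speed = _speed_image(preproc.grad_rank, opts)
    mask = init.data.astype(bool)

    if opts.n3d > 0:
        refined = _gac(mask, speed, (sx, sy, sz), opts.n3d, opts)
        if refined.any():
            mask = refined
        if _touches_faces(mask, opts.face_touch_guard):
            warnings.warn("level set touched the box faces; stopping refinement")
            return SegmentationMask(mask, init.box)

    if opts.n2d > 0:
        out = np.zeros_like(mask)
        for z in range(mask.shape[0]):
            if not mask[z].any():
                continue
            sl = _gac(mask[z], speed[z], (sx, sy), opts.n2d, opts)
            out[z] = sl if sl.any() else mask[z]
        if out.any():
            mask = out
        if _touches_faces(mask, opts.face_touch_guard):
            warnings.warn("level set touched the box faces; stopping refinement")
    return SegmentationMask(mask, init.box)


def segment_lesion(vol: CTVolume, box: RegionBox,
                   opts: Optional[SegmentationOptions] = None) -> SegmentationMask:
    """Run all three AI-CALS stages on one lesion box."""
    opts = opts or SegmentationOptions()
    pre = preprocess(vol, box, opts)
    init = initial_surface(pre, box, opts)
    return levelset_refine(init, pre, opts)
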