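"""Synthetic pre/post-treatment CT lesion pairs with known ground truth.

The phantom emulates the kind of data the response-assessment pipeline is
built for: a roughly ellipsoidal bladder (dark urine-filled lumen inside a
soft-tissue wall) carrying a wall-attached, irregular, textured lesion at
two time points, sampled on an anisotropic CT grid with additive noise.
A cohort generator draws cases with a controllable complete-response rate;
complete responders have their post-treatment lesion removed entirely
(optionally replaced by benign residual wall thickening, a known confounder
for human readers).

The lesion is a sphere whose radius is modulated by a seeded low-frequency
radial perturbation, placed tangent to the outer bladder surface so that it
overlaps the wall and protrudes into the lumen. Lesion texture is seeded
Gaussian noise smoothed to a configurable correlation length, which gives
run-length texture features a controllable signal.

All randomness flows from one root seed through named per-case substreams,
so a cohort is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import CTVolume, RegionBox, ResponseLabel, SegmentationMask

#: relative semi-axis scale of the bladder ellipsoid on (z, y, x)
_BLADDER_AXES = (0.85, 1.0, 1.1)
#: direction (z, y, x) from the bladder centre to the lesion attachment point
_LESION_DIRECTION = (0.15, 0.95, 0.25)


@dataclass
class PhantomParams:
    """Parameters of one synthetic pre/post lesion pair.

    Intensities are HU-like arbitrary units. ``lesion_contrast`` is the
    lesion's mean level above ``lumen_level``; ``lesion_radius_post_mm = 0``
    encodes a complete response (the post volume carries no lesion).
    """

    grid_shape: Tuple[int, int, int] = (28, 96, 96)
    spacing_mm: Tuple[float, float, float] = (3.0, 0.75, 0.75)
    background_level: float = 40.0
    noise_sd: float = 5.0
    bladder_radius_mm: float = 28.0
    wall_thickness_mm: float = 3.0
    lumen_level: float = 10.0
    wall_level: float = 45.0
    lesion_radius_pre_mm: float = 10.0
    lesion_radius_post_mm: float = 6.0
    lesion_contrast: float = 70.0
    lesion_contrast_post: Optional[float] = None
    texture_corr_length_mm: float = 2.0
    texture_amplitude: float = 8.0
    shape_irregularity: float = 0.2
    residual_wall_thickening: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bladder_radius_mm <= 0 or self.lesion_radius_pre_mm <= 0:
            raise ValueError("radii must be > 0")
        if self.lesion_radius_post_mm < 0:
            raise ValueError("lesion_radius_post_mm must be >= 0")
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall_thickness_mm must be > 0")

    @property
    def label(self) -> ResponseLabel:
        return (ResponseLabel.COMPLETE if self.lesion_radius_post_mm == 0
                else ResponseLabel.NON_COMPLETE)


@dataclass
class SyntheticCase:
    """One synthetic lesion pair with ground truth."""

    case_id: str
    pre: CTVolume
    post: CTVolume
    true_mask_pre: SegmentationMask
    true_mask_post: Optional[SegmentationMask]
    box_pre: RegionBox
    box_post: RegionBox
    label: ResponseLabel
    params: PhantomParams


def _coords_mm(shape: Sequence[int], spacing: Sequence[float]) -> List[np.ndarray]:
    """Per-axis physical coordinates (mm) centred on the grid centre."""
    axes = []
    for n, s in zip(shape, spacing):
        c = (np.arange(n) - (n - 1) / 2.0) * s
        axes.append(c)
    return np.meshgrid(*axes, indexing="ij")


def _smooth_noise(shape: Sequence[int], spacing: Sequence[float],
                  corr_length_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian field with the given correlation length."""
    raw = rng.standard_normal(tuple(shape))
    sigma_vox = [max(corr_length_mm / s, 1e-6) for s in spacing]
    sm = gaussian_filter(raw, sigma=sigma_vox, mode="nearest")
    sd = sm.std()
    if sd < 1e-12:
        return np.zeros_like(sm)
    return (sm - sm.mean()) / sd


def _bladder_norm_radius(zz, yy, xx, radius_mm: float):
    az, ay, ax = (radius_mm * a for a in _BLADDER_AXES)
    return np.sqrt((zz / az) ** 2 + (yy / ay) ** 2 + (xx / ax) ** 2)


def _lesion_mask(zz, yy, xx, center: np.ndarray, radius_mm: float,
                 irregularity: float, perturb: np.ndarray,
                 rnorm: np.ndarray) -> np.ndarray:
    d = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    local_radius = radius_mm * (1.0 + irregularity * perturb)
    return (d <= local_radius) & (rnorm <= 1.0)


def generate_case(params: PhantomParams, case_id: str = "case") -> SyntheticCase:
    """Build one pre/post volume pair with ground-truth masks and boxes.

    Deterministic given ``params.seed``; the pre- and post-treatment lesions
    share the same attachment site and radial perturbation so that partial
    response looks like shrinkage of the same lesion.
    """
    p = params
    # tangent-inside placement requires the lesion to fit in the bladder
    if p.lesion_radius_pre_mm >= 0.8 * p.bladder_radius_mm:
        raise ValueError(
            f"lesion radius {p.lesion_radius_pre_mm} mm too large for bladder "
            f"radius {p.bladder_radius_mm} mm")

    zz, yy, xx = _coords_mm(p.grid_shape, p.spacing_mm)
    rnorm = _bladder_norm_radius(zz, yy, xx, p.bladder_radius_mm)
    wall_frac = p.wall_thickness_mm / p.bladder_radius_mm
    inside = rnorm <= 1.0
    lumen = rnorm <= 1.0 - wall_frac

    # outer-surface distance along the attachment direction
    direction = np.asarray(_LESION_DIRECTION, dtype=float)
    direction /= np.linalg.norm(direction)
    axes_mm = np.array([p.bladder_radius_mm * a for a in _BLADDER_AXES])
    surf_dist = 1.0 / np.sqrt(np.sum((direction / axes_mm) ** 2))

    ss = np.random.SeedSequence([int(p.seed) & 0x7FFFFFFF, 0xB1AD])
    streams = {name: np.random.default_rng(np.random.SeedSequence(
        entropy=ss.entropy, spawn_key=(i,)))
        for i, name in enumerate(["shape", "texture_pre", "texture_post",
                                  "noise_pre", "noise_post"])}

    perturb = _smooth_noise(p.grid_shape, p.spacing_mm,
                            max(p.texture_corr_length_mm * 3, 4.0), streams["shape"])

    def build(radius_mm: float, contrast: float, texture_rng, noise_rng,
              thickened: bool):
        img = np.full(p.grid_shape, p.background_level, dtype=float)
        img[inside] = p.wall_level
        img[lumen] = p.lumen_level
        mask = None
        if radius_mm > 0:
            center = direction * (surf_dist - radius_mm)
            mask = _lesion_mask(zz, yy, xx, center, radius_mm,
                                p.shape_irregularity, perturb, rnorm)
            texture = _smooth_noise(p.grid_shape, p.spacing_mm,
                                    p.texture_corr_length_mm, texture_rng)
            img[mask] = p.lumen_level + contrast + p.texture_amplitude * texture[mask]
        elif thickened:
            # benign residual wall thickening at the former lesion site
            site = direction * (surf_dist - p.lesion_radius_pre_mm)
            d = np.sqrt((zz - site[0]) ** 2 + (yy - site[1]) ** 2 + (xx - site[2]) ** 2)
            thick = (d <= 1.2 * p.lesion_radius_pre_mm) & lumen & \
                (rnorm > 1.0 - 2.5 * wall_frac)
            img[thick] = p.wall_level
        if p.noise_sd > 0:
            img += noise_rng.normal(0.0, p.noise_sd, size=p.grid_shape)
        return img, mask

    pre_img, pre_mask = build(p.lesion_radius_pre_mm, p.lesion_contrast,
                              streams["texture_pre"], streams["noise_pre"], False)
    contrast_post = (p.lesion_contrast if p.lesion_contrast_post is None
                     else p.lesion_contrast_post)
    post_img, post_mask = build(p.lesion_radius_post_mm, contrast_post,
                                streams["texture_post"], streams["noise_post"],
                                p.residual_wall_thickening)

    margin = (2, 6, 6)
    box_pre = RegionBox.from_mask(pre_mask, margin)
    pre_seg = SegmentationMask.from_full_grid(pre_mask, box_pre)
    if post_mask is not None and post_mask.any():
        box_post = RegionBox.from_mask(post_mask, margin)
        post_seg = SegmentationMask.from_full_grid(post_mask, box_post)
    else:
        box_post = box_pre  # same site, nothing left to see
        post_seg = None

    label = p.label
    return SyntheticCase(
        case_id=case_id,
        pre=CTVolume(pre_img, p.spacing_mm),
        post=CTVolume(post_img, p.spacing_mm),
        true_mask_pre=pre_seg,
        true_mask_post=post_seg,
        box_pre=box_pre,
        box_post=box_post,
        label=label,
        params=p,
    )


#: cohort sampling ranges used when the caller does not override them;
#: radii and contrast spans loosely mirror the spread of lesion sizes
#: visible in clinical series
DEFAULT_PARAM_RANGES: Dict[str, Tuple[float, float]] = {
    "lesion_radius_pre_mm": (7.0, 14.0),
    "lesion_contrast": (60.0, 90.0),
    "texture_corr_length_mm": (1.5, 3.0),
    "texture_amplitude": (5.0, 9.0),
    "shrinkage": (0.55, 0.9),        # post/pre radius ratio for non-responders
    "contrast_retention": (0.75, 1.0),  # post/pre contrast ratio for non-responders
}


def draw_labels(n_cases: int, response_rate: float, seed: int) -> np.ndarray:
    """The seeded label draw used by :func:`generate_cohort` (replayable)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0]))
    return rng.random(n_cases) < response_rate


def generate_cohort(n_cases: int, response_rate: float,
                    params_ranges: Optional[Dict[str, Tuple[float, float]]] = None,
                    seed: int = 0,
                    base_params: Optional[PhantomParams] = None,
                    thickening_prob: float = 0.0) -> List[SyntheticCase]:
    """Draw a cohort of synthetic lesion pairs.

    ``response_rate`` controls the fraction of complete responders (the
    training cohort this emulates had 28/104 ≈ 27%). Per-case geometry and
    texture parameters are drawn uniformly within ``params_ranges``;
    responders get an empty post-treatment lesion (with probability
    ``thickening_prob``, benign wall thickening replaces it).
    """
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    if not 0.0 <= response_rate <= 1.0:
        raise ValueError("response_rate must lie in [0, 1]")
    ranges = dict(DEFAULT_PARAM_RANGES)
    if params_ranges:
        ranges.update(params_ranges)
    base = base_params or PhantomParams()

    responders = draw_labels(n_cases, response_rate, seed)
    cases: List[SyntheticCase] = []
    for i in range(n_cases):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 1, i]))

        def u(key: str) -> float:
            lo, hi = ranges[key]
            return float(rng.uniform(lo, hi))

        r_pre = u("lesion_radius_pre_mm")
        if responders[i]:
            r_post, c_post = 0.0, None
            thick = bool(rng.random() < thickening_prob)
        else:
            r_post = r_pre * u("shrinkage")
            thick = False
        contrast = u("lesion_contrast")
        c_post = None if responders[i] else contrast * u("contrast_retention")
        params = replace(
            base,
            lesion_radius_pre_mm=r_pre,
            lesion_radius_post_mm=r_post,
            lesion_contrast=contrast,
            lesion_contrast_post=c_post,
            texture_corr_length_mm=u("texture_corr_length_mm"),
            texture_amplitude=u("texture_amplitude"),
            residual_wall_thickening=thick,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        cases.append(generate_case(params, case_id=f"case{i:03d}"))
    return cases
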