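"""Radiomics feature banks.

Two banks are computed:

* **SL bank** (91 features) — on the segmented 3D lesion after isotropic
  resampling: morphology (volume, surface area, central-slice shape and
  Fourier descriptors), gray-level statistics with a peripheral-shell
  contrast feature, gray-level run-length texture statistics (3D over 13
  directions and central-slice 2D over 4 directions, at several
  quantizations), and gradient-field statistics over the lesion surface.
  For a temporal lesion pair the classifier input is the per-feature
  percent change from pre- to post-treatment.
* **ROI bank** (38 features) — on a 32×32 paired pre/post ROI: gray-level
  histogram statistics plus 2D run-length statistics; ROI vectors are
  averaged per lesion before classification.

Conventions: run-length quantization uses equal-width bins over the masked
min–max range (a constant region collapses to a single bin); skewness and
kurtosis of a zero-variance region are defined as 0; the contrast feature
is Michelson-style against a 3-voxel peripheral shell on the central slice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure

from .types import CTVolume, FeatureVector, RegionBox, SegmentationMask

EPS = 1e-9
PCT_SENTINEL = 1000.0

#: the 13 canonical 3D run directions (one per opposite pair)
DIRECTIONS_3D: Tuple[Tuple[int, int, int], ...] = tuple(
    d for d in [
        (0, 0, 1), (0, 1, 0), (1, 0, 0),
        (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ])

#: the 4 canonical 2D run directions
DIRECTIONS_2D: Tuple[Tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

RLS_NAMES = ("sre", "lre", "gln", "rln", "rp",
             "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge")


# ------------------------------------------------------------------ resampling

def resample_isotropic(vol: CTVolume, mask: SegmentationMask
                       ) -> Tuple[CTVolume, SegmentationMask]:
    """Resample the lesion box to cubic voxels at the in-plane pixel size.

    Intensities are interpolated trilinearly, the mask nearest-neighbor.
    The returned volume/mask live on the resampled box grid (the mask's box
    spans the whole returned grid).
    """
    sz, sy, sx = vol.spacing_mm
    target = float(min(sy, sx))
    if target <= 0:
        raise ValueError("degenerate spacing")
    region = vol.crop(mask.box).astype(float)
    zoom = (sz / target, sy / target, sx / target)
    img = ndimage.zoom(region, zoom, order=1, mode="nearest", grid_mode=True)
    msk = ndimage.zoom(mask.data.astype(np.uint8), zoom, order=0,
                       mode="nearest", grid_mode=True).astype(bool)
    if img.shape != msk.shape:  # guard against rounding mismatches
        shape = tuple(min(a, b) for a, b in zip(img.shape, msk.shape))
        img = img[tuple(slice(s) for s in shape)]
        msk = msk[tuple(slice(s) for s in shape)]
    box = RegionBox((0, 0, 0), img.shape)
    return (CTVolume(img, (target, target, target)),
            SegmentationMask(msk, box))


# ------------------------------------------------------------------ run length

@dataclass
class RLMatrix:
    """Gray-level run-length matrix for one direction.

    ``counts[g, r]`` is the number of maximal runs of quantized level
    ``g`` (0-based) with length ``r + 1``.
    """

    counts: np.ndarray
    n_levels: int
    direction: Tuple[int, ...]

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())

    @property
    def n_pixels(self) -> int:
        runs = np.arange(1, self.counts.shape[1] + 1)
        return int(np.sum(self.counts * runs[None, :]))


def quantize(values: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width quantization over the masked min–max range.

    Returns an int array with levels 0..n_levels-1 inside the mask and -1
    outside. A constant region maps to the single level 0.
    """
    lev = np.full(values.shape, -1, dtype=np.int32)
    vals = values[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-12:
        lev[mask] = 0
        return lev
    q = np.floor((values - lo) / (hi - lo) * n_levels).astype(np.int32)
    np.clip(q, 0, n_levels - 1, out=q)
    lev[mask] = q[mask]
    return lev


def _shift(arr: np.ndarray, d: Sequence[int], fill) -> np.ndarray:
    """arr shifted so that out[v] = arr[v + d] (``fill`` where v+d is outside)."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for n, step in zip(arr.shape, d):
        if step >= 0:
            src.append(slice(step, n))
            dst.append(slice(0, n - step))
        else:
            src.append(slice(0, n + step))
            dst.append(slice(-step, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def run_length_matrix(img: np.ndarray, mask: np.ndarray, n_levels: int,
                      direction: Sequence[int]) -> RLMatrix:
    """Count maximal same-level runs along ``direction``, broken at mask edges."""
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    d = tuple(int(v) for v in direction)
    if len(d) != img.ndim or all(v == 0 for v in d):
        raise ValueError(f"direction {d} invalid for a {img.ndim}D image")

    lev = quantize(img, mask, n_levels)
    max_len = int(np.sum(np.abs(d) * np.array(img.shape))) + 1

    prev = _shift(lev, tuple(-v for v in d), -2)       # level at v - d
    starts = (lev >= 0) & (prev != lev)
    nxt = _shift(lev, d, -2)                           # level at v + d
    cont = (lev >= 0) & (nxt == lev)                   # run continues past v

    counts = np.zeros((n_levels, max_len), dtype=np.int64)
    ge = starts.copy()                                  # runs of length >= L start here
    length = 1
    n_ge_prev = None
    while ge.any() and length <= max_len:
        idx = lev[ge]
        n_ge = np.bincount(idx, minlength=n_levels)
        if n_ge_prev is not None:
            counts[:, length - 2] = n_ge_prev - n_ge
        n_ge_prev = n_ge
        # a run of length >= L+1 needs `cont` at the voxel (L-1) steps along
        step = tuple(v * (length - 1) for v in d)
        ge = ge & _shift(cont, step, False)
        length += 1
    if n_ge_prev is not None:
        counts[:, length - 2] = n_ge_prev

    last = np.max(np.nonzero(counts.any(axis=0))[0]) if counts.any() else 0
    return RLMatrix(counts[:, :last + 1].copy(), n_levels, d)


def rls_features(rlm: "RLMatrix | Sequence[RLMatrix]") -> FeatureVector:
    """The 11 classical run-length statistics (SRE … LRHGE).

    Given several matrices (one per direction), the statistics are averaged
    over directions. Gray level and run length indices are 1-based in the
    formulas.
    """
    mats = [rlm] if isinstance(rlm, RLMatrix) else list(rlm)
    if not mats:
        raise ValueError("no run-length matrices given")
    per_dir = []
    for m in mats:
        c = np.asarray(m.counts, dtype=float)
        nr = c.sum()
        if nr <= 0:
            raise ValueError("all-zero run-length matrix")
        i = np.arange(1, c.shape[0] + 1)[:, None].astype(float)
        j = np.arange(1, c.shape[1] + 1)[None, :].astype(float)
        np_pix = float(np.sum(c * j))
        per_dir.append([
            np.sum(c / j ** 2) / nr,           # SRE
            np.sum(c * j ** 2) / nr,           # LRE
            np.sum(c.sum(axis=1) ** 2) / nr,   # GLN
            np.sum(c.sum(axis=0) ** 2) / nr,   # RLN
            nr / np_pix,                       # RP
            np.sum(c / i ** 2) / nr,           # LGRE
            np.sum(c * i ** 2) / nr,           # HGRE
            np.sum(c / (i ** 2 * j ** 2)) / nr,  # SRLGE
            np.sum(c * i ** 2 / j ** 2) / nr,  # SRHGE
            np.sum(c * j ** 2 / i ** 2) / nr,  # LRLGE
            np.sum(c * i ** 2 * j ** 2) / nr,  # LRHGE
        ])
    vals = np.mean(np.asarray(per_dir, dtype=float), axis=0)
    return FeatureVector(RLS_NAMES, vals, bank_id="RLS")


def _rls_block(img: np.ndarray, mask: np.ndarray, n_levels: int,
               directions: Sequence[Sequence[int]], prefix: str) -> List[Tuple[str, float]]:
    mats = [run_length_matrix(img, mask, n_levels, d) for d in directions]
    fv = rls_features(mats)
    return [(f"{prefix}_{name}", val) for name, val in zip(fv.names, fv.values)]


# ------------------------------------------------------------------ morphology

def _central_slice(mask: np.ndarray) -> int:
    areas = mask.reshape(mask.shape[0], -1).sum(axis=1)
    return int(np.argmax(areas))


def _boundary_fourier(mask2d: np.ndarray, n_harmonics: int = 10,
                      n_samples: int = 64) -> np.ndarray:
    """Normalized Fourier-descriptor magnitudes of the largest boundary contour.

    Translation is removed with the DC term, scale with the first harmonic;
    returns |F_k / F_1| for k = 2 .. n_harmonics+1 (all ≈ 0 for a circle).
    """
    contours = measure.find_contours(mask2d.astype(float), 0.5)
    if not contours:
        return np.zeros(n_harmonics)
    contour = max(contours, key=len)
    if len(contour) < 4:
        return np.zeros(n_harmonics)
    # uniform arc-length resampling
    diffs = np.diff(contour, axis=0)
    seglen = np.sqrt((diffs ** 2).sum(axis=1))
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    if s[-1] < EPS:
        return np.zeros(n_harmonics)
    t = np.linspace(0.0, s[-1], n_samples, endpoint=False)
    ys = np.interp(t, s, contour[:, 0])
    xs = np.interp(t, s, contour[:, 1])
    z = xs + 1j * ys
    F = np.fft.fft(z)
    denom = abs(F[1]) + EPS
    ks = np.arange(2, 2 + n_harmonics)
    return np.abs(F[ks]) / denom


def morphology_features(mask_iso: SegmentationMask,
                        spacing: Sequence[float]) -> FeatureVector:
    """3D size plus central-slice shape descriptors.

    3D: volume, marching-cubes surface area, surface-to-volume ratio.
    Central slice (maximal lesion area): area, perimeter, circularity
    4πA/P², rectangularity A / bounding-box area, and Fourier descriptors.
    """
    mask = mask_iso.data
    if not mask.any():
        raise ValueError("empty mask")
    spacing = tuple(float(s) for s in spacing)
    voxvol = float(np.prod(spacing))
    volume = mask.sum() * voxvol

    padded = np.pad(mask, 1).astype(float)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
        surface = float(measure.mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        surface = 6.0 * mask.sum() * spacing[1] * spacing[2]  # voxel-face fallback

    zc = _central_slice(mask)
    sl = mask[zc]
    px = spacing[1]  # isotropic
    area = float(sl.sum()) * px * px
    perim = float(measure.perimeter_crofton(sl, directions=4)) * px
    circularity = 4.0 * np.pi * area / (perim ** 2 + EPS)
    ys, xs = np.nonzero(sl)
    bbox_area = float((ys.max() - ys.min() + 1) * (xs.max() - xs.min() + 1)) * px * px
    rectangularity = area / (bbox_area + EPS)
    fd = _boundary_fourier(sl, n_harmonics=10)
    fd_energy = float(np.sum(fd ** 2))

    names = ["volume_mm3", "surface_area_mm2", "surface_to_volume",
             "central_area_mm2", "central_perimeter_mm", "circularity",
             "rectangularity"] + [f"fd_h{k}" for k in range(2, 12)] + ["fd_energy"]
    vals = [volume, surface, surface / (volume + EPS), area, perim,
            circularity, rectangularity] + list(fd) + [fd_energy]
    return FeatureVector(tuple(names), np.asarray(vals), bank_id="morph")


# ------------------------------------------------------------------ gray level

def _moments(vals: np.ndarray) -> Tuple[float, float, float, float]:
    """mean, SD, skewness, excess kurtosis with the zero-variance convention."""
    mu = float(vals.mean())
    sd = float(vals.std())
    if sd < 1e-12:
        return mu, 0.0, 0.0, 0.0
    z = (vals - mu) / sd
    return mu, sd, float(np.mean(z ** 3)), float(np.mean(z ** 4) - 3.0)


def _hist_entropy_energy(vals: np.ndarray, bins: int = 64) -> Tuple[float, float]:
    hist, _ = np.histogram(vals, bins=bins)
    p = hist / max(hist.sum(), 1)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz))), float(np.sum(p ** 2))


def gray_contrast_features(vol_iso: CTVolume, mask_iso: SegmentationMask
                           ) -> FeatureVector:
    """Gray-level statistics inside the lesion plus a peripheral contrast.

    Contrast is computed on the central slice as
    ``(mean_in − mean_shell) / (|mean_in + mean_shell| + ε)`` with a
    3-voxel peripheral shell; if the shell is empty (mask fills the box)
    the documented sentinel 0 is returned.
    """
    mask = mask_iso.data
    if not mask.any():
        raise ValueError("empty mask")
    vals = vol_iso.intensities[mask]
    mu, sd, skew, kurt = _moments(vals)
    entropy, energy = _hist_entropy_energy(vals)

    zc = _central_slice(mask)
    sl_mask = mask[zc]
    sl_img = vol_iso.intensities[zc]
    shell = ndimage.binary_dilation(sl_mask, iterations=3) & ~sl_mask
    if shell.any():
        m_in = float(sl_img[sl_mask].mean())
        m_sh = float(sl_img[shell].mean())
        contrast = (m_in - m_sh) / (abs(m_in + m_sh) + EPS)
    else:
        contrast = 0.0  # sentinel: shell empty, contrast undefined

    names = ("gl_mean", "gl_sd", "gl_skewness", "gl_kurtosis", "gl_min",
             "gl_max", "gl_median", "gl_p10", "gl_p90", "gl_entropy",
             "gl_energy", "contrast")
    vals_out = np.array([mu, sd, skew, kurt, float(vals.min()), float(vals.max()),
                         float(np.median(vals)), float(np.percentile(vals, 10)),
                         float(np.percentile(vals, 90)), entropy, energy, contrast])
    return FeatureVector(names, vals_out, bank_id="gray")


# ------------------------------------------------------------------ gradient field

def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask minus its 1-voxel (6-connected) erosion; the mask itself when
    it has no interior."""
    er = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    surf = mask & ~er
    return surf if surf.any() else mask.copy()


def gradient_field_features(vol_iso: CTVolume, mask_iso: SegmentationMask
                            ) -> FeatureVector:
    """Gradient-magnitude statistics over the lesion surface voxels."""
    mask = mask_iso.data
    if not mask.any():
        raise ValueError("empty mask")
    grads = np.gradient(vol_iso.intensities.astype(float), *vol_iso.spacing_mm)
    gmag = np.sqrt(sum(g ** 2 for g in grads))
    surf = surface_voxels(mask)
    vals = gmag[surf]
    mu, sd, skew, kurt = _moments(vals)
    names = ("grad_mean", "grad_sd", "grad_skewness", "grad_kurtosis",
             "grad_max", "grad_range")
    out = np.array([mu, sd, skew, kurt, float(vals.max()),
                    float(vals.max() - vals.min())])
    return FeatureVector(names, out, bank_id="gradfield")


# ------------------------------------------------------------------ SL bank

SL_RLS_LEVELS_3D = (8, 16, 32)
SL_RLS_LEVELS_2D = (8, 16)


def sl_bank_names() -> Tuple[str, ...]:
    """The versioned, ordered manifest of the 91-feature SL bank."""
    names: List[str] = []
    names += ["volume_mm3", "surface_area_mm2", "surface_to_volume",
              "central_area_mm2", "central_perimeter_mm", "circularity",
              "rectangularity"] + [f"fd_h{k}" for k in range(2, 12)] + ["fd_energy"]
    names += ["gl_mean", "gl_sd", "gl_skewness", "gl_kurtosis", "gl_min",
              "gl_max", "gl_median", "gl_p10", "gl_p90", "gl_entropy",
              "gl_energy", "contrast"]
    for nl in SL_RLS_LEVELS_3D:
        names += [f"rls3d_q{nl}_{n}" for n in RLS_NAMES]
    for nl in SL_RLS_LEVELS_2D:
        names += [f"rls2d_q{nl}_{n}" for n in RLS_NAMES]
    names += ["grad_mean", "grad_sd", "grad_skewness", "grad_kurtosis",
              "grad_max", "grad_range"]
    return tuple(names)


SL_BANK_SIZE = len(sl_bank_names())  # 91


def extract_sl_features(vol: CTVolume, mask: SegmentationMask) -> FeatureVector:
    """The full SL bank on one segmented lesion (after isotropic resampling)."""
    if mask.is_empty:
        raise ValueError("empty mask")
    vol_i, mask_i = resample_isotropic(vol, mask)
    if mask_i.is_empty:
        raise ValueError("mask vanished during resampling")
    feats: List[Tuple[str, float]] = []
    mf = morphology_features(mask_i, vol_i.spacing_mm)
    feats += list(zip(mf.names, mf.values))
    gf = gray_contrast_features(vol_i, mask_i)
    feats += list(zip(gf.names, gf.values))
    for nl in SL_RLS_LEVELS_3D:
        feats += _rls_block(vol_i.intensities, mask_i.data, nl,
                            DIRECTIONS_3D, f"rls3d_q{nl}")
    zc = _central_slice(mask_i.data)
    for nl in SL_RLS_LEVELS_2D:
        feats += _rls_block(vol_i.intensities[zc], mask_i.data[zc], nl,
                            DIRECTIONS_2D, f"rls2d_q{nl}")
    grf = gradient_field_features(vol_i, mask_i)
    feats += list(zip(grf.names, grf.values))

    names = tuple(n for n, _ in feats)
    assert names == sl_bank_names(), "SL bank manifest drifted"
    return FeatureVector(names, np.array([v for _, v in feats]), bank_id="SL")


def sl_zero_vector() -> FeatureVector:
    """The 'no lesion' SL vector (all features 0).

    Used for complete responders whose post-treatment segmentation is
    empty, so percent change becomes −100% for every positive pre feature.
    """
    names = sl_bank_names()
    return FeatureVector(names, np.zeros(len(names)), bank_id="SL")


def percent_change(pre_fv: FeatureVector, post_fv: FeatureVector) -> FeatureVector:
    """Per-feature 100·(post − pre)/|pre|, with a ±1000 sentinel when the
    pre-treatment value is (numerically) zero."""
    if not pre_fv.same_bank(post_fv):
        raise ValueError("bank mismatch between pre and post vectors")
    pre, post = pre_fv.values, post_fv.values
    out = np.zeros_like(pre)
    ok = np.abs(pre) >= EPS
    out[ok] = 100.0 * (post[ok] - pre[ok]) / np.abs(pre[ok])
    deg = ~ok
    out[deg] = np.sign(post[deg] - pre[deg]) * PCT_SENTINEL
    return FeatureVector(pre_fv.names, out, bank_id=f"{pre_fv.bank_id}_pct_change")


# ------------------------------------------------------------------ ROI bank

def roi_bank_names() -> Tuple[str, ...]:
    names = ["mean", "sd", "skewness", "kurtosis", "energy", "entropy",
             "min", "max", "range", "median", "p5", "p10", "p25", "p75",
             "p90", "p95"]
    for nl in (8, 16):
        names += [f"rls_q{nl}_{n}" for n in RLS_NAMES]
    return tuple(names)


ROI_BANK_SIZE = len(roi_bank_names())  # 38


def extract_roi_features(patch: np.ndarray) -> FeatureVector:
    """The 38-feature ROI bank on one 32×32 paired ROI."""
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (32, 32):
        raise ValueError(f"paired ROI must be 32x32, got {patch.shape}")
    vals = patch.ravel()
    mu, sd, skew, kurt = _moments(vals)
    entropy, energy = _hist_entropy_energy(vals)
    feats: List[Tuple[str, float]] = [
        ("mean", mu), ("sd", sd), ("skewness", skew), ("kurtosis", kurt),
        ("energy", energy), ("entropy", entropy),
        ("min", float(vals.min())), ("max", float(vals.max())),
        ("range", float(vals.max() - vals.min())),
        ("median", float(np.median(vals))),
        ("p5", float(np.percentile(vals, 5))), ("p10", float(np.percentile(vals, 10))),
        ("p25", float(np.percentile(vals, 25))), ("p75", float(np.percentile(vals, 75))),
        ("p90", float(np.percentile(vals, 90))), ("p95", float(np.percentile(vals, 95))),
    ]
    full = np.ones_like(patch, dtype=bool)
    for nl in (8, 16):
        feats += _rls_block(patch, full, nl, DIRECTIONS_2D, f"rls_q{nl}")
    names = tuple(n for n, _ in feats)
    assert names == roi_bank_names(), "ROI bank manifest drifted"
    return FeatureVector(names, np.array([v for _, v in feats]), bank_id="ROI")


def aggregate_per_lesion(vectors: Sequence[FeatureVector]) -> FeatureVector:
    """Elementwise mean of same-bank vectors (the 'per-lesion' features)."""
    if not vectors:
        raise ValueError("no vectors to aggregate")
    first = vectors[0]
    for v in vectors[1:]:
        if not first.same_bank(v):
            raise ValueError("cannot aggregate vectors from different banks")
    stacked = np.stack([v.values for v in vectors], axis=0)
    return FeatureVector(first.names, stacked.mean(axis=0), bank_id=first.bank_id)
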