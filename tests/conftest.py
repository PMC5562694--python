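"""Shared fixtures: small synthetic volumes with known geometry."""

from __future__ import annotations

import numpy as np
import pytest

from bladresp.types import CTVolume, RegionBox, SegmentationMask


def make_sphere_volume(radius_vox: float = 10.0, pad: int = 4,
                       inside: float = 100.0, outside: float = 20.0,
                       noise_sd: float = 0.0, texture_sd: float = 0.0,
                       seed: int = 0, spacing=(1.0, 1.0, 1.0)):
    """A solid digital sphere in a tight box, with optional white noise and
    spatially correlated texture (the kind real soft tissue shows).

    Returns (CTVolume, RegionBox over the whole grid, truth SegmentationMask).
    """
    n = int(np.ceil(radius_vox)) * 2 + 1 + 2 * pad
    c = (n - 1) / 2.0
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n].astype(float)
    sphere = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= radius_vox ** 2
    img = np.where(sphere, inside, outside).astype(float)
    rng = np.random.default_rng(seed)
    if texture_sd > 0:
        from scipy.ndimage import gaussian_filter

        tex = gaussian_filter(rng.standard_normal(img.shape), 2.0)
        img += texture_sd * tex / tex.std()
    if noise_sd > 0:
        img += rng.normal(0, noise_sd, img.shape)
    box = RegionBox((0, 0, 0), (n, n, n))
    return CTVolume(img, spacing), box, SegmentationMask(sphere, box)


@pytest.fixture
def sphere_case():
    return make_sphere_volume(radius_vox=9.0, pad=5, noise_sd=3.0,
                              texture_sd=12.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
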