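"""Feature banks: run-length oracles, morphology closed forms, invariances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bladresp import radiomics as R
from bladresp.types import CTVolume, FeatureVector, RegionBox, SegmentationMask

from conftest import make_sphere_volume


# ------------------------------------------------------------------ oracles

def brute_force_rlm(img, mask, n_levels, d):
    """Per-line run scanner, independent of the vectorized implementation."""
    lev = R.quantize(np.asarray(img, float), np.asarray(mask, bool), n_levels)
    shape = lev.shape
    counts = {}
    for start in itertools.product(*[range(s) for s in shape]):
        if lev[start] < 0:
            continue
        prev = tuple(np.array(start) - np.array(d))
        if all(0 <= p < s for p, s in zip(prev, shape)) and lev[prev] == lev[start]:
            continue  # not a run start
        length, cur = 1, start
        while True:
            nxt = tuple(np.array(cur) + np.array(d))
            if not all(0 <= p < s for p, s in zip(nxt, shape)):
                break
            if lev[nxt] != lev[start]:
                break
            length, cur = length + 1, nxt
        counts[(int(lev[start]), length)] = counts.get((int(lev[start]), length), 0) + 1
    return counts


def rls_double_sum(counts):
    """Direct re-evaluation of the 11 statistics from the matrix."""
    c = np.asarray(counts, float)
    nr = c.sum()
    i = np.arange(1, c.shape[0] + 1)[:, None]
    j = np.arange(1, c.shape[1] + 1)[None, :]
    npix = (c * j).sum()
    return dict(
        sre=(c / j ** 2).sum() / nr, lre=(c * j ** 2).sum() / nr,
        gln=(c.sum(1) ** 2).sum() / nr, rln=(c.sum(0) ** 2).sum() / nr,
        rp=nr / npix, lgre=(c / i ** 2).sum() / nr, hgre=(c * i ** 2).sum() / nr,
        srlge=(c / (i * j) ** 2).sum() / nr, srhge=(c * i ** 2 / j ** 2).sum() / nr,
        lrlge=(c * j ** 2 / i ** 2).sum() / nr, lrhge=(c * (i * j) ** 2).sum() / nr)


# ------------------------------------------------------------------ run length

class TestRunLength:
    def test_three_pixel_row(self):
        m = R.run_length_matrix(np.array([[1., 1., 2.]]), np.ones((1, 3), bool),
                                2, (0, 1))
        assert m.counts[0, 1] == 1   # level 1, run length 2
        assert m.counts[1, 0] == 1   # level 2, run length 1
        assert m.counts.sum() == 2

    @pytest.mark.parametrize("ndim", [2, 3])
    def test_matches_brute_force(self, ndim, rng):
        dirs = R.DIRECTIONS_2D if ndim == 2 else R.DIRECTIONS_3D
        shape = (9, 8) if ndim == 2 else (5, 6, 7)
        for trial in range(6):
            img = rng.integers(0, 40, size=shape)
            mask = rng.random(shape) < 0.75
            if not mask.any():
                continue
            nl = int(rng.choice([2, 4, 8]))
            for d in dirs:
                m = R.run_length_matrix(img, mask, nl, d)
                mine = {(g, r + 1): int(v)
                        for (g, r), v in np.ndenumerate(m.counts) if v}
                assert mine == brute_force_rlm(img, mask, nl, d)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.sampled_from([2, 4, 8]),
           st.sampled_from(R.DIRECTIONS_2D))
    def test_pixel_conservation(self, seed, n_levels, direction):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 30, size=(10, 10))
        mask = rng.random((10, 10)) < 0.7
        mask[0, 0] = True
        m = R.run_length_matrix(img, mask, n_levels, direction)
        assert m.n_pixels == int(mask.sum())

    def test_single_run_closed_forms(self):
        m = R.run_length_matrix(np.full((1, 6), 3.0), np.ones((1, 6), bool),
                                2, (0, 1))
        fv = R.rls_features(m)
        assert fv["lre"] == pytest.approx(36.0)
        assert fv["sre"] == pytest.approx(1 / 36.0)

    def test_constant_image_gln_equals_run_count(self, rng):
        img = np.full((7, 7), 5.0)
        m = R.run_length_matrix(img, np.ones((7, 7), bool), 4, (1, 0))
        fv = R.rls_features(m)
        assert fv["gln"] == pytest.approx(m.n_runs)

    def test_statistics_match_double_sum_oracle(self, rng):
        img = rng.integers(0, 64, (12, 12))
        m = R.run_length_matrix(img, np.ones((12, 12), bool), 8, (1, 1))
        fv = R.rls_features(m)
        for name, val in rls_double_sum(m.counts).items():
            assert fv[name] == pytest.approx(val, rel=1e-12)

    def test_invalid_inputs(self):
        img, mask = np.zeros((4, 4)), np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            R.run_length_matrix(img, np.zeros((4, 4), bool), 4, (0, 1))
        with pytest.raises(ValueError):
            R.run_length_matrix(img, mask, 1, (0, 1))
        with pytest.raises(ValueError):
            R.run_length_matrix(img, mask, 4, (0, 0))


# ------------------------------------------------------------------ resampling

class TestResample:
    def test_isotropic_input_unchanged(self, rng):
        vol = CTVolume(rng.normal(40, 5, (12, 12, 12)), (1.0, 1.0, 1.0))
        box = RegionBox((0, 0, 0), (12, 12, 12))
        mask = SegmentationMask(rng.random((12, 12, 12)) > 0.4, box)
        vi, mi = R.resample_isotropic(vol, mask)
        np.testing.assert_allclose(vi.intensities, vol.intensities, atol=1e-6)
        np.testing.assert_array_equal(mi.data, mask.data)

    def test_output_spacing_isotropic_and_volume_preserved(self, rng):
        vol = CTVolume(rng.normal(40, 5, (10, 40, 40)), (3.0, 0.75, 0.75))
        zz, yy, xx = np.mgrid[-5:5, -20:20, -20:20]
        m = (zz * 3.0) ** 2 + (yy * 0.75) ** 2 + (xx * 0.75) ** 2 <= 8 ** 2
        mask = SegmentationMask(m, RegionBox((0, 0, 0), (10, 40, 40)))
        vi, mi = R.resample_isotropic(vol, mask)
        assert len(set(vi.spacing_mm)) == 1
        v0 = mask.n_voxels * np.prod(vol.spacing_mm)
        v1 = mi.n_voxels * np.prod(vi.spacing_mm)
        assert abs(v1 - v0) / v0 < 0.05


# ------------------------------------------------------------------ morphology

class TestMorphology:
    def _slab(self, mask2d, spacing=(1.0, 1.0, 1.0)):
        m = np.zeros((3, *mask2d.shape), bool)
        m[1] = mask2d
        return SegmentationMask(m, RegionBox((0, 0, 0), m.shape)), spacing

    def test_disk_circularity_and_descriptors(self):
        yy, xx = np.mgrid[-31:32, -31:32]
        mask, sp = self._slab((yy ** 2 + xx ** 2) <= 20 ** 2)
        fv = R.morphology_features(mask, sp)
        assert fv["circularity"] >= 0.95
        assert fv["fd_energy"] < 0.02   # a circle has no higher harmonics

    def test_rectangle_rectangularity(self):
        m = np.zeros((40, 40), bool)
        m[5:25, 8:30] = True
        mask, sp = self._slab(m)
        fv = R.morphology_features(mask, sp)
        assert fv["rectangularity"] == pytest.approx(1.0, abs=1e-6)

    def test_sphere_volume_close_form(self):
        _, _, truth = make_sphere_volume(radius_vox=10.0, pad=3)
        fv = R.morphology_features(truth, (1.0, 1.0, 1.0))
        analytic = 4 / 3 * np.pi * 1000
        assert abs(fv["volume_mm3"] - analytic) / analytic < 0.05
        assert abs(fv["surface_area_mm2"] - 4 * np.pi * 100) / (4 * np.pi * 100) < 0.15

    def test_empty_mask_rejected(self):
        empty = SegmentationMask(np.zeros((3, 5, 5), bool),
                                 RegionBox((0, 0, 0), (3, 5, 5)))
        with pytest.raises(ValueError):
            R.morphology_features(empty, (1, 1, 1))


# ------------------------------------------------------------------ gray level

class TestGrayContrast:
    def test_uniform_volume_zero_contrast(self):
        vol = CTVolume(np.full((5, 20, 20), 70.0), (1, 1, 1))
        m = np.zeros((5, 20, 20), bool)
        m[2, 8:12, 8:12] = True
        fv = R.gray_contrast_features(vol, SegmentationMask(m, RegionBox((0, 0, 0), m.shape)))
        assert fv["contrast"] == pytest.approx(0.0, abs=1e-9)
        assert fv["gl_sd"] == 0.0 and fv["gl_skewness"] == 0.0

    def test_full_contrast_closed_form(self):
        img = np.zeros((3, 20, 20))
        m = np.zeros((3, 20, 20), bool)
        m[1, 8:12, 8:12] = True
        img[m] = 100.0
        fv = R.gray_contrast_features(CTVolume(img, (1, 1, 1)),
                                      SegmentationMask(m, RegionBox((0, 0, 0), m.shape)))
        assert fv["contrast"] == pytest.approx(1.0, abs=1e-6)

    def test_mean_matches_direct_average(self, rng):
        img = rng.normal(60, 12, (4, 16, 16))
        m = rng.random((4, 16, 16)) > 0.5
        fv = R.gray_contrast_features(CTVolume(img, (1, 1, 1)),
                                      SegmentationMask(m, RegionBox((0, 0, 0), m.shape)))
        assert fv["gl_mean"] == pytest.approx(img[m].mean(), rel=1e-12)


# ------------------------------------------------------------------ gradient field

class TestGradientField:
    def test_uniform_volume_all_zero(self):
        vol = CTVolume(np.full((6, 10, 10), 30.0), (1, 1, 1))
        m = np.zeros((6, 10, 10), bool)
        m[2:4, 3:7, 3:7] = True
        fv = R.gradient_field_features(vol, SegmentationMask(m, RegionBox((0, 0, 0), m.shape)))
        assert np.all(fv.values == 0.0)

    def test_surface_voxel_count_matches_6conn_oracle(self, rng):
        from scipy import ndimage

        m = rng.random((8, 12, 12)) > 0.6
        m = ndimage.binary_closing(m)
        if not m.any():
            pytest.skip("degenerate draw")
        surf = R.surface_voxels(m)
        # oracle: voxels of m with at least one 6-neighbour outside m
        oracle = np.zeros_like(m)
        for idx in np.argwhere(m):
            for ax in range(3):
                for d in (-1, 1):
                    nb = idx.copy()
                    nb[ax] += d
                    if (nb < 0).any() or (nb >= np.array(m.shape)).any() \
                            or not m[tuple(nb)]:
                        oracle[tuple(idx)] = True
        if not oracle.any():
            oracle = m.copy()
        np.testing.assert_array_equal(surf, oracle)

    def test_step_sphere_mean_surface_gradient(self):
        vol, _, truth = make_sphere_volume(radius_vox=12.0, pad=4,
                                           inside=100.0, outside=0.0)
        fv = R.gradient_field_features(vol, truth)
        # central differences across a sharp step of height S contribute S/2
        # per axis crossing the boundary; surface voxels cross 1-3 axes, so
        # the mean magnitude lies between S/2 and sqrt(3)*S/2
        assert 0.9 * 50.0 <= fv["grad_mean"] <= 1.05 * np.sqrt(3) * 50.0

    def test_single_voxel_mask_surface_is_mask(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        assert R.surface_voxels(m).sum() == 1


# ------------------------------------------------------------------ banks

class TestBanks:
    def test_sl_bank_size_and_determinism(self, sphere_case):
        vol, box, truth = sphere_case
        fv1 = R.extract_sl_features(vol, truth)
        fv2 = R.extract_sl_features(vol, truth)
        assert len(fv1) == R.SL_BANK_SIZE == 91
        np.testing.assert_allclose(fv1.values, fv2.values, atol=1e-9)

    def test_sl_subfeatures_match_standalone_ops(self, sphere_case):
        vol, box, truth = sphere_case
        fv = R.extract_sl_features(vol, truth)
        vi, mi = R.resample_isotropic(vol, truth)
        mf = R.morphology_features(mi, vi.spacing_mm)
        assert fv["volume_mm3"] == pytest.approx(mf["volume_mm3"], rel=1e-12)
        gf = R.gray_contrast_features(vi, mi)
        assert fv["gl_mean"] == pytest.approx(gf["gl_mean"], rel=1e-12)

    def test_sl_translation_invariance(self, rng):
        img = rng.normal(50, 8, (30, 30, 30))
        m = np.zeros((30, 30, 30), bool)
        zz, yy, xx = np.mgrid[-15:15, -15:15, -15:15]
        blob = (zz ** 2 + yy ** 2 + xx ** 2) <= 36
        m |= blob
        vol = CTVolume(img, (1, 1, 1))
        box1 = RegionBox.from_mask(m, (3, 3, 3))
        fv1 = R.extract_sl_features(vol, SegmentationMask.from_full_grid(m, box1))
        # translate volume + mask by (2, 3, 1)
        img2 = np.roll(img, (2, 3, 1), axis=(0, 1, 2))
        m2 = np.roll(m, (2, 3, 1), axis=(0, 1, 2))
        box2 = RegionBox.from_mask(m2, (3, 3, 3))
        fv2 = R.extract_sl_features(CTVolume(img2, (1, 1, 1)),
                                    SegmentationMask.from_full_grid(m2, box2))
        np.testing.assert_allclose(fv1.values, fv2.values, rtol=1e-7, atol=1e-9)

    def test_morphology_invariant_gray_equivariant_under_shift(self, sphere_case):
        vol, box, truth = sphere_case
        shifted = CTVolume(vol.intensities + 25.0, vol.spacing_mm)
        fv1 = R.extract_sl_features(vol, truth)
        fv2 = R.extract_sl_features(shifted, truth)
        assert fv2["volume_mm3"] == pytest.approx(fv1["volume_mm3"])
        assert fv2["circularity"] == pytest.approx(fv1["circularity"])
        assert fv2["gl_mean"] == pytest.approx(fv1["gl_mean"] + 25.0, rel=1e-9)

    def test_roi_bank_size_and_constant_patch_conventions(self):
        fv = R.extract_roi_features(np.full((32, 32), 44.0))
        assert len(fv) == R.ROI_BANK_SIZE == 38
        assert fv["sd"] == 0.0 and fv["skewness"] == 0.0

    def test_roi_skewness_matches_moment_oracle(self, rng):
        patch = rng.gamma(2.0, 10.0, (32, 32))
        fv = R.extract_roi_features(patch)
        v = patch.ravel()
        z = (v - v.mean()) / v.std()
        assert fv["skewness"] == pytest.approx((z ** 3).mean(), rel=1e-10)

    def test_roi_requires_32x32(self):
        with pytest.raises(ValueError):
            R.extract_roi_features(np.zeros((32, 16)))


# ------------------------------------------------------------------ percent change & aggregation

class TestPercentChangeAggregate:
    def _fv(self, vals, bank="SL"):
        return FeatureVector(tuple(f"f{i}" for i in range(len(vals))),
                             np.asarray(vals, float), bank)

    def test_identical_timepoints_zero(self):
        fv = self._fv([3.0, -2.0, 7.5])
        out = R.percent_change(fv, fv)
        np.testing.assert_array_equal(out.values, 0.0)
        assert out.bank_id == "SL_pct_change"

    def test_halving_is_minus_fifty(self):
        out = R.percent_change(self._fv([10.0]), self._fv([5.0]))
        assert out.values[0] == pytest.approx(-50.0)

    def test_zero_pre_gives_capped_sentinel(self):
        out = R.percent_change(self._fv([0.0, 0.0]), self._fv([1.0, -1.0]))
        np.testing.assert_array_equal(out.values, [1000.0, -1000.0])

    def test_bank_mismatch_rejected(self):
        with pytest.raises(ValueError):
            R.percent_change(self._fv([1.0]), self._fv([1.0], bank="ROI"))

    def test_aggregate_mean_and_oracle(self, rng):
        vecs = [self._fv(v, "ROI") for v in [(0.0, 2.0), (2.0, 0.0)]]
        out = R.aggregate_per_lesion(vecs)
        np.testing.assert_array_equal(out.values, [1.0, 1.0])
        vecs = [self._fv(rng.normal(size=4), "ROI") for _ in range(5)]
        acc = np.zeros(4)
        for v in vecs:
            acc += v.values
        np.testing.assert_allclose(R.aggregate_per_lesion(vecs).values, acc / 5,
                                   rtol=1e-12)
        assert R.aggregate_per_lesion([vecs[0]]).values == pytest.approx(vecs[0].values)

    def test_aggregate_empty_rejected(self):
        with pytest.raises(ValueError):
            R.aggregate_per_lesion([])
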