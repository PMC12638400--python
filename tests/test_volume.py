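import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motioniq import (BrainMask, MaskMode, NormMode, PreprocConfig, Volume,
                      apply_mask_mode, masked_histogram, normalize_volume,
                      reduce_slicewise, select_slices)
from motioniq.volume import DegenerateVolumeError


def _vol(data, **kw):
    return Volume(data=np.asarray(data, dtype=float), **kw)


class TestNormalize:
    def test_minmax_maps_extremes(self):
        data = np.linspace(2, 6, 1000).reshape(10, 10, 10)
        out = normalize_volume(_vol(data), "minmax")
        assert out.data.min() == 0.0 and out.data.max() == 1.0
        np.testing.assert_allclose(out.data.ravel()[499], (data.ravel()[499] - 2) / 4)

    def test_none_is_identity(self, toy_volume):
        out = normalize_volume(toy_volume, "none")
        assert out is toy_volume

    def test_meanstd_standardises(self, toy_volume):
        out = normalize_volume(toy_volume, "meanstd")
        assert abs(out.data.mean()) < 1e-12
        assert abs(out.data.std() - 1.0) < 1e-12

    def test_percentile_is_robust_to_single_outlier(self):
        # 1000 voxels, all 1 except one voxel at 1000: the robust mapping
        # sends the bulk near 0 and clips the outlier to 1, while min-max
        # sends the bulk exactly to 0 -- the outlier-sensitivity diagnostic
        data = np.ones(1000)
        data[500] = 1000.0
        v = _vol(data.reshape(10, 10, 10))
        pct = normalize_volume(v, "percentile", (1.0, 99.9))
        bulk = np.delete(pct.data.ravel(), 500)
        assert np.all(bulk <= 0.01)
        assert pct.data.ravel()[500] == 1.0
        mm = normalize_volume(v, "minmax")
        assert np.all(np.delete(mm.data.ravel(), 500) == 0.0)

    @pytest.mark.parametrize("mode", ["minmax", "meanstd", "percentile"])
    def test_constant_volume_rejected(self, mode):
        with pytest.raises(DegenerateVolumeError):
            normalize_volume(_vol(np.full((8, 8, 8), 3.0)), mode)

    @pytest.mark.parametrize("mode,atol", [("minmax", 1e-12),
                                           ("percentile", 2e-3)])
    def test_idempotence(self, toy_volume, mode, atol):
        # percentile idempotence is approximate: clipping moves the 1st
        # percentile by about one inter-voxel spacing near the boundary
        once = normalize_volume(toy_volume, mode)
        twice = normalize_volume(once, mode)
        np.testing.assert_allclose(twice.data, once.data, atol=atol)


class TestMaskMode:
    def test_none_identity(self, toy_volume):
        out, domain = apply_mask_mode(toy_volume, None, "none")
        assert out is toy_volume and domain is None

    def test_all_ones_multiply_identity(self, toy_volume):
        mask = BrainMask(data=np.ones(toy_volume.data.shape, dtype=np.uint8))
        out, domain = apply_mask_mode(toy_volume, mask, "multiply")
        np.testing.assert_array_equal(out.data, toy_volume.data)
        assert domain is None

    def test_multiply_preserves_in_mask_bits(self, toy_volume, toy_mask):
        out, _ = apply_mask_mode(toy_volume, toy_mask, "multiply")
        assert np.array_equal(out.data[toy_mask.data], toy_volume.data[toy_mask.data])
        assert np.all(out.data[~toy_mask.data] == 0)

    def test_mask_mode_domain_size(self, toy_volume):
        m = np.zeros(toy_volume.data.shape, dtype=np.uint8)
        m[0:2, 0:2, 5] = 1  # 4-voxel domain in one slice
        out, domain = apply_mask_mode(toy_volume, BrainMask(data=m), "mask")
        np.testing.assert_array_equal(out.data, toy_volume.data)
        assert domain.sum() == 4

    def test_shape_mismatch(self, toy_volume):
        bad = BrainMask(data=np.ones((8, 8, 8), dtype=np.uint8))
        with pytest.raises(ValueError):
            apply_mask_mode(toy_volume, bad, "multiply")


class TestSelectSlices:
    def _mask_with_fractions(self, fracs, area=100):
        planes = []
        for f in fracs:
            plane = np.zeros(area, dtype=np.uint8)
            plane[: int(round(f * area))] = 1
            planes.append(plane.reshape(10, 10))
        return BrainMask(data=np.stack(planes, axis=2))

    def test_threshold_keeps_ge(self):
        m = self._mask_with_fractions([0.05, 0.20, 0.50])
        assert select_slices(m, 0.1, axis=2) == [1, 2]

    def test_zero_threshold_keeps_any_brain(self):
        m = self._mask_with_fractions([0.0, 0.01, 0.30])
        assert select_slices(m, 0.0, axis=2) == [1, 2]

    def test_no_qualifying_slices(self):
        m = self._mask_with_fractions([0.01, 0.02, 0.03])
        assert select_slices(m, 0.5, axis=2) == []

    @given(thr1=st.floats(0, 1), thr2=st.floats(0, 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_threshold(self, thr1, thr2):
        m = self._mask_with_fractions([0.05, 0.1, 0.2, 0.4, 0.8])
        lo, hi = sorted([thr1, thr2])
        assert set(select_slices(m, hi, axis=2)) <= set(select_slices(m, lo, axis=2))


class TestReduce:
    @pytest.mark.parametrize("reduction,direction,expected", [
        ("worst", "higher_better", 0.2),
        ("worst", "lower_better", 0.8),
        ("mean", "higher_better", 0.5),
        ("mean", "lower_better", 0.5),
    ])
    def test_examples(self, reduction, direction, expected):
        assert reduce_slicewise([0.2, 0.8, 0.5], reduction, direction) == expected

    def test_nan_excluded(self):
        assert reduce_slicewise([0.2, float("nan"), 0.8], "mean") == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reduce_slicewise([], "mean")
        with pytest.raises(ValueError):
            reduce_slicewise([float("nan")], "worst", "higher_better")

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_worst_brackets_mean(self, values):
        lo = reduce_slicewise(values, "worst", "higher_better")
        hi = reduce_slicewise(values, "worst", "lower_better")
        mid = reduce_slicewise(values, "mean")
        assert lo <= mid + 1e-12 and mid <= hi + 1e-12


class TestMaskedHistogram:
    def test_counts_conserve(self, toy_volume, toy_mask):
        _, counts = masked_histogram(toy_volume, toy_mask, n_bins=17)
        assert counts.sum() == toy_mask.data.sum()

    def test_constant_in_mask_single_bin(self, toy_mask):
        data = np.ones((12, 12, 12))
        data[~toy_mask.data] = np.linspace(0, 5, (~toy_mask.data).sum())
        _, counts = masked_histogram(_vol(data), toy_mask, n_bins=10)
        assert (counts > 0).sum() == 1

    def test_percentile_aligns_histograms_better_than_minmax(self):
        # a degraded copy with one huge outlier voxel: after percentile
        # normalization the in-mask histograms of image and reference
        # overlap far more than after min-max
        rng = np.random.default_rng(3)
        ref = rng.random((12, 12, 12)) + 0.5
        img = ref + rng.normal(0, 0.01, ref.shape)
        img[0, 0, 0] = 500.0
        mask = BrainMask(data=(rng.random(ref.shape) < 0.5).astype(np.uint8))
        edges = np.linspace(0, 1, 51)

        def overlap(norm):
            a = normalize_volume(_vol(img), norm)
            b = normalize_volume(_vol(ref), norm)
            ca, _ = np.histogram(a.data[mask.data], bins=edges)
            cb, _ = np.histogram(b.data[mask.data], bins=edges)
            return np.minimum(ca, cb).sum()

        assert overlap("percentile") > overlap("minmax")


class TestPreprocConfig:
    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            PreprocConfig(percentile_bounds=(99.0, 1.0))

    def test_label(self):
        c = PreprocConfig(MaskMode.NONE, NormMode.MINMAX, "mean")
        assert c.label == "none-minmax-mean"


class TestVolumeInvariants:
    def test_rejects_nonfinite(self):
        data = np.ones((8, 8, 8))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            Volume(data=data)

    def test_rejects_small_dims(self):
        with pytest.raises(ValueError):
            Volume(data=np.ones((4, 8, 8)))

    def test_mask_rejects_nonbinary_and_empty(self):
        with pytest.raises(ValueError):
            BrainMask(data=np.full((8, 8, 8), 2))
        with pytest.raises(ValueError):
            BrainMask(data=np.zeros((8, 8, 8)))
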