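import numpy as np
import pytest
from scipy import ndimage

from motioniq import (MotionTrajectory, StudyConfig, build_study,
                      corrupt_with_motion, inject_outliers, krippendorff_alpha,
                      make_phantom, make_trajectory, simulate_raters, ssim)
from motioniq.volume import SlicePair, normalize_volume


class TestPhantom:
    def test_same_seed_bit_identical(self):
        a, ma = make_phantom(shape=(32, 32, 32), seed=9, noise_sd=0.01)
        b, mb = make_phantom(shape=(32, 32, 32), seed=9, noise_sd=0.01)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(ma.data, mb.data)

    def test_brain_occupies_minor_fraction(self):
        _, m = make_phantom(shape=(48, 48, 48), seed=1)
        assert m.data.mean() < 0.4

    def test_contrast_presets_share_geometry(self):
        t1, m1 = make_phantom(shape=(32, 32, 32), seed=3, contrast="MPRAGE",
                              noise_sd=0.0)
        t2, m2 = make_phantom(shape=(32, 32, 32), seed=3, contrast="FLAIR",
                              noise_sd=0.0)
        assert np.array_equal(m1.data, m2.data)
        # white matter sits at the volume centre: bright on T1, darker on FLAIR
        c = tuple(s // 2 for s in t1.data.shape)
        assert t1.data[c] > 0.8 and t2.data[c] < 0.7

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValueError):
            make_phantom(shape=(16, 32, 32))


class TestTrajectory:
    def test_zero_severity_zero_trajectory(self):
        t = make_trajectory(0.0, 32, n_segments=4)
        assert t.severity() == 0.0
        assert not t.translations_mm.any() and not t.rotations_deg.any()

    def test_requested_severity_attained(self):
        t = make_trajectory(2.5, 64, n_segments=8, seed=4)
        assert t.severity() == pytest.approx(2.5, rel=1e-9)

    def test_severity_scales_with_parameters(self):
        t = make_trajectory(1.0, 64, seed=2)
        doubled = MotionTrajectory(2 * t.translations_mm, 2 * t.rotations_deg,
                                   t.segments)
        assert doubled.severity() == pytest.approx(2 * t.severity(), rel=1e-12)

    def test_coverage_validation(self):
        zeros = np.zeros((2, 3))
        with pytest.raises(ValueError):
            MotionTrajectory(zeros, zeros, ((0, 10), (12, 32))).validate_coverage(32)
        with pytest.raises(ValueError):
            MotionTrajectory(zeros, zeros, ((0, 20), (18, 32))).validate_coverage(32)


class TestMotionCorruption:
    def test_zero_trajectory_identity(self, phantom_32):
        v, _ = phantom_32
        t = make_trajectory(0.0, 32, n_segments=4)
        out = corrupt_with_motion(v, t)
        np.testing.assert_allclose(out.data, v.data,
                                   rtol=1e-6, atol=1e-6 * v.data.max())

    def test_single_segment_translation_shifts_image(self, phantom_32):
        """One segment covering all lines: Fourier compositing reduces to
        the rigid transform itself (shift theorem sanity check)."""
        v, _ = phantom_32
        t = MotionTrajectory(np.array([[0.0, 6.0, 0.0]]),
                             np.zeros((1, 3)), ((0, 32),))
        out = corrupt_with_motion(v, t)
        expected = ndimage.shift(v.data, (0, 2.0, 0), order=1)  # 6 mm / 3 mm
        np.testing.assert_allclose(out.data, np.abs(expected), atol=1e-6)

    def test_translation_only_energy_conserved(self):
        # whole-voxel translations isolate the k-space compositing from
        # trilinear-interpolation attenuation (which low-passes sub-voxel
        # shifts and is exercised elsewhere)
        v, _ = make_phantom(shape=(32, 32, 32), seed=7, noise_sd=0.0)
        rng = np.random.default_rng(8)
        trans = 3.0 * rng.integers(-1, 2, (4, 3)).astype(float)
        t = MotionTrajectory(trans, np.zeros((4, 3)),
                             ((0, 8), (8, 16), (16, 24), (24, 32)))
        out = corrupt_with_motion(v, t)
        e0 = float((v.data ** 2).sum())
        e1 = float((out.data ** 2).sum())
        assert abs(e1 - e0) / e0 < 0.01

    def test_ssim_decreases_along_severity_ladder(self, phantom_32):
        v, m = phantom_32
        ref = normalize_volume(v, "percentile")
        vals = []
        for i, s in enumerate((0.5, 1.5, 4.0)):
            c = corrupt_with_motion(v, make_trajectory(s, 32, seed=30 + i))
            cn = normalize_volume(c, "percentile")
            vals.append(ssim(SlicePair(cn.get_slice(16), ref.get_slice(16))))
        assert vals[0] > vals[1] > vals[2]


class TestRaters:
    def test_no_noise_no_severity_gives_perfect_scores(self):
        t = simulate_raters([0.0, 0.0], ["a", "b"], noise_sd=0.0, bias_sd=0.0,
                            seed=1)
        assert (t.scores.to_numpy() == 5).all()

    def test_noise_free_scores_weakly_decrease_with_severity(self):
        sev = [0.0, 1.0, 2.0, 3.0, 4.0]
        t = simulate_raters(sev, [f"v{i}" for i in range(5)],
                            noise_sd=0.0, bias_sd=0.0, seed=2)
        for col in t.scores:
            assert (np.diff(t.scores[col].to_numpy()) <= 0).all()

    def test_alpha_in_plausible_band_at_stated_noise(self):
        rng = np.random.default_rng(77)
        sev = rng.uniform(0, 4, 88)
        t = simulate_raters(sev, [f"v{i}" for i in range(88)],
                            noise_sd=0.5, seed=3)
        alpha = krippendorff_alpha(t.scores.to_numpy(), "ordinal")
        assert 0.5 < alpha < 1.0

    def test_low_severity_scores_high(self):
        t = simulate_raters([0.0] * 10 + [4.0], [f"v{i}" for i in range(11)],
                            noise_sd=0.3, seed=4)
        from motioniq import weighted_mean_score
        means = weighted_mean_score(t)
        assert means.iloc[:10].mean() >= 4.5


class TestStudy:
    def test_structure_matches_config(self, small_study):
        assert len(small_study.subjects) == 3
        for sub in small_study.subjects:
            assert len(sub.degraded) == 3
            assert all(s > 0 for s in sub.severities)
            assert sub.mask.data.shape == sub.reference.data.shape
        tab = small_study.table()
        assert tab.is_reference.sum() == 3
        assert set(tab.volume_id) == set(small_study.ratings.scores.index)

    def test_default_config_is_twenty_two_by_four(self):
        cfg = StudyConfig()
        assert cfg.n_subjects == 22
        assert len(cfg.severities) == 3  # + 1 reference = 4 conditions
        assert cfg.shape == (64, 64, 64)

    def test_same_seed_reproducible(self):
        cfg = StudyConfig(n_subjects=2, shape=(32, 32, 32))
        a = build_study(cfg, seed=5)
        b = build_study(cfg, seed=5)
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.reference.data, sb.reference.data)
            for va, vb in zip(sa.degraded, sb.degraded):
                assert np.array_equal(va.data, vb.data)
        assert a.ratings.scores.equals(b.ratings.scores)

    def test_scores_are_likert(self, small_study):
        vals = small_study.ratings.scores.to_numpy()
        assert np.isin(vals[np.isfinite(vals)], [1, 2, 3, 4, 5]).all()


class TestOutliers:
    def test_fraction_of_voxels_replaced(self, phantom_32):
        v, _ = phantom_32
        out = inject_outliers(v, fraction=0.001, seed=3)
        changed = (out.data != v.data).sum()
        assert changed == max(1, round(0.001 * v.data.size))
        assert out.data.max() > 5 * v.data.max()
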