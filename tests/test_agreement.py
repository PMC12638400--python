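import numpy as np
import pandas as pd
import pytest
from scipy import stats

from motioniq import (AgreementReport, RatingTable, krippendorff_alpha,
                      median_rank, significance_filter, spearman,
                      weighted_mean_score)
from oracles import krippendorff_oracle, spearman_rho_oracle


def _table(rows, roles):
    df = pd.DataFrame(rows, columns=list(roles))
    df.index = [f"vol{i}" for i in range(len(df))]
    return RatingTable(scores=df, roles=roles)


class TestWeightedMean:
    def test_double_weight_on_radiologists(self):
        t = _table([[4, 4, 3, 5]],
                   {"a": "radiologist", "b": "radiologist",
                    "c": "radiographer", "d": "radiographer"})
        assert weighted_mean_score(t).iloc[0] == pytest.approx(4.0)

    def test_single_rater_identity(self):
        t = _table([[3]], {"a": "radiologist"})
        assert weighted_mean_score(t).iloc[0] == 3.0

    def test_constant_scores(self):
        t = _table([[2, 2, 2, 2]],
                   {"a": "radiologist", "b": "radiologist",
                    "c": "radiographer", "d": "radiographer"})
        assert weighted_mean_score(t).iloc[0] == 2.0

    def test_missing_raters_dropped_from_both_sums(self):
        t = _table([[5, np.nan, 1, np.nan]],
                   {"a": "radiologist", "b": "radiologist",
                    "c": "radiographer", "d": "radiographer"})
        assert weighted_mean_score(t).iloc[0] == pytest.approx((2 * 5 + 1) / 3)

    def test_equal_weights_reduce_to_mean(self):
        scores = pd.DataFrame([[1, 3, 5], [2, 2, 4]], columns=["a", "b", "c"],
                              index=["v0", "v1"])
        t = RatingTable(scores=scores,
                        roles={r: "radiologist" for r in "abc"})
        np.testing.assert_allclose(weighted_mean_score(t), scores.mean(axis=1))


class TestKrippendorff:
    def test_identical_columns_perfect_agreement(self):
        col = np.array([1, 2, 3, 4, 5, 1, 2, 3, 4, 5], dtype=float)
        scores = np.stack([col, col], axis=1)
        assert krippendorff_alpha(scores, "ordinal") == pytest.approx(1.0)

    def test_random_ratings_near_zero(self):
        rng = np.random.default_rng(123)
        scores = rng.integers(1, 6, size=(200, 4)).astype(float)
        assert abs(krippendorff_alpha(scores, "ordinal")) < 0.1

    def test_toy_matrix_matches_enumeration_oracle(self):
        scores = np.array([[1, 2, 2, np.nan],
                           [3, 3, 4, 3],
                           [5, 4, 4, 5]], dtype=float)
        for level in ("nominal", "interval", "ordinal"):
            assert krippendorff_alpha(scores, level) == pytest.approx(
                krippendorff_oracle(scores, level), abs=1e-10)

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            scores = rng.integers(1, 6, size=(12, 4)).astype(float)
            scores[rng.random(scores.shape) < 0.15] = np.nan
            if np.unique(scores[np.isfinite(scores)]).size < 2:
                continue
            assert krippendorff_alpha(scores, "ordinal") == pytest.approx(
                krippendorff_oracle(scores, "ordinal"), abs=1e-10)

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError):
            krippendorff_alpha(np.full((10, 3), 4.0), "ordinal")


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3], [30, 20, 10])[0] == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        x, y = [1, 2, 2, 4], [3, 1, 4, 5]
        assert spearman(x, y)[0] == pytest.approx(spearman_rho_oracle(x, y),
                                                  abs=1e-12)

    def test_rho_matches_scipy(self, rng):
        for n in (5, 12, 40):
            x, y = rng.random(n), rng.random(n)
            assert spearman(x, y)[0] == pytest.approx(
                stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_exact_p_small_n(self):
        # 3! = 6 permutations; |rho| = 1 achieved by identity and reversal
        _, p = spearman([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(2 / 6)

    def test_large_n_p_matches_t_approximation(self, rng):
        x = rng.random(40)
        y = x + rng.normal(0, 0.5, 40)
        _, p = spearman(x, y)
        sp = stats.spearmanr(x, y).pvalue
        assert p == pytest.approx(sp, rel=1e-6)

    def test_monotone_transform_invariance(self, rng):
        x = rng.random(15)
        y = rng.random(15)
        r0, _ = spearman(x, y)
        r1, _ = spearman(np.exp(3 * x), y ** 3 + 7)
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


def _toy_report():
    rho = pd.DataFrame({"seq1": [0.9, 0.5], "seq2": [0.3, 0.8]},
                       index=["M1", "M2"])
    p = pd.DataFrame({"seq1": [0.04, 0.06], "seq2": [0.2, 0.01]},
                     index=["M1", "M2"])
    alpha = pd.Series({"seq1": 0.8, "seq2": 0.7})
    return AgreementReport(rho=rho, p=p, alpha=alpha)


class TestSignificanceFilter:
    def test_threshold_masks_correct_cells(self):
        filt = significance_filter(_toy_report(), 0.05)
        assert filt.rho.loc["M1", "seq1"] == 0.9       # p = 0.04 retained
        assert np.isnan(filt.rho.loc["M2", "seq1"])    # p = 0.06 masked
        assert np.isnan(filt.rho.loc["M1", "seq2"])
        assert filt.rho.loc["M2", "seq2"] == 0.8

    def test_empty_report_passthrough(self):
        empty = AgreementReport(rho=pd.DataFrame(dtype=float, index=["M"],
                                                 columns=["s"]),
                                p=pd.DataFrame(dtype=float, index=["M"],
                                               columns=["s"]),
                                alpha=pd.Series(dtype=float),
                                median_ranks=pd.Series(dtype=float))
        out = significance_filter(empty)
        assert out.rho.isna().all().all()


class TestMedianRank:
    def test_single_sequence(self):
        rho = pd.DataFrame({"s": [0.9, 0.5, 0.7]}, index=list("ABC"))
        assert median_rank(rho).tolist() == [1.0, 3.0, 2.0]

    def test_reversed_orderings_average(self):
        rho = pd.DataFrame({"s1": [0.9, 0.5], "s2": [0.4, 0.6]},
                           index=["A", "B"])
        assert median_rank(rho).tolist() == [1.5, 1.5]

    def test_ties_get_average_rank(self):
        rho = pd.DataFrame({"s": [0.7, 0.7, 0.1]}, index=list("ABC"))
        assert median_rank(rho).tolist() == [1.5, 1.5, 3.0]

    def test_sign_ignored(self):
        rho = pd.DataFrame({"s": [-0.9, 0.5]}, index=["A", "B"])
        assert median_rank(rho).tolist() == [1.0, 2.0]


class TestRatingTable:
    def test_tidy_round_trip(self):
        t = _table([[4, 3], [2, 5]], {"a": "radiologist", "b": "radiographer"})
        back = RatingTable.from_tidy(t.to_tidy())
        pd.testing.assert_frame_equal(
            back.scores.sort_index(axis=1), t.scores.sort_index(axis=1),
            check_names=False)
        assert back.roles == t.roles

    def test_score_range_enforced(self):
        with pytest.raises(ValueError):
            _table([[0, 3]], {"a": "radiologist", "b": "radiographer"})
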