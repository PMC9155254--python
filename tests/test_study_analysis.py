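"""Response filtering, ANOVA, correlations, Bonferroni and report tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from simpedit import fixtures as fx
from simpedit.study_analysis import (ACCURACY_COLUMNS, bonferroni_threshold,
                                     build_report, demographic_correlations,
                                     filter_responses, one_way_anova,
                                     pearson_one_tailed, per_text_accuracy,
                                     secondary_accuracy)


def frame(seconds):
    return pd.DataFrame({"reading_seconds": seconds,
                         "participant_id": range(len(seconds))})


class TestFilterResponses:
    def test_boundary_exactly_sixty_retained(self):
        retained, excluded = filter_responses(frame([59.0, 60.0, 61.0]))
        assert list(retained["reading_seconds"]) == [60.0, 61.0]
        assert list(excluded["reading_seconds"]) == [59.0]

    def test_all_slow_readers_nothing_excluded(self):
        retained, excluded = filter_responses(frame([60.0, 200.0, 90.0]))
        assert len(excluded) == 0 and len(retained) == 3

    def test_missing_timing_flagged_not_silently_dropped(self):
        retained, excluded = filter_responses(frame([np.nan, 120.0]))
        assert len(retained) == 1
        assert list(excluded["exclusion_reason"]) == ["missing_timing"]

    def test_retained_rows_unaltered(self):
        df = frame([120.0, 45.0])
        df["likert"] = [3, 2]
        retained, _ = filter_responses(df)
        assert retained.iloc[0]["likert"] == 3
        assert "exclusion_reason" not in retained.columns

    def test_exclusion_is_per_text_not_per_participant(self):
        df = pd.DataFrame({"participant_id": [1, 1, 1, 1],
                           "reading_seconds": [30.0, 120.0, 130.0, 140.0]})
        retained, excluded = filter_responses(df)
        assert len(retained) == 3 and len(excluded) == 1


class TestOneWayAnova:
    def test_identical_groups_f_zero_p_one(self):
        res = one_way_anova([1, 2, 3], [1, 2, 3])
        assert res.f_value == 0.0 and res.p_value == 1.0

    def test_hand_decomposition(self):
        """Groups [1,2,3] vs [2,3,4]: SSB=1.5, SSW=4, df=(1,4), F=1.5."""
        res = one_way_anova([1, 2, 3], [2, 3, 4])
        assert res.f_value == pytest.approx(1.5)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.p_value == pytest.approx(float(sps.f.sf(1.5, 1, 4)))

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = rng.normal(size=rng.integers(3, 30))
            b = rng.normal(loc=0.3, size=rng.integers(3, 30))
            res = one_way_anova(a, b)
            ref = sps.f_oneway(a, b)
            assert res.f_value == pytest.approx(ref.statistic, abs=1e-9)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_two_groups_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            a = rng.normal(size=12)
            b = rng.normal(loc=0.5, size=15)
            res = one_way_anova(a, b)
            t = sps.ttest_ind(a, b).statistic
            assert res.f_value == pytest.approx(t * t, abs=1e-9)

    def test_degenerate_zero_variance_unequal_means(self):
        res = one_way_anova([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(res.f_value) and res.p_value == 0.0

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([1.0], [2.0, 3.0])


class TestPearsonOneTailed:
    def test_perfect_correlation(self):
        r, p = pearson_one_tailed([1, 2, 3], [10, 20, 30])
        assert r == pytest.approx(1.0) and p == 0.0

    def test_hand_covariance_example(self):
        r, p = pearson_one_tailed([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(0.9819805, abs=1e-6)
        assert 0.0 < p < 0.5

    def test_one_tailed_halves_the_two_tailed_p(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r, p = pearson_one_tailed(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue / 2, abs=1e-12)

    def test_null_rejection_rate_near_alpha(self):
        """x independent of y: the one-tailed test rejects at ~alpha."""
        rng = np.random.default_rng(17)
        rejections = sum(
            pearson_one_tailed(rng.normal(size=25), rng.normal(size=25))[1] < 0.05
            for _ in range(400))
        assert 0.02 < rejections / 400 < 0.09

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_one_tailed([1, 1, 1], [1, 2, 3])


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 4, 0.0125), (0.05, 1, 0.05), (0.01, 5, 0.002)])
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 4)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestBuildReport:
    @pytest.fixture(scope="class")
    @staticmethod
    def responses():
        return fx.make_responses(fx.SyntheticConfig(seed=21))

    def test_identical_conditions_give_zero_f(self):
        df = pd.DataFrame({
            "condition": ["original"] * 3 + ["simplified"] * 3,
            "likert": [1, 2, 3, 1, 2, 3]})
        report = build_report(df, measures=["likert"])
        assert report.iloc[0]["f_value"] == 0.0

    def test_report_layout_covers_all_measures(self, responses):
        report = build_report(responses)
        measures = list(report["measure"])
        for expected in ("likert", "tf_before_5", "mc_while_1", "tf_after_5",
                         "mc_after_4", "unique_word_count", "prop_similar",
                         "cosine_similarity", "correct_facts", "main_point",
                         "completeness", "correctness", "rouge_unigram_f",
                         "rouge_lcs_precision", "rouge_bigram_recall"):
            assert expected in measures
        assert set(report.columns) >= {"mean_original", "sd_original",
                                       "mean_simplified", "sd_simplified",
                                       "f_value", "p_value"}

    def test_report_reproduces_group_means(self, responses):
        report = build_report(responses).set_index("measure")
        by_cond = responses.groupby("condition")["likert"]
        assert report.loc["likert", "mean_original"] == pytest.approx(
            by_cond.mean()["original"], abs=1e-12)
        assert report.loc["likert", "sd_simplified"] == pytest.approx(
            by_cond.std()["simplified"], abs=1e-12)

    def test_empty_condition_cell_flagged_not_fabricated(self):
        df = pd.DataFrame({"condition": ["original"] * 4,
                           "likert": [1, 2, 3, 4]})
        report = build_report(df, measures=["likert"])
        assert report.iloc[0]["flag"] == "insufficient_data"
        assert np.isnan(report.iloc[0]["f_value"])


class TestSecondaryAnalysis:
    @pytest.fixture(scope="class")
    @staticmethod
    def responses():
        return fx.make_responses(fx.SyntheticConfig(seed=22))

    def test_accuracy_excludes_before_reading_items(self, responses):
        acc = secondary_accuracy(responses)
        cols = [c for c in ACCURACY_COLUMNS if c in responses.columns]
        assert not any(c.startswith("tf_before") for c in cols)
        expected = responses[cols].mean(axis=1)
        assert np.allclose(acc, expected)

    def test_demographic_correlation_table_shape(self, responses):
        table = demographic_correlations(responses)
        assert len(table) == 6  # 2 demographics x (all, original, simplified)
        assert (table["bonferroni_threshold"] == 0.0125).all()
        assert table["r"].abs().max() <= 1.0

    def test_per_text_accuracy_covers_texts_and_conditions(self, responses):
        table = per_text_accuracy(responses)
        assert set(table["text_id"]) == set(fx.TEXT_IDS)
        assert {"original", "simplified"} <= set(table.columns)
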