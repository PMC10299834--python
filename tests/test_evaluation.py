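"""Tests of accuracy metrics, aggregation, regression and the chi-squared contrast."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pawstrike import (
    AGED_FRACTIONS,
    YOUNG_FRACTIONS,
    BoutRecord,
    BoutSpec,
    PredictionSeries,
    accuracy,
    aggregate_predictions,
    chisq_distribution_contrast,
    per_label_histograms,
    regress_strikes_vs_turns,
    simulate_bout,
    within_k_accuracy,
)
from pawstrike.evaluation import DegenerateFitError, confusion_matrix

from .oracles import chi2_2xk, least_squares_fit


class TestAccuracy:
    def test_identical_vectors(self):
        assert accuracy([1, 2, 3], [1, 2, 3]) == 1.0

    def test_direct_count(self):
        assert accuracy([0, 0, 1, 2], [0, 0, 2, 2]) == 0.75

    def test_matches_confusion_matrix_recomputation(self, rng):
        preds = rng.integers(0, 8, 200)
        labels = rng.integers(0, 8, 200)
        cm = confusion_matrix(preds, labels, n_classes=8)
        assert accuracy(preds, labels) == pytest.approx(np.trace(cm) / cm.sum())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            accuracy([1], [1, 2])


class TestWithinK:
    def test_fig6_style_tolerance_band(self):
        # 40 clips labeled 4 Hz of which 34 predicted as 3, 4 or 5 Hz -> 85%
        preds = np.array([3] * 10 + [4] * 12 + [5] * 12 + [0] * 6)
        labels = np.full(40, 4)
        assert within_k_accuracy(preds, labels, k=1) == pytest.approx(0.85)

    def test_k_zero_equals_exact(self, rng):
        preds = rng.integers(0, 8, 100)
        labels = rng.integers(0, 8, 100)
        assert within_k_accuracy(preds, labels, k=0) == accuracy(preds, labels)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 7), st.integers(0, 7)), min_size=1, max_size=60
        )
    )
    def test_monotone_in_k_and_saturates(self, data):
        preds, labels = map(np.array, zip(*data))
        accs = [within_k_accuracy(preds, labels, k=k) for k in range(8)]
        assert accs[0] == accuracy(preds, labels)
        assert all(a <= b for a, b in zip(accs, accs[1:]))
        assert accs[7] == 1.0


class TestPerLabelHistograms:
    def test_perfect_predictions_all_exact(self):
        h = per_label_histograms([0, 1, 1], [0, 1, 1])
        assert h[0]["exact"] == 1 and h[1]["exact"] == 2
        assert h[1]["off_by_one"] == h[1]["beyond_one"] == 0

    def test_fig6_label4_partition(self):
        preds = np.array([3] * 10 + [4] * 12 + [5] * 12 + [0] * 6)
        labels = np.full(40, 4)
        h = per_label_histograms(preds, labels)[4]
        assert h["exact"] == 12
        assert h["within_one"] == 34

    def test_partition_conserves_counts(self, rng):
        preds = rng.integers(0, 8, 300)
        labels = rng.integers(0, 8, 300)
        for c, h in per_label_histograms(preds, labels).items():
            assert h["exact"] + h["off_by_one"] + h["beyond_one"] == h["n"]
            assert h["n"] == int((labels == c).sum())


class TestAggregation:
    def test_all_zero_series(self):
        bins, total = aggregate_predictions(
            PredictionSeries("b", np.zeros(180, int)), bin_s=60
        )
        assert not bins.any() and total == 0

    def test_constant_4hz(self):
        bins, total = aggregate_predictions(
            PredictionSeries("b", np.full(120, 4)), bin_s=60
        )
        assert list(bins) == [240, 240] and total == 480

    def test_ragged_tail_kept_and_linear(self, rng):
        freq = rng.integers(0, 8, 130)
        bins, total = aggregate_predictions(PredictionSeries("b", freq), bin_s=60)
        assert len(bins) == 3
        assert bins.sum() == total == freq.sum()

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            aggregate_predictions(PredictionSeries("b", np.zeros(0, int)))


class TestRegression:
    def test_perfectly_linear(self):
        records = [BoutRecord(f"b{i}", i * 100.0, 25.0 * i * 100) for i in range(1, 6)]
        fit = regress_strikes_vs_turns(records)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(25.0)

    def test_matches_closed_form_oracle(self, rng):
        strikes = rng.uniform(0, 5000, 30)
        turns = 0.25 * strikes + rng.normal(0, 50, 30)
        records = [BoutRecord(f"b{i}", s, max(t, 0)) for i, (s, t) in enumerate(zip(strikes, turns))]
        fit = regress_strikes_vs_turns(records)
        slope, intercept, r2 = least_squares_fit(
            [r.total_strikes for r in records], [r.total_turns for r in records]
        )
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.r_squared == pytest.approx(r2)

    def test_noiseless_simulated_bouts_r2_one(self):
        records = []
        for b in range(10):
            freq, turns = simulate_bout(
                BoutSpec(turn_noise_sd=0.0, turns_per_strike=1.0, seed=b)
            )
            records.append(BoutRecord(f"b{b}", float(freq.sum()), float(turns.sum())))
        fit = regress_strikes_vs_turns(records)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_input_rejected(self):
        records = [BoutRecord(f"b{i}", 100.0, 25.0) for i in range(5)]
        with pytest.raises(DegenerateFitError):
            regress_strikes_vs_turns(records)


class TestChiSquared:
    def test_identical_counts_zero_statistic(self):
        res = chisq_distribution_contrast([10, 20, 30], [10, 20, 30])
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 2

    def test_cohort_contrast_significant(self):
        # label distributions of the two cohorts (4800 vs 1000 clips)
        aged = np.round(np.array(AGED_FRACTIONS) / 100 * 4800)
        young = np.round(np.array(YOUNG_FRACTIONS[:8]) / 100 * 1000)
        res = chisq_distribution_contrast(aged, young)
        assert res.p_value < 0.001

    def test_matches_textbook_oracle(self):
        a, b = [30, 10], [20, 40]
        res = chisq_distribution_contrast(a, b)
        stat, df = chi2_2xk(a, b)
        assert res.statistic == pytest.approx(stat)
        assert res.df == df

    def test_zero_classes_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero total"):
            res = chisq_distribution_contrast([5, 0, 5], [5, 0, 5])
        assert res.df == 1

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            chisq_distribution_contrast([0, 0], [0, 0])
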