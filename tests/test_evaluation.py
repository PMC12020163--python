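"""Metrics: average precision, ECE, acquisition curves, paired tests."""

import numpy as np
import pytest
from scipy.stats import wilcoxon as scipy_wilcoxon

from molal import (
    InputError,
    MetricTrace,
    average_precision,
    cumulative_positive_curve,
    expected_calibration_error,
    gain_over_random,
    iterations_to_fraction,
    stable_from_pvalues,
    stable_significance_iteration,
    wilcoxon_at,
)


def brute_force_ap(scores, labels):
    """Step-wise AP computed literally: precision at each positive in
    descending-score order, with tied scores grouped."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    thresholds = np.unique(scores)[::-1]
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for thr in thresholds:
        sel = scores >= thr
        tp = labels[sel].sum()
        precision = tp / sel.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestAveragePrecision:
    def test_perfect_ranking_is_one(self):
        assert average_precision([4, 3, 2, 1], [1, 1, 0, 0]) == 1.0

    def test_worked_example(self):
        ap = average_precision([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert ap == pytest.approx((1.0 + 2 / 3) / 2, abs=1e-12)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(0)
        n, prevalence = 20000, 0.1
        labels = (rng.uniform(size=n) < prevalence).astype(int)
        ap = average_precision(rng.uniform(size=n), labels)
        se = np.sqrt(prevalence * (1 - prevalence) / n)
        assert abs(ap - prevalence) < 3 * se + 0.01

    def test_single_class_is_error(self):
        with pytest.raises(InputError):
            average_precision([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(4, 30)
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            ours = average_precision(scores, labels)
            assert ours == pytest.approx(brute_force_ap(scores, labels), abs=1e-12)


class TestEce:
    def test_perfectly_confident_correct_is_zero(self):
        assert expected_calibration_error(np.ones(10), np.ones(10, int)) == 0.0

    def test_single_bin_worked_example(self):
        # four points at p=0.8, three correct: |0.75 - 0.8| = 0.05
        ece = expected_calibration_error(np.full(4, 0.8), np.array([1, 1, 1, 0]))
        assert ece == pytest.approx(0.05, abs=1e-12)

    def test_bounded(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=500)
        y = rng.integers(0, 2, 500)
        assert 0.0 <= expected_calibration_error(p, y) <= 1.0

    def test_calibrated_predictor_tends_to_zero(self):
        rng = np.random.default_rng(3)
        n = 100_000
        p = rng.uniform(size=n)
        y = (rng.uniform(size=n) < p).astype(int)
        assert expected_calibration_error(p, y) < 0.02

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(InputError):
            expected_calibration_error(np.array([1.2]), np.array([1]))


class TestAcquisitionCurves:
    def test_cumulative_curve(self):
        assert cumulative_positive_curve(np.array([1, 0, 1])).tolist() == [1, 1, 2]

    def test_all_negative_curve_is_zero(self):
        assert cumulative_positive_curve(np.zeros(5, int)).tolist() == [0] * 5

    def test_iterations_to_fraction_examples(self):
        assert iterations_to_fraction(np.array([1, 1, 2, 3]), 4, 0.5) == 3
        assert iterations_to_fraction(np.array([1, 1, 2, 3]), 4, 1.0) is None

    def test_iterations_to_fraction_validates(self):
        with pytest.raises(InputError):
            iterations_to_fraction(np.array([1]), 0, 0.5)

    def test_uniform_curve_tracks_prevalence(self):
        rng = np.random.default_rng(4)
        prevalence, iters, reps = 0.2, 200, 50
        finals = [
            cumulative_positive_curve((rng.uniform(size=iters) < prevalence).astype(int))[-1]
            for _ in range(reps)
        ]
        se = np.sqrt(prevalence * (1 - prevalence) * iters / reps)
        assert abs(np.mean(finals) - prevalence * iters) < 3 * se


def _traces(values, arm, metric="avg_precision"):
    """Build single-point-grid traces for paired tests at iteration 0."""
    out = []
    for seed, v in enumerate(values):
        kwargs = dict(
            iterations=[0, 10], avg_precision=[v, v], ece=[v, v],
            cum_positives=[0, 0], arm=arm, task="t", seed=seed,
        )
        out.append(MetricTrace(**kwargs))
    return out


class TestPairedComparisons:
    def test_gain_zero_for_identical_arms(self):
        a = _traces([0.5, 0.6, 0.7], "a")
        b = _traces([0.5, 0.6, 0.7], "b")
        _, mean, _ = gain_over_random(a, b)
        assert np.allclose(mean, 0.0)

    def test_constant_offset_gain(self):
        a = _traces([0.55, 0.65, 0.75], "a")
        b = _traces([0.50, 0.60, 0.70], "b")
        _, mean, sem = gain_over_random(a, b)
        assert np.allclose(mean, 0.05)
        assert np.allclose(sem, 0.0, atol=1e-12)

    def test_wilcoxon_identical_pairs_degenerate(self):
        a = _traces([0.5] * 8, "a")
        with pytest.raises(InputError, match="degenerate"):
            wilcoxon_at(a, _traces([0.5] * 8, "b"), 0)

    def test_wilcoxon_consistent_dominance_significant(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0.4, 0.6, 20)
        a = _traces(base + 0.1 + 0.001 * rng.normal(size=20), "a")
        b = _traces(base, "b")
        res = wilcoxon_at(a, b, 0, alternative="greater")
        assert res.p_value < 0.05
        assert res.winner == "a"

    def test_rejection_rate_matches_permutation_oracle(self):
        """Under a known shift, the signed-rank rejection rate agrees with a
        sign-permutation oracle within Monte-Carlo error."""
        rng = np.random.default_rng(6)
        n_pairs, reps, shift = 10, 120, 0.5
        rej_test = rej_perm = 0
        for _ in range(reps):
            d = shift + rng.normal(size=n_pairs)
            rej_test += scipy_wilcoxon(d, alternative="greater").pvalue < 0.05
            # permutation oracle: sign-flip distribution of the mean
            flips = rng.choice([-1.0, 1.0], size=(400, n_pairs))
            null = (flips * np.abs(d)).mean(axis=1)
            p_perm = (null >= d.mean()).mean()
            rej_perm += p_perm < 0.05
        diff = abs(rej_test - rej_perm) / reps
        se = np.sqrt(2 * 0.25 / reps)
        assert diff < 3 * se + 0.05


class TestStableSignificance:
    def test_scan_from_right_example(self):
        grid = np.array([0, 10, 20, 30, 40])
        pvals = np.array([0.2, 0.01, 0.2, 0.01, 0.01])
        assert stable_from_pvalues(grid, pvals, alpha=0.05) == 30

    def test_never_significant_is_none(self):
        assert stable_from_pvalues(np.array([0, 10]), np.array([0.5, 0.5])) is None

    def test_transient_onset_not_returned(self):
        grid = np.array([0, 10, 20])
        pvals = np.array([0.01, 0.5, 0.5])
        assert stable_from_pvalues(grid, pvals) is None

    def test_end_to_end_onset_with_separated_traces(self):
        rng = np.random.default_rng(7)
        grid = [0, 10, 20, 30]
        a_tr, b_tr = [], []
        for seed in range(10):
            noise = 0.01 * rng.normal(size=4)
            base = np.array([0.5, 0.5, 0.5, 0.5])
            # arm a pulls clearly ahead from grid point 20 onward
            a_vals = base + np.array([0.0, 0.0, 0.2, 0.2]) + noise
            a_tr.append(MetricTrace(grid, a_vals, a_vals, [0] * 4, "a", "t", seed))
            b_tr.append(MetricTrace(grid, base, base, [0] * 4, "b", "t", seed))
        assert stable_significance_iteration(a_tr, b_tr, alpha=0.05) == 20
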