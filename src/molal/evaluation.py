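"""Evaluation metrics and paired comparisons for active-learning runs.

Ranking quality on the held-out test set is summarized by average precision
(area under the precision-recall curve), which remains informative under the
heavy class imbalance typical of toxicity screens. Uncertainty quality is
summarized by the Expected Calibration Error: predictions are binned by
predicted-class confidence into equal-width bins and the bin-weighted
absolute gap between confidence and empirical accuracy is averaged.

Acquisition behaviour is summarized by the cumulative count of positive
(e.g. toxic) compounds labeled up to each iteration, and by the iteration at
which a given fraction of all pool positives has been found.

Arms are compared pairwise per (task, seed) with Wilcoxon signed-rank tests;
the "stable significance" iteration is the earliest grid point from which
one arm stays significantly better at every later grid point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import wilcoxon
from sklearn.metrics import average_precision_score

from .mol_data import InputError


@dataclass
class MetricTrace:
    """Iteration-indexed metric curves for one (arm, task, seed) run."""

    iterations: np.ndarray
    avg_precision: np.ndarray
    ece: np.ndarray
    cum_positives: np.ndarray
    arm: str = ""
    task: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        self.iterations = np.asarray(self.iterations, dtype=np.int64)
        self.avg_precision = np.asarray(self.avg_precision, dtype=np.float64)
        self.ece = np.asarray(self.ece, dtype=np.float64)
        self.cum_positives = np.asarray(self.cum_positives, dtype=np.float64)


@dataclass
class ComparisonResult:
    """Outcome of a paired signed-rank comparison at one iteration."""

    iteration: int
    p_value: float
    winner: str
    stable_from: int | None = None


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step-wise AP).

    AP = sum_k (R_k - R_{k-1}) P_k over descending-score thresholds, with
    tied scores grouped into a single threshold.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise InputError("average precision undefined for single-class labels")
    return float(average_precision_score(y, np.asarray(scores, dtype=np.float64)))


def expected_calibration_error(
    probs: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> float:
    """Binned calibration gap of a binary probabilistic classifier.

    Confidence is max(p, 1-p) for predicted positive-class probability p and
    predicted label 1[p >= 0.5]. Confidences are split into ``n_bins``
    equal-width bins over [0, 1]; empty bins contribute nothing.
    """
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if ((p < 0) | (p > 1)).any():
        raise InputError("probabilities must lie in [0, 1]")
    if p.shape != y.shape:
        raise InputError("probs and labels disagree in shape")
    pred = (p >= 0.5).astype(int)
    conf = np.where(pred == 1, p, 1.0 - p)
    correct = (pred == y).astype(np.float64)
    # right-inclusive bins so conf = 1.0 lands in the last bin
    bins = np.clip((conf * n_bins).astype(int), 0, n_bins - 1)
    ece = 0.0
    n = p.size
    for b in range(n_bins):
        mask = bins == b
        nb = int(mask.sum())
        if nb == 0:
            continue
        ece += (nb / n) * abs(correct[mask].mean() - conf[mask].mean())
    return float(ece)


def cumulative_positive_curve(acquired_labels: np.ndarray) -> np.ndarray:
    """Running count of positive labels among acquisitions, per iteration."""
    y = np.asarray(acquired_labels, dtype=np.int64)
    if y.size == 0:
        raise InputError("no acquisitions recorded")
    return np.cumsum(y == 1)


def iterations_to_fraction(
    curve: np.ndarray, total_positives: int, fraction: float
) -> int | None:
    """First iteration (1-based) whose cumulative count reaches the target.

    The target is ``ceil(fraction * total_positives)``; returns None when the
    curve never reaches it.
    """
    if total_positives <= 0:
        raise InputError("total_positives must be positive")
    if not 0 < fraction <= 1:
        raise InputError("fraction must be in (0, 1]")
    need = int(np.ceil(fraction * total_positives))
    hits = np.flatnonzero(np.asarray(curve) >= need)
    return int(hits[0]) + 1 if hits.size else None


def _paired_values(
    traces_a: list[MetricTrace],
    traces_b: list[MetricTrace],
    iteration: int,
    metric: str,
) -> tuple[np.ndarray, np.ndarray]:
    key = lambda t: (t.task, t.seed)
    by_b = {key(t): t for t in traces_b}
    a_vals, b_vals = [], []
    for ta in traces_a:
        tb = by_b.get(key(ta))
        if tb is None:
            raise InputError(f"unpaired trace for (task, seed) = {key(ta)}")
        for tr, acc in ((ta, a_vals), (tb, b_vals)):
            pos = np.flatnonzero(tr.iterations == iteration)
            if pos.size == 0:
                raise InputError(f"iteration {iteration} not on the evaluation grid")
            acc.append(getattr(tr, metric)[pos[0]])
    return np.asarray(a_vals), np.asarray(b_vals)


def gain_over_random(
    traces_arm: list[MetricTrace],
    traces_random: list[MetricTrace],
    metric: str = "avg_precision",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired per-(task, seed) difference curve arm - random.

    Returns (iteration grid, mean difference, standard error of the mean).
    """
    if len(traces_arm) != len(traces_random):
        raise InputError("arm and random trace sets must pair one-to-one")
    grid = traces_arm[0].iterations
    for t in traces_arm + traces_random:
        if not np.array_equal(t.iterations, grid):
            raise InputError("all traces must share the evaluation grid")
    diffs = []
    for it in grid:
        a, b = _paired_values(traces_arm, traces_random, int(it), metric)
        diffs.append(a - b)
    diffs = np.asarray(diffs)  # (n_grid, n_pairs)
    mean = diffs.mean(axis=1)
    sem = diffs.std(axis=1, ddof=1) / np.sqrt(diffs.shape[1]) if diffs.shape[1] > 1 else np.zeros_like(mean)
    return grid.copy(), mean, sem


def wilcoxon_at(
    traces_a: list[MetricTrace],
    traces_b: list[MetricTrace],
    iteration: int,
    metric: str = "avg_precision",
    alternative: str = "greater",
) -> ComparisonResult:
    """Signed-rank test on paired per-(task, seed) values at one iteration."""
    a, b = _paired_values(traces_a, traces_b, iteration, metric)
    if a.size < 6:
        raise InputError("need at least 6 paired observations")
    if np.all(a == b):
        raise InputError("all paired differences are zero; test degenerate")
    stat = wilcoxon(a, b, alternative=alternative, zero_method="wilcox")
    winner = traces_a[0].arm if a.mean() >= b.mean() else traces_b[0].arm
    return ComparisonResult(iteration=iteration, p_value=float(stat.pvalue), winner=winner)


def stable_from_pvalues(
    grid: np.ndarray, pvalues: np.ndarray, alpha: float = 0.05
) -> int | None:
    """Scan a p-value sequence from the right for the stable-significance
    onset: the earliest grid point significant at every later point too."""
    grid = np.asarray(grid)
    pvalues = np.asarray(pvalues, dtype=np.float64)
    if grid.size < 2:
        raise InputError("evaluation grid needs at least 2 points")
    stable: int | None = None
    for it, p in zip(grid[::-1], pvalues[::-1]):
        if p < alpha:
            stable = int(it)
        else:
            break
    return stable


def stable_significance_iteration(
    traces_a: list[MetricTrace],
    traces_b: list[MetricTrace],
    alpha: float = 0.05,
    metric: str = "avg_precision",
) -> int | None:
    """Earliest grid iteration from which arm a stays significantly above b.

    One-sided (a > b) signed-rank p-values are computed at every grid point;
    the answer is the smallest grid point i with p < alpha at i and at every
    later grid point, scanning from the right. None when even the final
    point is not significant.
    """
    grid = traces_a[0].iterations
    if grid.size < 2:
        raise InputError("evaluation grid needs at least 2 points")
    pvals = []
    for it in grid:
        try:
            pvals.append(wilcoxon_at(traces_a, traces_b, int(it), metric, "greater").p_value)
        except InputError:
            pvals.append(1.0)  # degenerate ties: not significant
    return stable_from_pvalues(grid, np.asarray(pvals), alpha)


def aggregate_mean(
    traces: list[MetricTrace], metric: str = "avg_precision"
) -> tuple[np.ndarray, np.ndarray]:
    """Grid and mean curve, averaging across tasks then across seeds."""
    grid = traces[0].iterations
    by_seed: dict[int, list[np.ndarray]] = {}
    for t in traces:
        if not np.array_equal(t.iterations, grid):
            raise InputError("traces must share the evaluation grid")
        by_seed.setdefault(t.seed, []).append(getattr(t, metric))
    per_seed = [np.mean(rows, axis=0) for rows in by_seed.values()]
    return grid.copy(), np.mean(per_seed, axis=0)
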