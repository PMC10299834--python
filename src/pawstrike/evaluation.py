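"""Accuracy metrics, temporal aggregation, and activity statistics.

Exact accuracy is the fraction of clips whose predicted frequency class
matches the label; within-1-Hz accuracy loosens the criterion to
|prediction - label| <= 1 Hz, the tolerance used when judging how well
the classifier resolves neighbouring gait speeds.  Per-label histograms
partition each true class's predictions into {exact, off by 1 Hz,
off by more}.  Per-second predictions aggregate to per-minute foot-strike
counts and bout totals, which are regressed against the wheel's own
per-minute turn counts — the conventional low-resolution readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PredictionSeries",
    "BoutRecord",
    "RegressionResult",
    "ChiSquareResult",
    "DegenerateFitError",
    "accuracy",
    "within_k_accuracy",
    "class_balanced_accuracy",
    "confusion_matrix",
    "per_label_histograms",
    "aggregate_predictions",
    "regress_strikes_vs_turns",
    "chisq_distribution_contrast",
]


class DegenerateFitError(ValueError):
    """Regression input carries no variance to fit."""


@dataclass
class PredictionSeries:
    """Per-second predicted foot-strike frequency (Hz) across one bout."""

    bout_id: str
    freq_hz: np.ndarray

    def __post_init__(self) -> None:
        self.freq_hz = np.asarray(self.freq_hz, dtype=np.int64)
        if self.freq_hz.ndim != 1:
            raise ValueError("freq_hz must be a 1-D per-second series")
        if np.any(self.freq_hz < 0):
            raise ValueError("frequencies must be nonnegative")


@dataclass
class BoutRecord:
    """Bout totals: predicted foot strikes vs. recorded wheel turns."""

    bout_id: str
    total_strikes: float
    total_turns: float

    def __post_init__(self) -> None:
        if self.total_strikes < 0 or self.total_turns < 0:
            raise ValueError("bout totals must be nonnegative")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def _check_pair(preds, labels) -> tuple[np.ndarray, np.ndarray]:
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if preds.shape != labels.shape or preds.ndim != 1:
        raise ValueError(
            f"predictions and labels must be equal-length vectors, "
            f"got {preds.shape} vs {labels.shape}"
        )
    if len(preds) == 0:
        raise ValueError("empty prediction set")
    return preds, labels


def accuracy(preds, labels) -> float:
    """Fraction of exact class matches (overall, not class-balanced)."""
    preds, labels = _check_pair(preds, labels)
    return float((preds == labels).mean())


def within_k_accuracy(preds, labels, k: int = 1) -> float:
    """Fraction of predictions within ``k`` Hz of the label (default 1)."""
    preds, labels = _check_pair(preds, labels)
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    return float((np.abs(preds.astype(int) - labels.astype(int)) <= k).mean())


def class_balanced_accuracy(preds, labels) -> float:
    """Mean of per-class recalls; insensitive to the 0-Hz dominance."""
    preds, labels = _check_pair(preds, labels)
    recalls = [
        (preds[labels == c] == c).mean() for c in np.unique(labels)
    ]
    return float(np.mean(recalls))


def confusion_matrix(preds, labels, n_classes: int | None = None) -> np.ndarray:
    """Counts[true, predicted] over the class axis."""
    preds, labels = _check_pair(preds, labels)
    k = n_classes or int(max(preds.max(), labels.max())) + 1
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (labels, preds), 1)
    return cm


def per_label_histograms(preds, labels) -> dict[int, dict]:
    """For each true label: predicted-class counts and the partition
    {exact, off_by_one, beyond_one}.

    The three partition counts sum to the number of clips carrying that
    label; ``within_one`` (= exact + off_by_one) is also reported, since
    tolerance-band summaries are usually quoted cumulatively.
    """
    preds, labels = _check_pair(preds, labels)
    out: dict[int, dict] = {}
    for c in np.unique(labels):
        p = preds[labels == c]
        diff = np.abs(p.astype(int) - int(c))
        values, counts = np.unique(p, return_counts=True)
        out[int(c)] = {
            "n": int(len(p)),
            "predicted_counts": {int(v): int(k) for v, k in zip(values, counts)},
            "exact": int((diff == 0).sum()),
            "off_by_one": int((diff == 1).sum()),
            "beyond_one": int((diff > 1).sum()),
            "within_one": int((diff <= 1).sum()),
        }
    return out


def aggregate_predictions(
    series: PredictionSeries, bin_s: int = 60
) -> tuple[np.ndarray, int]:
    """Per-bin foot-strike counts and the bout total.

    Each second at frequency f contributes f strikes; bins are
    ``bin_s``-second windows and a ragged tail is kept as a short bin.
    """
    if len(series.freq_hz) == 0:
        raise ValueError("empty prediction series")
    if bin_s < 1:
        raise ValueError(f"bin_s must be >= 1, got {bin_s}")
    edges = np.arange(0, len(series.freq_hz), bin_s)
    bins = np.add.reduceat(series.freq_hz, edges)
    return bins, int(series.freq_hz.sum())


def regress_strikes_vs_turns(records) -> RegressionResult:
    """OLS of bout-total wheel turns on bout-total predicted foot strikes."""
    records = list(records)
    if len(records) < 3:
        raise ValueError(f"need >= 3 bout records, got {len(records)}")
    strikes = np.array([r.total_strikes for r in records], dtype=np.float64)
    turns = np.array([r.total_turns for r in records], dtype=np.float64)
    if np.ptp(strikes) == 0:
        raise DegenerateFitError("strike totals have zero variance")
    fit = stats.linregress(strikes, turns)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )


def chisq_distribution_contrast(counts_a, counts_b) -> ChiSquareResult:
    """Pearson chi-squared test of independence on a 2 x K contingency table.

    Used to contrast two labeled frequency distributions (e.g. aged vs.
    young cohorts).  Classes with zero total count are dropped with a
    warning, since expected counts must be positive; df = K - 1 over the
    K retained classes.
    """
    a = np.asarray(counts_a, dtype=np.float64)
    b = np.asarray(counts_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must share one class axis")
    keep = (a + b) > 0
    if not keep.any():
        raise ValueError("empty contingency table")
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} class(es) with zero total count",
            stacklevel=2,
        )
    table = np.vstack([a[keep], b[keep]])
    res = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic), df=int(res.dof), p_value=float(res.pvalue)
    )
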