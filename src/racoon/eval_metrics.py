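"""Discrimination and calibration metrics.

Global and per-protein AUROC, Youden-J optimal thresholds with bootstrap
uncertainty, reliability histograms with expected and maximal calibration
error (ECE / MCE), and generic non-parametric bootstrap machinery.

Conventions: higher score = pathogenic (callers orient raw LLRs by
negation); a variant is classified pathogenic when its score is >= the
threshold; reliability bins are equal-width on [0, 1], half-open with the
last bin closed at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .data_model import VariantTable
from .exceptions import DataError

#: A reliability bin enters the MCE only with more than this many samples.
MCE_MIN_COUNT = 50


def auroc(scores: Sequence[float], labels: Sequence[float]) -> float:
    """Rank-based AUROC with midrank tie handling."""
    y = np.asarray(labels, dtype=float)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise DataError("AUROC undefined with a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def per_protein_auroc(
    table: VariantTable,
    min_variants: int = 1,
    require_both_classes: bool = True,
    weighted: bool = False,
    scores: Optional[Sequence[float]] = None,
) -> float:
    """Mean AUROC over qualifying proteins.

    A protein qualifies with at least ``min_variants`` labeled variants and
    (by default) at least one variant of each class; others are excluded
    from the mean.  ``weighted`` weights proteins by variant count.
    ``scores`` overrides the table's raw scores (e.g. with calibrated
    probabilities).
    """
    if not table.has_labels():
        raise DataError("per-protein AUROC requires labels")
    x = np.asarray(scores, dtype=float) if scores is not None else table.scores
    y = table.labels
    vals, weights = [], []
    for _, idx in table.df.groupby("protein_id", sort=False).indices.items():
        idx = np.asarray(idx)
        sub_y = y[idx]
        if len(idx) < min_variants:
            continue
        has_both = np.any(sub_y == 1) and np.any(sub_y == 0)
        if require_both_classes and not has_both:
            continue
        if not has_both:
            continue  # AUROC is undefined regardless
        vals.append(auroc(x[idx], sub_y))
        weights.append(len(idx))
    if not vals:
        raise DataError("no qualifying protein")
    if weighted:
        return float(np.average(vals, weights=weights))
    return float(np.mean(vals))


def _youden_scan(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Best threshold (score >= c is pathogenic) and its J = TPR − FPR.

    Candidates are midpoints between consecutive distinct scores plus ±∞;
    ties are broken toward the smallest qualifying threshold.
    """
    distinct = np.unique(x)
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if len(distinct) > 1 else np.empty(0)
    candidates = np.concatenate(([-np.inf], mids, distinct, [np.inf]))
    candidates = np.unique(candidates)
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    # counts of scores >= c via searchsorted on sorted scores per class
    xs_pos = np.sort(x[y == 1])
    xs_neg = np.sort(x[y == 0])
    tpr = 1.0 - np.searchsorted(xs_pos, candidates, side="left") / n_pos
    fpr = 1.0 - np.searchsorted(xs_neg, candidates, side="left") / n_neg
    j = tpr - fpr
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximizer
    return float(candidates[best]), float(j[best])


def youden_threshold(
    scores: Sequence[float],
    labels: Sequence[float],
    bootstrap: int = 1000,
    seed: Optional[int] = None,
) -> tuple[float, float, float]:
    """Optimal classification threshold by the Youden J statistic.

    Returns ``(threshold, bootstrap_sd, J)``.  The threshold maximizes
    TPR − FPR over an exhaustive candidate scan; its uncertainty is the
    standard deviation over ``bootstrap`` resampled datasets.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise DataError("threshold undefined with a single class")
    thr, j = _youden_scan(x, y)
    sd = float("nan")
    if bootstrap and bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = len(x)
        vals = []
        for _ in range(bootstrap):
            idx = rng.integers(0, n, size=n)
            yy = y[idx]
            if not (np.any(yy == 1) and np.any(yy == 0)):
                continue
            t, _ = _youden_scan(x[idx], yy)
            if np.isfinite(t):
                vals.append(t)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
    return thr, sd, j


@dataclass(frozen=True)
class ReliabilityReport:
    """Binned confidence-vs-frequency table with ECE and MCE."""

    bin_edges: np.ndarray
    bin_count: np.ndarray
    bin_mean_confidence: np.ndarray
    bin_pathogenic_frequency: np.ndarray
    ece: float
    mce: Optional[float]


def reliability_histogram(
    probs: Sequence[float],
    labels: Sequence[float],
    n_bins: int = 10,
    mce_min_count: int = MCE_MIN_COUNT,
) -> ReliabilityReport:
    """Reliability table over equal-width probability bins.

    ECE is the count-weighted mean absolute gap between per-bin mean
    confidence and empirical pathogenic frequency; MCE is the maximal gap
    over bins with more than ``mce_min_count`` samples (None if no bin
    qualifies).
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.min() < 0.0 or p.max() > 1.0:
        raise DataError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.minimum((p * n_bins).astype(int), n_bins - 1)  # last bin closed at 1
    count = np.bincount(idx, minlength=n_bins)
    conf = np.zeros(n_bins)
    freq = np.zeros(n_bins)
    occ = count > 0
    conf[occ] = np.bincount(idx, weights=p, minlength=n_bins)[occ] / count[occ]
    freq[occ] = np.bincount(idx, weights=(y == 1.0), minlength=n_bins)[occ] / count[occ]
    gaps = np.abs(conf - freq)
    ece = float((count[occ] * gaps[occ]).sum() / count.sum())
    big = count > mce_min_count
    mce = float(gaps[big].max()) if big.any() else None
    return ReliabilityReport(edges, count, conf, freq, ece, mce)


def bootstrap_eval(
    metric: Callable[[VariantTable], float],
    table: VariantTable,
    iters: int = 100,
    seed: Optional[int] = None,
    max_retries: int = 100,
) -> tuple[float, float]:
    """Non-parametric bootstrap of a table-level metric.

    Records are resampled with replacement; a resample on which the metric
    fails (e.g. a single class) is redrawn, up to ``max_retries`` times per
    iteration.  Returns the bootstrap mean and standard deviation.
    """
    if iters < 1:
        raise DataError("iters must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(table)
    vals = []
    for _ in range(iters):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            try:
                vals.append(metric(table.take(idx)))
                break
            except DataError:
                if attempt == max_retries:
                    raise
    vals = np.asarray(vals)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd
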