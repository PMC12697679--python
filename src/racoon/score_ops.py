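"""Score-level operators.

Log-likelihood ratios from per-position logit vectors, sliding-window
bookkeeping for proteins longer than the language-model context, normalized
entropy of prediction vectors, robust outlier filters, and the modified
min–max normalization used to place heterogeneous predictor scores on a
common pathogenic-high [0, 1] scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import log_softmax

from .exceptions import DataError, ParameterError


@dataclass(frozen=True)
class LogitVector:
    """Raw model logits at one position plus wild-type/mutant token indices."""

    values: np.ndarray
    wt_index: int
    mut_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or len(self.values) < 2:
            raise DataError("logit vector must be 1-D with at least 2 entries")
        if self.wt_index == self.mut_index:
            raise DataError("wild-type and mutant indices must differ")


def llr_from_logits(lv: LogitVector, mode: str = "eq2") -> float:
    """Log-likelihood ratio of mutant vs wild-type amino acid.

    ``eq2``
        Subtract the wild-type logit from the whole vector, log-softmax the
        shifted vector and read off the mutant entry.  By shift invariance of
        the softmax this equals ``log softmax(values)[mut]`` — i.e. the log
        probability of the mutant token, not a literal ratio.
    ``naive_diff``
        The raw logit difference ``values[mut] − values[wt]``, which is what
        log-softmax-then-subtract reduces to algebraically.

    Both conventions appear in practice; ``eq2`` is the default.
    """
    v = lv.values
    if not np.all(np.isfinite(v)):
        raise DataError("logits must be finite")
    if mode == "eq2":
        shifted = v - v[lv.wt_index]
        return float(log_softmax(shifted)[lv.mut_index])
    if mode == "naive_diff":
        return float(v[lv.mut_index] - v[lv.wt_index])
    raise ParameterError(f"unknown LLR mode {mode!r}")


@dataclass(frozen=True)
class WindowPlan:
    """Sliding windows over a protein sequence.

    Each entry is ``(window_start, window_end, scored_start, scored_end)``,
    0-based half-open.  Scored ranges are pairwise disjoint and cover the
    whole sequence.
    """

    windows: tuple[tuple[int, int, int, int], ...]

    @property
    def scored_ranges(self) -> list[tuple[int, int]]:
        return [(s, e) for (_, _, s, e) in self.windows]


def plan_windows(seq_len: int, window: int = 1022, overlap: int = 250) -> WindowPlan:
    """Plan sliding windows for a sequence longer than the model context.

    Interior windows score only their central ``window − 2·overlap``
    positions; the first and last windows additionally score their terminal
    overlap regions so coverage is complete and disjoint.
    """
    if seq_len < 1:
        raise ParameterError("seq_len must be >= 1")
    if window <= 2 * overlap:
        raise ParameterError("window must exceed twice the overlap")
    if seq_len <= window:
        return WindowPlan(((0, seq_len, 0, seq_len),))

    core = window - 2 * overlap
    out: list[tuple[int, int, int, int]] = []
    scored_start = 0
    win_start = 0
    while scored_start < seq_len:
        win_start = min(win_start, seq_len - window)
        win_end = win_start + window
        last = win_end >= seq_len
        scored_end = seq_len if last else win_start + overlap + core
        out.append((win_start, win_end, scored_start, scored_end))
        scored_start = scored_end
        win_start += core
    return WindowPlan(tuple(out))


def normalized_entropy(p: Sequence[float], flipped: bool = False) -> float:
    """Certainty of a probability vector on a [0, 1] scale.

    Returns ``1 − H(p)/log N`` (1 = one-hot, 0 = uniform), with the usual
    ``0·log 0 := 0`` convention.  With ``flipped=True`` the complement
    ``H(p)/log N`` is returned instead (1 = complete uncertainty), the
    orientation used when plotting entropy distributions.
    """
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n < 2:
        raise DataError("probability vector needs at least 2 entries")
    if np.any(p < 0):
        raise DataError("probabilities must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise DataError("probabilities must sum to 1")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum()) / np.log(n)
    return h if flipped else 1.0 - h


def modified_zscore_filter(values: Sequence[float], threshold: float = 4.25) -> np.ndarray:
    """Keep-mask removing extreme outliers by the modified z-score.

    ``z_i = 0.6745·|x_i − median| / MAD``; values with ``z_i > threshold``
    (strict) are dropped.  Applied to the pooled data without class
    separation.  When MAD = 0 the score is undefined: nothing is removed and
    a warning is emitted.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 1:
        raise DataError("need at least one value")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("MAD is zero; modified z-score undefined, keeping all values",
                      stacklevel=2)
        return np.ones(len(x), dtype=bool)
    z = 0.6745 * np.abs(x - med) / mad
    return z <= threshold


def percentile_filter(values: Sequence[float], tail_frac: float = 0.001) -> np.ndarray:
    """Keep-mask removing both 0.1-percentile tails (strict exceedance)."""
    if not 0.0 < tail_frac < 0.5:
        raise ParameterError("tail_frac must lie in (0, 0.5)")
    x = np.asarray(values, dtype=float)
    if len(x) < 10:
        raise DataError("need at least 10 values for a percentile filter")
    lo = np.quantile(x, tail_frac)
    hi = np.quantile(x, 1.0 - tail_frac)
    return (x >= lo) & (x <= hi)


def minmax_normalize_orient(scores: Sequence[float], labels: Sequence[float]) -> np.ndarray:
    """Modified min–max normalization with pathogenic-high orientation.

    Tail outliers (0.1 percentile each side) are excluded when computing the
    min–max range; all values are then rescaled, clipped into [0, 1], and
    flipped (``s → 1 − s``) if the pathogenic mean is below the benign mean.
    Outliers thus end up clamped at 1 on the high tail and 0 on the low tail
    *after* orientation.  Scores already within [0, 1] are not rescaled, only
    flipped if needed.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise DataError("both classes required to orient scores")

    if x.min() >= 0.0 and x.max() <= 1.0:
        out = x.copy()
    else:
        keep = percentile_filter(x)
        lo, hi = x[keep].min(), x[keep].max()
        if hi == lo:
            out = np.full_like(x, 0.5)
        else:
            out = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    if out[y == 1].mean() < out[y == 0].mean():
        out = 1.0 - out
    return out
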