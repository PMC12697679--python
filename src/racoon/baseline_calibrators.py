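"""Comparison calibrators.

Balanced logistic rescaling (global and per-subgroup), direct equal-frequency
histogram binning of raw labeled scores, and a hybrid that pools synthetic
mixture draws with raw scores.  These are the baselines the tree-based
calibration is measured against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .data_model import VariantTable
from .exceptions import DataError
from .node_calibration import CalibrationHistogram, equal_frequency_edges
from .score_ops import percentile_filter

GLOBAL_GROUP = "__global__"


@dataclass(frozen=True)
class LogisticParams:
    """Scale and intercept of a univariate logistic rescaling."""

    c1: float
    c2: float

    def apply(self, scores) -> np.ndarray:
        """sigmoid(c1·x + c2), in (0, 1) and monotone in x."""
        return expit(self.c1 * np.asarray(scores, dtype=float) + self.c2)


def logistic_calibrate(
    scores: Sequence[float],
    labels: Sequence[float],
    n_per_class: Optional[int] = None,
    seed: Optional[int] = None,
    tail_frac: float = 0.001,
    l2: bool = False,
) -> LogisticParams:
    """Fit a balanced univariate logistic rescaling.

    Tail outliers are removed first; a balanced subsample (``n_per_class``
    per class, majority class down-sampled without replacement) is then fit
    by maximum likelihood (L-BFGS, 100 iterations, no penalty unless
    ``l2``).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    keep = percentile_filter(x, tail_frac)
    x, y = x[keep], y[keep]
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("both classes required to fit a logistic calibrator")
    n = n_per_class if n_per_class is not None else min(len(pos), len(neg))
    if len(pos) < n or len(neg) < n:
        raise DataError(f"need at least {n} samples per class after outlier removal")
    rng = np.random.default_rng(seed)
    idx = np.concatenate([rng.choice(pos, n, replace=False),
                          rng.choice(neg, n, replace=False)])
    lr = LogisticRegression(
        penalty="l2" if l2 else None,
        solver="lbfgs",
        max_iter=100,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separable data hits the iteration cap
        lr.fit(x[idx].reshape(-1, 1), y[idx])
    return LogisticParams(float(lr.coef_[0, 0]), float(lr.intercept_[0]))


def _scheme_groups(table: VariantTable, scheme: str) -> np.ndarray:
    """Subgroup key per record; empty string means fall back to global."""
    def col(name):
        return table.attribute_values(name)

    n = len(table)
    out = np.array([""] * n, dtype=object)
    if scheme == "ppi_split":
        v = col("ppi")
        out[v == 1.0] = "ppi"
        out[v == 0.0] = "non_ppi"
    elif scheme == "fold_split":
        v = col("disordered")
        out[v == 1.0] = "disordered"
        out[v == 0.0] = "ordered"
    elif scheme == "joint":
        d = col("disordered")
        p = col("ppi")
        out[d == 1.0] = "disordered"
        ordered = d == 0.0
        out[ordered & (p == 1.0)] = "ordered_ppi"
        out[ordered & (p == 0.0)] = "ordered_non_ppi"
    else:
        raise DataError(f"unknown scheme {scheme!r}")
    return out


def subgroup_logistic_calibrate(
    table: VariantTable,
    scheme: str = "fold_split",
    n_per_class: Optional[int] = None,
    seed: Optional[int] = None,
) -> dict[str, LogisticParams]:
    """Independent logistic rescaling per residue subgroup.

    Schemes: ``ppi_split`` (interface vs not), ``fold_split`` (disordered vs
    ordered), ``joint`` (disordered, ordered-interface, ordered-other).  A
    subgroup with fewer than ``2·n_per_class`` usable variants falls back to
    the global fit with a warning, as do variants whose scheme attributes
    are missing.  The returned map always contains the global parameters
    under :data:`GLOBAL_GROUP`.
    """
    if not table.has_labels():
        raise DataError("calibration requires labels")
    x = table.scores
    y = table.labels
    rng = np.random.default_rng(seed)
    out = {GLOBAL_GROUP: logistic_calibrate(
        x, y, n_per_class, seed=int(rng.integers(2**31 - 1)))}
    groups = _scheme_groups(table, scheme)
    for g in sorted(set(groups) - {""}):
        sel = groups == g
        need = 2 * n_per_class if n_per_class is not None else 2
        if sel.sum() < need:
            warnings.warn(f"subgroup {g!r} too small; using global fit", stacklevel=2)
            out[g] = out[GLOBAL_GROUP]
            continue
        try:
            out[g] = logistic_calibrate(x[sel], y[sel], n_per_class,
                                        seed=int(rng.integers(2**31 - 1)))
        except DataError:
            warnings.warn(f"subgroup {g!r} unfittable; using global fit", stacklevel=2)
            out[g] = out[GLOBAL_GROUP]
    return out


def apply_subgroup_calibration(
    table: VariantTable,
    params: Mapping[str, LogisticParams],
    scheme: str,
) -> np.ndarray:
    """Calibrated probabilities using each variant's subgroup parameters."""
    groups = _scheme_groups(table, scheme)
    x = table.scores
    out = np.empty(len(table))
    for g in set(groups):
        sel = groups == g
        p = params.get(g if g else GLOBAL_GROUP, params[GLOBAL_GROUP])
        out[sel] = p.apply(x[sel])
    return out


def direct_binning_calibrate(scores: Sequence[float], labels: Sequence[float],
                             n_bins: int) -> CalibrationHistogram:
    """Equal-frequency binning of raw labeled scores.

    Each bin's value is the empirical pathogenic fraction of the raw scores
    it contains.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if n_bins > len(x):
        raise DataError(f"n_bins={n_bins} exceeds sample count {len(x)}")
    edges = equal_frequency_edges(x, n_bins)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    path = np.bincount(idx, weights=(y == 1.0), minlength=len(edges) - 1)
    frac = np.where(counts > 0, path / np.maximum(counts, 1), 0.0)
    return CalibrationHistogram(edges, frac, 0)


def hybrid_binning_calibrate(
    synthetic_scores: Sequence[float],
    synthetic_is_pathogenic: Sequence[bool],
    raw_scores: Sequence[float],
    raw_labels: Sequence[float],
    n_bins: int,
) -> CalibrationHistogram:
    """Equal-frequency binning over pooled synthetic draws and raw scores.

    Synthetic draws count toward the pathogenic fraction by their source
    mixture, raw scores by their label.  With an empty raw (synthetic) side
    this reduces to pure synthetic (direct) binning.
    """
    xs = np.asarray(synthetic_scores, dtype=float)
    ps = np.asarray(synthetic_is_pathogenic, dtype=bool)
    xr = np.asarray(raw_scores, dtype=float)
    yr = np.asarray(raw_labels, dtype=float)
    pooled = np.concatenate([xs, xr])
    is_path = np.concatenate([ps, yr == 1.0])
    if len(pooled) == 0:
        raise DataError("both sources empty")
    if n_bins > len(pooled):
        raise DataError(f"n_bins={n_bins} exceeds pooled sample count {len(pooled)}")
    edges = equal_frequency_edges(pooled, n_bins)
    idx = np.clip(np.searchsorted(edges, pooled, side="right") - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    path = np.bincount(idx, weights=is_path, minlength=len(edges) - 1)
    frac = np.where(counts > 0, path / np.maximum(counts, 1), 0.0)
    return CalibrationHistogram(edges, frac, len(xs))
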