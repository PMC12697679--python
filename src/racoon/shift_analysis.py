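"""Label-shift and class-conditional feature-distribution-shift analysis.

Quantifies, per binary residue attribute M:

* the *label shift* — absolute difference between the pooled pathogenic
  rate and the rate inside the subgroup;
* the *class-conditional divergence* — the sum over labels of the squared
  Jensen–Shannon distance between the feature distributions of M and ¬M,
  estimated on a smoothed equal-width histogram over [0, 1];
* mutual information between attributes and labels at the residue vs
  protein level, with bootstrap uncertainty;
* Fisher exact tests with Benjamini–Hochberg correction; and
* Kendall-τ rank stability of divergences across histogram resolutions.

All logarithms are natural, so each per-label divergence lies in [0, ln 2]
and the two-label sum in [0, 2·ln 2].
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import fisher_exact, kendalltau
from scipy.stats import false_discovery_control
from sklearn.metrics import mutual_info_score

from .data_model import VariantTable
from .exceptions import DataError

#: Default histogram smoothing constant (in e-units, per the natural-log
#: convention used throughout).
DEFAULT_EPS = math.exp(-12)


@dataclass(frozen=True)
class ShiftResult:
    """Shift statistics for one attribute."""

    attribute: str
    label_shift: float
    divergence: float
    subgroup_sizes: tuple[int, int]  # (n_M, n_notM)
    scoring_strategy: str = "score"


def _smoothed_hist(x: np.ndarray, bins: int, eps: float) -> np.ndarray:
    counts, _ = np.histogram(x, bins=bins, range=(0.0, 1.0))
    p = counts / counts.sum() + eps
    return p / p.sum()


def minmax_to_unit(x: np.ndarray) -> np.ndarray:
    """Map a feature onto [0, 1] by plain min–max (constant input → 0.5)."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def conditional_jsd(
    feature: Sequence[float],
    mask: Sequence[bool],
    labels: Sequence[float],
    bins: int = 100,
    eps: float = DEFAULT_EPS,
    normalize: bool = False,
) -> float:
    """Class-conditional Jensen–Shannon divergence between M and ¬M.

    For each label l the feature values of the two subgroups are histogrammed
    into ``bins`` equal-width bins on [0, 1], every bin is smoothed by ``eps``
    and renormalized, and the squared Jensen–Shannon distance (natural log)
    is computed; the two per-label divergences are summed.  ``normalize``
    min–max maps features that are not already in [0, 1] (e.g. raw LLRs).
    """
    x = np.asarray(feature, dtype=float)
    m = np.asarray(mask, dtype=bool)
    y = np.asarray(labels, dtype=float)
    if normalize:
        x = minmax_to_unit(x)
    if x.min() < 0.0 or x.max() > 1.0:
        raise DataError("feature must lie in [0, 1]; pass normalize=True for raw scores")

    total = 0.0
    for lab, lab_name in ((1.0, "pathogenic"), (0.0, "benign")):
        sel = y == lab
        a = x[sel & m]
        b = x[sel & ~m]
        if len(a) == 0:
            raise DataError(f"empty subgroup-label cell: (M, {lab_name})")
        if len(b) == 0:
            raise DataError(f"empty subgroup-label cell: (not-M, {lab_name})")
        p = _smoothed_hist(a, bins, eps)
        q = _smoothed_hist(b, bins, eps)
        total += float(jensenshannon(p, q, base=math.e) ** 2)
    return total


def label_shift(labels: Sequence[float], mask: Sequence[bool]) -> float:
    """|pooled pathogenic rate − subgroup pathogenic rate|."""
    y = np.asarray(labels, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if m.sum() == 0:
        raise DataError("empty subgroup")
    return float(abs(y.mean() - y[m].mean()))


@dataclass(frozen=True)
class MIEstimate:
    point: float
    mean: float
    sd: float


def mutual_information(
    labels: Sequence[float],
    groups: Sequence,
    bootstrap: int = 1000,
    seed: Optional[int] = None,
) -> MIEstimate:
    """Plug-in mutual information (nats) with bootstrap uncertainty.

    Rows are resampled with replacement ``bootstrap`` times; the returned
    mean/sd summarize the bootstrap distribution, ``point`` is the estimate
    on the full data.
    """
    y = np.asarray(labels)
    g = np.asarray(groups)
    if len(np.unique(g)) < 2:
        raise DataError("need at least 2 groups")
    point = float(mutual_info_score(y, g))
    rng = np.random.default_rng(seed)
    n = len(y)
    vals = np.empty(bootstrap)
    for i in range(bootstrap):
        idx = rng.integers(0, n, size=n)
        vals[i] = mutual_info_score(y[idx], g[idx])
    return MIEstimate(point=point, mean=float(vals.mean()), sd=float(vals.std(ddof=1)))


def protein_level_groups(table: VariantTable, attribute: str, n_bins: int = 3) -> np.ndarray:
    """Per-record protein group by attribute enrichment.

    For each protein the fraction of its (non-missing) variant records with
    the attribute true is computed, and proteins are assigned to ``n_bins``
    equal-width groups over the observed fraction range.  All records of a
    protein share its group.
    """
    vals = table.attribute_values(attribute)
    pid = table.protein_ids
    frac_by_protein: dict = {}
    for p, idx in pd.Series(range(len(pid))).groupby(pd.Series(pid), sort=False).groups.items():
        v = vals[np.asarray(idx)]
        v = v[np.isfinite(v)]
        frac_by_protein[p] = float(v.mean()) if len(v) else 0.0
    fr = np.array(list(frac_by_protein.values()))
    lo, hi = fr.min(), fr.max()
    if hi == lo:
        group_of = {p: 0 for p in frac_by_protein}
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        group_of = {
            p: min(int(np.searchsorted(edges, f, side="right")) - 1, n_bins - 1)
            for p, f in frac_by_protein.items()
        }
    return np.array([group_of[p] for p in pid], dtype=int)


def fisher_bh(tables: Sequence[Sequence[Sequence[int]]],
              alpha: float = 0.05) -> list[tuple[float, float, float]]:
    """Two-sided Fisher exact tests with Benjamini–Hochberg adjustment.

    Returns one ``(odds_ratio, p, p_adjusted)`` triple per 2×2 table.
    """
    ors, ps = [], []
    for t in tables:
        t = np.asarray(t, dtype=int)
        if t.shape != (2, 2) or (t < 0).any():
            raise DataError("each table must be a non-negative 2x2 count matrix")
        if t.sum() == 0:
            raise DataError("all-zero contingency table")
        orr, p = fisher_exact(t, alternative="two-sided")
        ors.append(float(orr))
        ps.append(float(p))
    p_adj = false_discovery_control(ps, method="bh")
    return [(o, p, float(pa)) for o, p, pa in zip(ors, ps, p_adj)]


def kendall_tau_stability(
    divergences_by_binsize: Mapping[int, Mapping[str, float]],
) -> pd.DataFrame:
    """Pairwise Kendall τ between divergence rankings at different bin sizes."""
    sizes = sorted(divergences_by_binsize)
    if len(sizes) < 2:
        raise DataError("need at least 2 bin sizes")
    attr_sets = [frozenset(divergences_by_binsize[s]) for s in sizes]
    if len(set(attr_sets)) != 1:
        raise DataError("attribute sets differ across bin sizes")
    attrs = sorted(attr_sets[0])
    mat = pd.DataFrame(np.eye(len(sizes)), index=sizes, columns=sizes)
    for a, b in itertools.combinations(sizes, 2):
        va = [divergences_by_binsize[a][k] for k in attrs]
        vb = [divergences_by_binsize[b][k] for k in attrs]
        tau = kendalltau(va, vb).statistic
        mat.loc[a, b] = mat.loc[b, a] = tau
    return mat


def shift_scan(
    table: VariantTable,
    attributes: Optional[Sequence[str]] = None,
    bins: int = 100,
    feature: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Per-attribute shift report.

    Columns: attribute, n_M, n_notM, label_shift, divergence, OR, p, p_adj.
    ``feature`` defaults to the (min–max mapped) raw score.  Attributes whose
    subgroup-label cells are empty are reported with NaN divergence.
    """
    if not table.has_labels():
        raise DataError("shift scan requires labels")
    attributes = list(attributes) if attributes is not None else list(table.attribute_names)
    y = table.labels
    x = minmax_to_unit(np.asarray(feature, dtype=float) if feature is not None
                       else table.scores)

    rows = []
    contingency = []
    for a in attributes:
        v = table.attribute_values(a)
        known = np.isfinite(v)
        m = known & (v == 1.0)
        nm = known & (v == 0.0)
        n_m, n_nm = int(m.sum()), int(nm.sum())
        ls = label_shift(y[known], m[known]) if n_m else math.nan
        try:
            div = conditional_jsd(x[known], (v == 1.0)[known], y[known], bins=bins)
        except DataError:
            div = math.nan
        rows.append((a, n_m, n_nm, ls, div))
        contingency.append([
            [int((y[m] == 1).sum()), int((y[m] == 0).sum())],
            [int((y[nm] == 1).sum()), int((y[nm] == 0).sum())],
        ])
    stats = fisher_bh(contingency)
    df = pd.DataFrame(rows, columns=["attribute", "n_M", "n_notM",
                                     "label_shift", "divergence"])
    df["OR"] = [s[0] for s in stats]
    df["p"] = [s[1] for s in stats]
    df["p_adj"] = [s[2] for s in stats]
    return df
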