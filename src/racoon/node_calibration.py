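"""Per-node distribution modelling and the score→probability mapping.

Each calibrated tree node carries:

* the pathogenic fraction of the subgroup, estimated from a small random
  sample of labels (500 by default — comfortably above the ~385 required
  for a ±0.05 normal-approximation 95% confidence interval on a Bernoulli
  rate with no prior on p);
* two two-component 1-D Gaussian mixtures, one per class, fitted by EM on
  400 sampled scores per class (reusing the fraction-estimation sample);
* an equal-frequency calibration histogram built from 40,000 synthetic
  mixture draws, mixed according to the estimated fraction.  Each bin's
  value is the pathogenic-source proportion of the draws it holds, i.e. an
  estimate of P(pathogenic | score ∈ bin, subgroup).

At inference a variant walks the tree as far as its (possibly missing)
attributes allow and reads its probability from that node's histogram.
Raw scores are used as-is (more negative = more deleterious for LLRs); the
histograms encode the orientation implicitly.
"""

from __future__ import annotations

import datetime
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .calibration_tree import (CalibTreeNode, TreeConfig, _node_seed,
                               build_tree, prune_tree, traverse)
from .data_model import VariantTable
from .exceptions import DataError, ParameterError
from .score_ops import modified_zscore_filter

MODEL_FORMAT_VERSION = "1"


def fraction_sample_size(confidence: float = 0.95, half_width: float = 0.05,
                         p: float = 0.5) -> int:
    """Normal-approximation sample size for a Bernoulli rate estimate.

    Smallest n such that the two-sided ``confidence`` interval for a
    proportion has half-width at most ``half_width``, with no finite
    population correction.  With no prior on p the worst case p = 0.5 is
    used, giving n = 385 at 95% / ±0.05.
    """
    if not 0 < confidence < 1 or half_width <= 0:
        raise ParameterError("confidence in (0,1) and half_width > 0 required")
    z = norm.ppf(1.0 - (1.0 - confidence) / 2.0)
    return int(math.ceil(z * z * p * (1.0 - p) / (half_width * half_width)))


@dataclass(frozen=True)
class GaussianMixtureParams:
    """A 1-D K-component Gaussian mixture."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        for name in ("weights", "means", "variances"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        k = len(self.weights)
        if len(self.means) != k or len(self.variances) != k:
            raise DataError("weights, means and variances must share one length")
        if not np.isclose(self.weights.sum(), 1.0):
            raise DataError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise DataError("variances must be positive")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        return rng.normal(self.means[comp], np.sqrt(self.variances[comp]))

    def sorted_by_mean(self) -> "GaussianMixtureParams":
        order = np.argsort(self.means)
        return GaussianMixtureParams(self.weights[order], self.means[order],
                                     self.variances[order])

    def to_dict(self) -> dict:
        return {"weights": self.weights.tolist(), "means": self.means.tolist(),
                "variances": self.variances.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "GaussianMixtureParams":
        return cls(np.asarray(d["weights"]), np.asarray(d["means"]),
                   np.asarray(d["variances"]))


@dataclass(frozen=True)
class CalibrationHistogram:
    """Equal-frequency score bins with per-bin pathogenic fraction.

    ``edges`` has ``n_bins + 1`` entries; the outer edges are ∓∞ sentinels
    so any real score falls into a bin.  Bins are half-open [lo, hi).
    """

    edges: np.ndarray
    bin_fraction: np.ndarray
    n_synthetic: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))
        object.__setattr__(self, "bin_fraction", np.asarray(self.bin_fraction, dtype=float))
        if len(self.edges) != len(self.bin_fraction) + 1:
            raise DataError("edges must have one more entry than bin_fraction")
        interior = self.edges[1:-1]
        if np.any(np.diff(interior) <= 0):
            raise DataError("interior edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.bin_fraction)

    def bin_index(self, score) -> np.ndarray:
        idx = np.searchsorted(self.edges, np.asarray(score, dtype=float), side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)

    def lookup(self, score) -> np.ndarray:
        """Pathogenic fraction of the bin(s) containing ``score``."""
        return self.bin_fraction[self.bin_index(score)]

    def to_dict(self) -> dict:
        edges = ["-inf"] + [float(e) for e in self.edges[1:-1]] + ["+inf"]
        return {"edges": edges, "bin_fraction": self.bin_fraction.tolist(),
                "n_synthetic": int(self.n_synthetic)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationHistogram":
        edges = np.array([-np.inf if e == "-inf" else np.inf if e == "+inf" else float(e)
                          for e in d["edges"]])
        return cls(edges, np.asarray(d["bin_fraction"]), int(d["n_synthetic"]))


@dataclass
class CalibrationConfig:
    """All fitting hyperparameters of the calibration pipeline."""

    tree: TreeConfig = field(default_factory=TreeConfig)
    n_fraction: int = 500
    n_gmm: int = 400
    n_components: int = 2
    n_sample: int = 40000
    n_bins: int = 50
    zscore_threshold: float = 4.25
    seed: int = 0

    def __post_init__(self) -> None:
        # a single master seed drives both tree subsampling and node fits
        self.tree.seed = self.seed

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tree"]["partition_attrs"] = list(self.tree.partition_attrs)
        return d


def estimate_fraction(node_labels: Sequence[float], n_p: int = 500,
                      rng: Optional[np.random.Generator] = None
                      ) -> tuple[float, np.ndarray]:
    """Pathogenic fraction from a small random label sample.

    Samples ``n_p`` labels without replacement (all of them when the node is
    smaller) and returns the sample mean together with the sampled positions,
    which the mixture-fitting step reuses to keep the labeled footprint
    minimal.
    """
    y = np.asarray(node_labels, dtype=float)
    if len(y) == 0:
        raise DataError("node has no labels")
    rng = rng or np.random.default_rng()
    if len(y) <= n_p:
        idx = np.arange(len(y))
    else:
        idx = rng.choice(len(y), size=n_p, replace=False)
    return float(y[idx].mean()), idx


def fit_node_gmms(
    node_scores: Sequence[float],
    node_labels: Sequence[float],
    reuse_idx: Optional[np.ndarray] = None,
    n_gmm: int = 400,
    n_components: int = 2,
    seed: Optional[int] = None,
    return_indices: bool = False,
):
    """Fit per-class score mixtures by expectation-maximization.

    ``n_gmm`` scores per class are used (positions in ``reuse_idx`` first,
    topped up at random).  EM uses k-means initialization, one restart,
    tolerance 1e-3 and at most 100 iterations.  A class whose sampled scores
    are all identical degenerates to a near-point component with a warning.
    Returns ``(benign, pathogenic)``.
    """
    x = np.asarray(node_scores, dtype=float)
    y = np.asarray(node_labels, dtype=float)
    rng = np.random.default_rng(seed)
    reuse = np.asarray(reuse_idx, dtype=int) if reuse_idx is not None else np.empty(0, int)

    out = []
    used: list[np.ndarray] = []
    for lab in (0.0, 1.0):
        cls = np.flatnonzero(y == lab)
        if len(cls) < n_gmm:
            raise DataError(
                f"class {int(lab)} has {len(cls)} scores, fewer than n_gmm={n_gmm}")
        head = reuse[y[reuse] == lab] if len(reuse) else np.empty(0, int)
        head = head[:n_gmm]
        if len(head) < n_gmm:
            pool = np.setdiff1d(cls, head, assume_unique=False)
            extra = rng.choice(pool, size=n_gmm - len(head), replace=False)
            chosen = np.concatenate([head, extra])
        else:
            chosen = head
        used.append(chosen)
        sample = x[chosen]
        if np.ptp(sample) == 0:
            warnings.warn(f"class {int(lab)} scores are degenerate; "
                          "falling back to a near-point component", stacklevel=2)
            w = np.zeros(n_components)
            w[0] = 1.0
            out.append(GaussianMixtureParams(
                w, np.full(n_components, sample[0]), np.full(n_components, 1e-12)))
            continue
        gm = GaussianMixture(
            n_components=n_components,
            covariance_type="diag",
            tol=1e-3,
            max_iter=100,
            n_init=1,
            init_params="kmeans",
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(sample.reshape(-1, 1))
        out.append(GaussianMixtureParams(
            gm.weights_.copy(), gm.means_.ravel().copy(),
            gm.covariances_.ravel().copy()))
    if return_indices:
        return out[0], out[1], np.concatenate(used)
    return out[0], out[1]


def equal_frequency_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Interior equal-frequency bin edges at order-statistic midpoints.

    Per-bin counts differ by at most one for distinct values; heavy ties
    spanning an edge can make counts uneven.  Returned edges include the
    ∓∞ sentinels.
    """
    n = len(values)
    if n_bins > n:
        raise DataError(f"n_bins={n_bins} exceeds sample count {n}")
    s = np.sort(np.asarray(values, dtype=float))
    cut = [(k * n) // n_bins for k in range(1, n_bins)]
    interior = np.array([(s[c - 1] + s[c]) / 2.0 for c in cut])
    # collapse duplicate edges caused by ties, then rebuild sentinels
    interior = np.unique(interior)
    return np.concatenate(([-np.inf], interior, [np.inf]))


def build_histogram(
    gmm_benign: GaussianMixtureParams,
    gmm_pathogenic: GaussianMixtureParams,
    fraction: float,
    n_sample: int = 40000,
    n_bins: int = 50,
    rng: Optional[np.random.Generator] = None,
) -> CalibrationHistogram:
    """Build the node's calibration histogram from synthetic mixture draws.

    ``round(n_sample·fraction)`` pathogenic-sourced and the remaining
    benign-sourced samples are drawn, pooled, and split into equal-frequency
    bins; each bin's value is the pathogenic-sourced proportion inside it.
    """
    if not 0.0 <= fraction <= 1.0:
        raise DataError("fraction must lie in [0, 1]")
    rng = rng or np.random.default_rng()
    n_path = int(round(n_sample * fraction))  # banker's rounding
    n_ben = n_sample - n_path
    draws = np.concatenate([
        gmm_pathogenic.sample(n_path, rng),
        gmm_benign.sample(n_ben, rng),
    ])
    is_path = np.concatenate([np.ones(n_path, bool), np.zeros(n_ben, bool)])
    edges = equal_frequency_edges(draws, n_bins)
    idx = np.clip(np.searchsorted(edges, draws, side="right") - 1, 0, len(edges) - 2)
    n_eff = len(edges) - 1
    counts = np.bincount(idx, minlength=n_eff)
    path_counts = np.bincount(idx, weights=is_path, minlength=n_eff)
    with np.errstate(invalid="ignore"):
        frac = np.where(counts > 0, path_counts / np.maximum(counts, 1), 0.0)
    return CalibrationHistogram(edges, frac, n_sample)


@dataclass
class CalibModel:
    """A fitted calibration tree, serializable to JSON."""

    root: CalibTreeNode
    config: CalibrationConfig
    version: str = MODEL_FORMAT_VERSION
    fit_timestamp: str = ""

    # -- inference ---------------------------------------------------------

    def map_variant(self, attrs: Mapping[str, Optional[bool]],
                    score: float) -> tuple[float, tuple]:
        """Calibrated pathogenic probability and the node path used."""
        node = traverse(self.root, attrs)
        if node.histogram is None:
            raise DataError(f"node {node.path} is not calibrated")
        return float(node.histogram.lookup(score)), node.path

    def predict_table(self, table: VariantTable) -> tuple[np.ndarray, list]:
        """Vectorized mapping of a whole table: grouped by terminal node."""
        attrs_used = {a for n in self.root.walk() if n.split_attr
                      for a in (n.split_attr,)}
        cols = {a: table.attribute_values(a) for a in attrs_used
                if a in table.attribute_names}
        scores = table.scores
        n = len(table)
        probs = np.empty(n)
        paths: list = [None] * n

        def descend(node: CalibTreeNode, idx: np.ndarray) -> None:
            a = node.split_attr
            col = cols.get(a) if a is not None else None
            if node.is_leaf() or col is None:
                stop_here, rest = idx, {}
            else:
                vals = col[idx]
                stop_here = idx[~np.isfinite(vals)]
                rest = {}
                for side in (False, True):
                    sub = idx[np.isfinite(vals) & (vals == float(side))]
                    if side in node.children:
                        rest[side] = sub
                    else:
                        stop_here = np.concatenate([stop_here, sub])
            if len(stop_here):
                if node.histogram is None:
                    raise DataError(f"node {node.path} is not calibrated")
                probs[stop_here] = node.histogram.lookup(scores[stop_here])
                for i in stop_here:
                    paths[i] = node.path
            for side, sub in rest.items():
                if len(sub):
                    descend(node.children[side], sub)

        descend(self.root, np.arange(n))
        return probs, paths

    # -- serialization -----------------------------------------------------

    def to_json(self, path=None) -> str:
        nodes = []
        for n in self.root.walk():
            entry = {
                "path": [[a, bool(v)] for a, v in n.path],
                "split_attr": n.split_attr,
                "n_missing_split": int(n.n_missing_split),
                "n_total": int(n.n_total),
                "n_pathogenic": int(n.n_pathogenic),
                "n_benign": int(n.n_benign),
                "fraction": None if n.fraction is None else float(n.fraction),
                "gmm_benign": None if n.gmm_benign is None else n.gmm_benign.to_dict(),
                "gmm_pathogenic": (None if n.gmm_pathogenic is None
                                   else n.gmm_pathogenic.to_dict()),
                "histogram": None if n.histogram is None else n.histogram.to_dict(),
            }
            nodes.append(entry)
        doc = {
            "version": self.version,
            "fit_timestamp": self.fit_timestamp,
            "config": self.config.to_dict(),
            "nodes": nodes,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CalibModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        cfg_d = dict(doc["config"])
        tree_d = dict(cfg_d.pop("tree"))
        tree_d["partition_attrs"] = tuple(tree_d["partition_attrs"])
        cfg = CalibrationConfig(tree=TreeConfig(**tree_d), **cfg_d)
        by_path: dict[tuple, CalibTreeNode] = {}
        for entry in sorted(doc["nodes"], key=lambda e: len(e["path"])):
            path = tuple((a, bool(v)) for a, v in entry["path"])
            node = CalibTreeNode(
                path=path,
                depth=len(path),
                available_attrs=(),
                split_attr=entry["split_attr"],
                n_missing_split=entry["n_missing_split"],
                n_total=entry["n_total"],
                n_pathogenic=entry["n_pathogenic"],
                n_benign=entry["n_benign"],
                fraction=entry["fraction"],
                gmm_benign=(None if entry["gmm_benign"] is None
                            else GaussianMixtureParams.from_dict(entry["gmm_benign"])),
                gmm_pathogenic=(None if entry["gmm_pathogenic"] is None
                                else GaussianMixtureParams.from_dict(entry["gmm_pathogenic"])),
                histogram=(None if entry["histogram"] is None
                           else CalibrationHistogram.from_dict(entry["histogram"])),
            )
            by_path[path] = node
            if path:
                parent = by_path[path[:-1]]
                parent.children[path[-1][1]] = node
        return cls(root=by_path[()], config=cfg,
                   version=doc["version"], fit_timestamp=doc["fit_timestamp"])


def fit_racoon(table: VariantTable, config: Optional[CalibrationConfig] = None,
               timestamp: Optional[str] = None) -> CalibModel:
    """Fit the full residue-aware calibration model.

    Pipeline: pooled modified-z outlier removal → tree construction →
    pruning → per-node fraction estimation, per-class mixture fits and
    calibration histogram.  Every surviving node is calibrated (a superset
    of the nodes inference can stop at), so the mapping step always finds a
    histogram.  Deterministic given ``config.seed``.
    """
    cfg = config or CalibrationConfig()
    if not table.has_labels():
        raise DataError("calibration requires a fully labeled table")

    keep = modified_zscore_filter(table.scores, threshold=cfg.zscore_threshold)
    kept_index = np.flatnonzero(keep)
    fit_table = table.take(kept_index)

    root = build_tree(fit_table, cfg.tree)
    prune_tree(root, cfg.tree)

    labels = fit_table.labels
    scores = fit_table.scores
    for node in root.walk():
        seq = _node_seed(cfg.tree, node.path)
        frac_seq, gmm_seq, hist_seq = seq.spawn(3)
        members = node.member_index
        node_labels = labels[members]
        node_scores = scores[members]
        frac, sample_idx = estimate_fraction(
            node_labels, cfg.n_fraction, np.random.default_rng(frac_seq))
        node.fraction = frac
        node.gmm_benign, node.gmm_pathogenic, train_idx = fit_node_gmms(
            node_scores, node_labels, reuse_idx=sample_idx,
            n_gmm=cfg.n_gmm, n_components=cfg.n_components,
            seed=gmm_seq.generate_state(1)[0], return_indices=True)
        node.histogram = build_histogram(
            node.gmm_benign, node.gmm_pathogenic, frac,
            n_sample=cfg.n_sample, n_bins=cfg.n_bins,
            rng=np.random.default_rng(hist_seq))
        # bookkeeping for leakage diagnostics: which table rows trained the GMMs
        node.fraction_sample_index = kept_index[members[sample_idx]]
        node.gmm_train_index = kept_index[members[train_idx]]

    ts = timestamp if timestamp is not None else (
        datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds"))
    model = CalibModel(root=root, config=cfg, fit_timestamp=ts)
    model.fit_table_index = kept_index
    return model


def leakage_gap(table: VariantTable, config: Optional[CalibrationConfig] = None,
                repeats: int = 20, seed: int = 0) -> tuple[float, float, float]:
    """Seen-vs-held-out AUROC gap of the calibration map.

    For each repeat a model is fitted with a derived seed; the *seen* set is
    the union of the leaf nodes' mixture-training rows, and the *held-out*
    set draws, per leaf, the same number of pathogenic and benign members
    from rows never used in training, so both sides share size and label
    ratio.  Returns ``(mean_seen_auroc, mean_heldout_auroc, |gap|)`` over
    repeats.  Because the calibration map only ever sees mixture summaries,
    the gap should sit within sampling noise of zero.
    """
    from .eval_metrics import auroc  # local import avoids a cycle

    base = config or CalibrationConfig()
    labels = table.labels
    rng = np.random.default_rng(seed)
    seen_vals, out_vals = [], []
    for r in range(repeats):
        cfg = CalibrationConfig(
            tree=TreeConfig(**{**asdict(base.tree),
                               "partition_attrs": base.tree.partition_attrs}),
            n_fraction=base.n_fraction, n_gmm=base.n_gmm,
            n_components=base.n_components, n_sample=base.n_sample,
            n_bins=base.n_bins, zscore_threshold=base.zscore_threshold,
            seed=seed + 1000 * (r + 1))
        model = fit_racoon(table, cfg)
        probs, _ = model.predict_table(table)
        seen_parts, out_parts = [], []
        for leaf in model.root.walk():
            if not leaf.is_leaf():
                continue
            train = np.asarray(leaf.gmm_train_index)
            members = np.asarray(model.fit_table_index)[leaf.member_index]
            unseen = np.setdiff1d(members, train)
            match = []
            for lab in (0.0, 1.0):
                need = int((labels[train] == lab).sum())
                pool = unseen[labels[unseen] == lab]
                match.append(rng.choice(pool, size=min(need, len(pool)),
                                        replace=False))
            seen_parts.append(train)
            out_parts.append(np.concatenate(match))
        seen = np.concatenate(seen_parts)
        out = np.concatenate(out_parts)
        seen_vals.append(auroc(probs[seen], labels[seen]))
        out_vals.append(auroc(probs[out], labels[out]))
    mean_seen = float(np.mean(seen_vals))
    mean_out = float(np.mean(out_vals))
    return mean_seen, mean_out, abs(mean_seen - mean_out)


def ensemble_predict(models: Sequence[CalibModel],
                     attrs: Mapping[str, Optional[bool]],
                     score: float, keep: int = 75) -> tuple[float, float]:
    """Trimmed-ensemble prediction over independently fitted models.

    Per-model probabilities are computed, the central ``keep`` values are
    retained (trimming equally from both tails), and their median and
    standard deviation are returned.
    """
    if keep > len(models):
        raise ParameterError("keep exceeds the number of models")
    probs = np.sort([m.map_variant(attrs, score)[0] for m in models])
    lo = (len(probs) - keep) // 2
    central = probs[lo:lo + keep]
    sd = float(central.std(ddof=1)) if keep > 1 else 0.0
    return float(np.median(central)), sd
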