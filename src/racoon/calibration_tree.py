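"""Attribute-partitioned calibration tree: construction and pruning.

The tree partitions labeled variants by binary residue attributes.  The root
always splits on protein length (long-context proteins are scored through a
sliding window and behave differently), after which each node splits
greedily on the remaining attribute with the largest class-conditional
Jensen–Shannon divergence inside the node, estimated on a seeded per-class
subsample.  Leaves with too few variants of either class are pruned
iteratively; their members remain available in every ancestor, so inference
can always fall back to a coarser subgroup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .data_model import VariantTable
from .exceptions import DataError
from .shift_analysis import conditional_jsd, minmax_to_unit

logger = logging.getLogger(__name__)


@dataclass
class TreeConfig:
    """Structure and pruning hyperparameters of the calibration tree.

    The pruning thresholds (1600 total / 400 pathogenic / 400 benign) ensure
    every surviving subgroup can both fit its mixture models and justify a
    separate calibration map.
    """

    partition_attrs: tuple[str, ...] = ("disordered", "sulfur_binding", "ppi")
    root_attr: str = "long_protein"
    min_total: int = 1600
    min_pos: int = 400
    min_neg: int = 400
    divergence_feature: str = "score"  # "score" | "entropy"
    divergence_bins: int = 100
    subset_per_class: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.min_total, self.min_pos, self.min_neg) <= 0:
            raise DataError("pruning thresholds must be positive")
        if self.root_attr in self.partition_attrs:
            raise DataError("root_attr must not appear in partition_attrs")

    @property
    def all_attrs(self) -> tuple[str, ...]:
        return (self.root_attr, *self.partition_attrs)


@dataclass
class CalibTreeNode:
    """One subgroup of the calibration tree.

    ``path`` is the ordered list of (attribute, value) decisions from the
    root; ``member_index`` indexes rows of the fitted table.  Records whose
    value for ``split_attr`` is missing stay counted here but are excluded
    from both children.  Calibration payloads (fraction, mixtures,
    histogram) are attached by the node-calibration stage.
    """

    path: tuple[tuple[str, bool], ...] = ()
    depth: int = 0
    member_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    available_attrs: tuple[str, ...] = ()
    split_attr: Optional[str] = None
    n_missing_split: int = 0
    children: dict = field(default_factory=dict)  # {True: node, False: node}
    n_total: int = 0
    n_pathogenic: int = 0
    n_benign: int = 0
    fraction: Optional[float] = None
    gmm_benign: Optional[object] = None
    gmm_pathogenic: Optional[object] = None
    histogram: Optional[object] = None

    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        """Yield this node and all descendants, pre-order."""
        yield self
        for v in (False, True):
            if v in self.children:
                yield from self.children[v].walk()

    def __repr__(self) -> str:  # pragma: no cover
        p = "/".join(f"{a}={int(v)}" for a, v in self.path) or "root"
        return f"CalibTreeNode({p}, n={self.n_total})"


def _node_seed(cfg: TreeConfig, path: tuple[tuple[str, bool], ...]) -> np.random.SeedSequence:
    """Deterministic per-node seed derived from the master seed and the path."""
    attrs = cfg.all_attrs
    enc = [cfg.seed]
    for a, v in path:
        enc.extend((attrs.index(a) + 1, int(v)))
    return np.random.SeedSequence(enc)


def _set_counts(node: CalibTreeNode, labels: np.ndarray) -> None:
    lab = labels[node.member_index]
    node.n_total = len(lab)
    node.n_pathogenic = int((lab == 1).sum())
    node.n_benign = int((lab == 0).sum())


def _subset_divergence(
    feature: np.ndarray,
    labels: np.ndarray,
    attr_vals: np.ndarray,
    idx: np.ndarray,
    cfg: TreeConfig,
    rng: np.random.Generator,
) -> Optional[float]:
    """Divergence of an attribute within a node, on a per-class subsample.

    Returns None if any (side, label) cell is empty, in which case the
    attribute cannot be evaluated at this node.
    """
    v = attr_vals[idx]
    known = np.isfinite(v)
    sub_idx = idx[known]
    v = v[known]
    samples = []
    for side in (1.0, 0.0):
        for lab in (1.0, 0.0):
            cell = sub_idx[(v == side) & (labels[sub_idx] == lab)]
            if len(cell) == 0:
                return None
            k = min(cfg.subset_per_class, len(cell))
            samples.append(rng.choice(cell, size=k, replace=False))
    chosen = np.concatenate(samples)
    return conditional_jsd(
        feature[chosen],
        attr_vals[chosen] == 1.0,
        labels[chosen],
        bins=cfg.divergence_bins,
    )


def build_tree(table: VariantTable, cfg: TreeConfig,
               feature: Optional[Sequence[float]] = None) -> CalibTreeNode:
    """Build the (unpruned) calibration tree.

    The root splits on ``cfg.root_attr``; every deeper node splits on the
    available attribute with the largest class-conditional divergence of the
    configured feature (the raw score by default, min–max mapped onto
    [0, 1]; per-variant entropies may be supplied via ``feature``).  Ties
    are broken by the declared attribute order.  Attributes that are never
    observed both true and false for both labels within a node are skipped
    there.
    """
    if not table.has_labels():
        raise DataError("tree construction requires fully labeled data")
    for a in cfg.all_attrs:
        if a not in table.attribute_names:
            raise DataError(f"attribute {a!r} not present in table")

    labels = table.labels
    if feature is not None:
        feat = minmax_to_unit(np.asarray(feature, dtype=float))
    else:
        feat = minmax_to_unit(table.scores)
    attr_cols = {a: table.attribute_values(a) for a in cfg.all_attrs}

    root = CalibTreeNode(
        member_index=np.arange(len(table)),
        available_attrs=tuple(cfg.partition_attrs),
    )
    _set_counts(root, labels)
    _split(root, cfg.root_attr, attr_cols, labels, forced=True)

    frontier = [root.children[v] for v in (False, True) if v in root.children]
    while frontier:
        node = frontier.pop()
        if not node.available_attrs or node.n_total == 0:
            continue
        rng = np.random.default_rng(_node_seed(cfg, node.path))
        best_attr, best_div = None, -np.inf
        for a in node.available_attrs:  # declared order breaks ties
            div = _subset_divergence(feat, labels, attr_cols[a],
                                     node.member_index, cfg, rng)
            if div is None:
                logger.info("attribute %r skipped at node %r (empty cell)", a, node.path)
                continue
            if div > best_div:
                best_attr, best_div = a, div
        if best_attr is None:
            continue
        _split(node, best_attr, attr_cols, labels)
        frontier.extend(node.children[v] for v in (False, True))
    return root


def _split(node: CalibTreeNode, attr: str,
           attr_cols: Mapping[str, np.ndarray], labels: np.ndarray,
           forced: bool = False) -> None:
    vals = attr_cols[attr][node.member_index]
    known = np.isfinite(vals)
    node.split_attr = attr
    node.n_missing_split = int((~known).sum())
    remaining = tuple(a for a in node.available_attrs if a != attr)
    for side in (False, True):
        members = node.member_index[known & (vals == float(side))]
        child = CalibTreeNode(
            path=node.path + ((attr, side),),
            depth=node.depth + 1,
            member_index=members,
            available_attrs=remaining,
        )
        _set_counts(child, labels)
        node.children[side] = child
    if forced and node.n_missing_split:
        logger.info("root attribute %r missing for %d records", attr, node.n_missing_split)


def prune_tree(root: CalibTreeNode, cfg: TreeConfig) -> CalibTreeNode:
    """Iteratively remove undersized leaves until a fixpoint.

    A leaf is removed when it has fewer than ``min_total`` variants,
    ``min_pos`` pathogenic or ``min_neg`` benign ones.  Members of removed
    leaves remain in their ancestors.  A parent whose children are both
    removed becomes a leaf and is itself re-examined on the next sweep.
    """
    def fails(n: CalibTreeNode) -> bool:
        return (n.n_total < cfg.min_total or n.n_pathogenic < cfg.min_pos
                or n.n_benign < cfg.min_neg)

    if fails(root):
        raise DataError(
            f"root node ({root.n_total} variants, {root.n_pathogenic} pathogenic, "
            f"{root.n_benign} benign) is below the pruning thresholds; "
            "nothing can be calibrated")

    changed = True
    while changed:
        changed = False
        # collect (parent, key) pairs for current leaves
        stack = [(None, None, root)]
        while stack:
            parent, key, node = stack.pop()
            if node.is_leaf():
                if parent is not None and fails(node):
                    del parent.children[key]
                    changed = True
            else:
                for v in list(node.children):
                    stack.append((node, v, node.children[v]))
    return root


def calibration_node_set(root: CalibTreeNode) -> list[CalibTreeNode]:
    """Nodes at which inference can terminate.

    These are the leaves, nodes with a single surviving child (the other was
    pruned), and nodes whose split attribute had missing values among their
    members — a variant lacking that attribute stops there.
    """
    out = []
    for n in root.walk():
        if n.is_leaf() or len(n.children) == 1 or n.n_missing_split > 0:
            out.append(n)
    return out


def traverse(root: CalibTreeNode, attrs: Mapping[str, Optional[bool]]) -> CalibTreeNode:
    """Follow a variant's attributes down the tree.

    Traversal stops at a leaf, when the required child was pruned, or when
    the next split attribute is missing from ``attrs``.
    """
    node = root
    while not node.is_leaf():
        a = node.split_attr
        v = attrs.get(a) if a is not None else None
        if a is None or v is None or v not in node.children:
            break
        node = node.children[bool(v)]
    return node
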