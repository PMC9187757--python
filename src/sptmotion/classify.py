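"""Hierarchical threshold-tree classification of trajectories.

Trajectories are assigned to motion populations (e.g. ``immobile`` /
``hybrid`` / ``mobile``) by descending a binary tree that weighs one
descriptor at each branch: go left when the value is less than or equal to
the node threshold, right otherwise.  Trees can be authored by hand (they
serialize to a small JSON document) or trained from a user-labelled
training set by greedy CART induction with Gini impurity.  Complexity is
limited only by a cap on the number of splits — no pruning, no surrogate
splits, equal class weights — which keeps the trees small enough to read
and reason about, the point of tree classifiers in this setting.
"""

from __future__ import annotations

import builtins
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ClassificationError, DataError, SchemaError
from .properties import PropertyTable
from .trajectory_io import TrajectorySet

__all__ = [
    "TreeNode",
    "ClassificationTree",
    "TrainingSet",
    "train_tree",
    "predict",
    "resubstitution_loss",
    "classify_set",
    "save_tree",
    "load_tree",
    "gini_impurity",
]


@dataclass
class TreeNode:
    """A tree node: either an internal threshold test or a labelled leaf."""

    property: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: str | None = None

    # NB: the field named ``property`` shadows the builtin in this class
    # body, so accessors below use ``builtins.property``.
    @builtins.property
    def is_leaf(self) -> bool:
        return self.label is not None

    def validate(self) -> None:
        if self.is_leaf:
            if self.property is not None or self.left or self.right:
                raise SchemaError("leaf node must carry only a label")
            return
        if (
            self.property is None
            or self.threshold is None
            or self.left is None
            or self.right is None
        ):
            raise SchemaError("internal node needs property, threshold, left, right")
        self.left.validate()
        self.right.validate()


@dataclass
class ClassificationTree:
    """Binary threshold tree over property names mapping rows to labels."""

    root: TreeNode

    def __post_init__(self) -> None:
        self.root.validate()

    @property
    def n_splits(self) -> int:
        return sum(1 for n in self._walk() if not n.is_leaf)

    @property
    def properties_used(self) -> set[str]:
        return {n.property for n in self._walk() if not n.is_leaf}

    @property
    def labels(self) -> set[str]:
        return {n.label for n in self._walk() if n.is_leaf}

    def _walk(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.append(node.right)
                stack.append(node.left)


@dataclass
class TrainingSet:
    """User-assigned labels for a subset of trajectories."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.labels = {str(k): str(v) for k, v in self.labels.items()}

    @property
    def ids(self) -> list[str]:
        return list(self.labels)

    @property
    def vocabulary(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_csv(cls, path) -> "TrainingSet":
        df = pd.read_csv(path, dtype=str)
        if not {"id", "label"} <= set(df.columns):
            raise SchemaError("training-set CSV needs columns 'id' and 'label'")
        return cls(dict(zip(df["id"], df["label"])))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"id": list(self.labels), "label": list(self.labels.values())}
        ).to_csv(path, index=False)


def gini_impurity(labels: np.ndarray) -> float:
    """Gini impurity ``1 - sum_c p_c^2`` of a label vector."""
    if len(labels) == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(1.0 - (p * p).sum())


def _majority_label(labels: np.ndarray) -> str:
    vals, counts = np.unique(labels, return_counts=True)
    # ties resolve to the lexicographically smallest label (np.unique sorts)
    return str(vals[np.argmax(counts)])


def _best_split(X: np.ndarray, y: np.ndarray, prop_names: list[str]):
    """Best (gain, property, threshold) over midpoint candidate thresholds.

    The gain is the decrease in Gini impurity summed over the two children,
    weighted by child size, relative to the parent node (not normalized by
    total sample size — callers weight by node size themselves).
    """
    n = len(y)
    classes, y_enc = np.unique(y, return_inverse=True)
    k = len(classes)
    parent_counts = np.bincount(y_enc, minlength=k)
    parent_gini = 1.0 - ((parent_counts / n) ** 2).sum()
    best = None  # (gain, prop_name, threshold)
    for col, name in enumerate(prop_names):
        v = X[:, col]
        order = np.argsort(v, kind="stable")
        vs, ys = v[order], y_enc[order]
        # cumulative class counts after each prefix
        onehot = np.zeros((n, k))
        onehot[np.arange(n), ys] = 1.0
        cum = np.cumsum(onehot, axis=0)
        # candidate split after position i when vs[i] < vs[i+1]
        cut = np.flatnonzero(vs[:-1] < vs[1:])
        if cut.size == 0:
            continue
        nl = cut + 1.0
        nr = n - nl
        cl = cum[cut]
        cr = parent_counts[None, :] - cl
        gini_l = 1.0 - ((cl / nl[:, None]) ** 2).sum(axis=1)
        gini_r = 1.0 - ((cr / nr[:, None]) ** 2).sum(axis=1)
        gain = parent_gini - (nl * gini_l + nr * gini_r) / n
        for i, g in zip(cut, gain):
            thr = 0.5 * (vs[i] + vs[i + 1])
            cand = (float(g), name, float(thr))
            if (
                best is None
                or cand[0] > best[0] + 1e-15
                or (
                    abs(cand[0] - best[0]) <= 1e-15
                    and (cand[1], cand[2]) < (best[1], best[2])
                )
            ):
                best = cand
    return best


def train_tree(
    table: PropertyTable,
    training: TrainingSet,
    max_splits: int = 5,
) -> ClassificationTree:
    """Grow a classification tree by greedy best-first CART induction.

    At each step, among all current impure leaves, the (property,
    threshold) pair that maximally reduces the total size-weighted Gini
    impurity is applied; candidate thresholds are midpoints between
    consecutive distinct sorted values.  Growth stops when ``max_splits``
    internal nodes exist, all leaves are pure, or no split reduces the
    impurity.  Leaf labels are majority votes, ties resolving to the
    lexicographically smallest label.  Equal-gain splits resolve by
    (property name, threshold), making training deterministic.

    Candidate properties are the table columns that are finite for every
    training trajectory.
    """
    if max_splits < 0:
        raise DataError("max_splits must be >= 0")
    missing = [tid for tid in training.ids if tid not in table.index]
    if missing:
        raise DataError(f"training ids absent from property table: {missing[:5]}")
    sub = table.loc[training.ids]
    num = sub.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    finite_cols = np.isfinite(num).all(axis=0)
    prop_names = [c for c, ok in zip(sub.columns, finite_cols) if ok]
    X = num[:, finite_cols]
    y = np.asarray([training.labels[tid] for tid in training.ids])

    if len(training.vocabulary) < 2:
        warnings.warn(
            "training set has a single label; returning a single-leaf tree",
            stacklevel=2,
        )
        return ClassificationTree(TreeNode(label=training.vocabulary[0]))
    if not prop_names:
        raise DataError("no finite-valued property columns available for training")

    root = TreeNode(label=_majority_label(y))
    # leaves as (node, sample index array), in creation order
    leaves: list[tuple[TreeNode, np.ndarray]] = [(root, np.arange(len(y)))]
    n_total = len(y)
    n_splits = 0
    while n_splits < max_splits:
        best_choice = None  # (weighted_gain, prop, thr, leaf_pos)
        for pos, (node, idx) in enumerate(leaves):
            if gini_impurity(y[idx]) == 0.0:
                continue
            cand = _best_split(X[idx], y[idx], prop_names)
            if cand is None or cand[0] <= 0.0:
                continue
            weighted = (len(idx) / n_total) * cand[0]
            key = (weighted, cand[1], cand[2], pos)
            if (
                best_choice is None
                or key[0] > best_choice[0] + 1e-15
                or (
                    abs(key[0] - best_choice[0]) <= 1e-15
                    and key[1:] < best_choice[1:]
                )
            ):
                best_choice = key
        if best_choice is None:
            break
        _, prop, thr, pos = best_choice
        node, idx = leaves.pop(pos)
        col = prop_names.index(prop)
        mask = X[idx, col] <= thr
        li, ri = idx[mask], idx[~mask]
        node.property = prop
        node.threshold = thr
        node.label = None
        node.left = TreeNode(label=_majority_label(y[li]))
        node.right = TreeNode(label=_majority_label(y[ri]))
        leaves.append((node.left, li))
        leaves.append((node.right, ri))
        n_splits += 1
    return ClassificationTree(root)


def predict(tree: ClassificationTree, row: Mapping[str, float] | pd.Series) -> str:
    """Classify one property row by descending the tree (``<=`` goes left)."""
    rid = getattr(row, "name", None)
    node = tree.root
    while not node.is_leaf:
        try:
            value = row[node.property]
        except (KeyError, IndexError):
            raise ClassificationError(
                f"trajectory {rid!r}: property {node.property!r} missing"
            ) from None
        value = float(value)
        if math.isnan(value):
            raise ClassificationError(
                f"trajectory {rid!r}: property {node.property!r} is NaN"
            )
        node = node.left if value <= node.threshold else node.right
    return node.label


def resubstitution_loss(
    tree: ClassificationTree,
    table: PropertyTable,
    training: TrainingSet,
) -> float:
    """Misclassification fraction of the tree on its own training set."""
    missing = [tid for tid in training.ids if tid not in table.index]
    if missing:
        raise DataError(f"training ids absent from property table: {missing[:5]}")
    wrong = sum(
        1
        for tid in training.ids
        if predict(tree, table.loc[tid]) != training.labels[tid]
    )
    return wrong / len(training)


def classify_set(
    tree: ClassificationTree,
    set_: TrajectorySet,
    table: PropertyTable,
) -> TrajectorySet:
    """Assign every trajectory in the set a population label via the tree."""
    missing = [t.id for t in set_.trajectories if t.id not in table.index]
    if missing:
        raise DataError(f"trajectories absent from property table: {missing[:5]}")
    labels = {t.id: predict(tree, table.loc[t.id]) for t in set_.trajectories}
    return set_.with_labels(labels)


def _node_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"label": node.label}
    return {
        "property": node.property,
        "threshold": node.threshold,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d) -> TreeNode:
    if not isinstance(d, dict):
        raise SchemaError(f"tree node must be an object, got {type(d).__name__}")
    if "label" in d:
        if not isinstance(d["label"], str):
            raise SchemaError("leaf label must be a string")
        return TreeNode(label=d["label"])
    try:
        return TreeNode(
            property=str(d["property"]),
            threshold=float(d["threshold"]),
            left=_node_from_dict(d["left"]),
            right=_node_from_dict(d["right"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed tree node: {exc}") from exc


def save_tree(tree: ClassificationTree, path) -> None:
    """Serialize a tree to JSON; thresholds keep full float precision."""
    doc = {"format": "sptmotion-tree", "version": 1, "node": _node_to_dict(tree.root)}
    Path(path).write_text(json.dumps(doc, indent=1))


def load_tree(path) -> ClassificationTree:
    """Load a tree saved by :func:`save_tree` (or authored by hand)."""
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "node" not in doc:
        raise SchemaError("tree JSON must be an object with a 'node' entry")
    return ClassificationTree(_node_from_dict(doc["node"]))
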