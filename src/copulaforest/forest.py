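"""Tree growth, bootstrap forests, weight-based prediction, and
selection-frequency variable importance.

Each tree is grown on a bootstrap multiset of the training rows; at
every node a fresh random subset of ``m`` features is drawn and the
best-gain split taken, until a node falls below ``n_size`` rows or no
candidate improves the cost.  A tree predicts through its leaf weights:
the weight of training row ``i`` at query ``x`` is its multiplicity in
the leaf containing ``x`` divided by the leaf size, and the forest
averages these weights over trees before applying them to the response
matrix — so predictions are convex combinations of training responses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .costs import SplitCriterion, best_split, make_criterion, node_cost
from .dataset import Dataset


@dataclass
class TreeNode:
    """Internal node (feature, threshold, children) or leaf (member rows).

    ``members`` holds original training-row indices with bootstrap
    multiplicity; ``x <= threshold`` descends left.
    """

    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    members: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return self.members is not None

    def locate(self, x: np.ndarray) -> "TreeNode":
        node = self
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node


def grow_tree(
    ds: Dataset,
    rows: np.ndarray,
    crit: SplitCriterion,
    m: int,
    n_size: int,
    rng: np.random.Generator,
    min_child: int = 1,
) -> TreeNode:
    """Recursively grow one tree on a bootstrap multiset of rows.

    A node with fewer than ``n_size`` rows, or whose best candidate has
    non-positive gain (unless ``crit.allow_negative_gain``), becomes a
    leaf.  The ``m``-feature pool is redrawn independently at every node.
    ``min_child > 1`` enforces a minimum leaf size instead of only a
    minimum splittable-node size.
    """
    rows = np.asarray(rows, dtype=np.intp)
    M = ds.n_features
    if not 1 <= m <= M:
        raise ValueError(f"m must be in [1, {M}]")

    def build(node_rows: np.ndarray) -> TreeNode:
        if len(node_rows) < max(n_size, 2 * min_child, 2):
            return TreeNode(members=node_rows)
        pool = rng.choice(M, size=m, replace=False)
        parent = node_cost(ds.Y[node_rows], crit)
        cand = best_split(ds, node_rows, pool, crit, parent_cost=parent, min_child=min_child)
        if cand is None or (cand.gain <= 0 and not crit.allow_negative_gain):
            return TreeNode(members=node_rows)
        return TreeNode(
            feature=cand.feature,
            threshold=cand.threshold,
            left=build(cand.left_rows),
            right=build(cand.right_rows),
        )

    return build(rows)


@dataclass
class Forest:
    """An ensemble of T trees plus the bootstrap record and hyperparameters."""

    trees: list[TreeNode]
    bootstrap_rows: list[np.ndarray]
    params: dict = field(default_factory=dict)
    n_train: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def build_forest(
    ds: Dataset,
    crit: SplitCriterion | str,
    T: int = 150,
    m: int = 10,
    n_size: int = 5,
    bootstrap_frac: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    alpha: float = 1.0,
    grid_resolution: int = 10,
    allow_negative_gain: bool = True,
    min_child: int = 1,
) -> Forest:
    """Grow ``T`` trees on independent bootstrap draws of
    ``ceil(bootstrap_frac * n)`` rows with replacement.

    ``crit`` may be a prepared :class:`SplitCriterion` or one of
    ``{"sse", "mahalanobis", "copula"}``, in which case root statistics
    are computed from ``ds.Y`` here.  The seed feeds a SeedSequence
    whose per-tree substreams drive bootstrap and feature draws, so
    growing more trees never reshuffles earlier ones.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0 < bootstrap_frac <= 1:
        raise ValueError("bootstrap_frac must be in (0, 1]")
    if isinstance(crit, str):
        crit = make_criterion(
            crit, ds.Y, alpha=alpha, grid_resolution=grid_resolution,
            allow_negative_gain=allow_negative_gain,
        )
    m = min(m, ds.n_features)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_boot = int(np.ceil(bootstrap_frac * ds.n))
    trees, boots = [], []
    for child in ss.spawn(T):
        rng = np.random.Generator(np.random.PCG64(child))
        rows = rng.choice(ds.n, size=n_boot, replace=True)
        trees.append(grow_tree(ds, rows, crit, m=m, n_size=n_size, rng=rng, min_child=min_child))
        boots.append(rows)
    params = {
        "T": T, "m": m, "n_size": n_size, "min_child": min_child,
        "bootstrap_frac": bootstrap_frac,
        "criterion": crit.kind, "alpha": crit.alpha,
        "grid_resolution": crit.grid_resolution,
        "allow_negative_gain": crit.allow_negative_gain,
    }
    return Forest(trees=trees, bootstrap_rows=boots, params=params, n_train=ds.n)


def tree_weights(x: np.ndarray, tree: TreeNode, n_train: int) -> np.ndarray:
    """Per-training-row prediction weights of one tree at query ``x``:
    leaf multiplicity of each row over the leaf size.  Sums to 1; rows
    outside the tree's bootstrap sample get weight 0."""
    leaf = tree.locate(np.asarray(x, dtype=float))
    w = np.bincount(leaf.members, minlength=n_train).astype(float)
    return w / len(leaf.members)


def forest_weights(x: np.ndarray, forest: Forest) -> np.ndarray:
    """Forest weights: the average of per-tree weights (a convex combination)."""
    w = np.zeros(forest.n_train)
    for tree in forest.trees:
        w += tree_weights(x, tree, forest.n_train)
    return w / forest.n_trees


def forest_predict(X_test: np.ndarray, forest: Forest, Y: np.ndarray) -> np.ndarray:
    """Predict responses for query rows by applying the averaged weights
    to the training responses (equivalently: the mean over trees of the
    containing leaf's mean response)."""
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    out = np.empty((X_test.shape[0], Y.shape[1]))
    for i, x in enumerate(X_test):
        out[i] = forest_weights(x, forest) @ Y
    return out


def variable_importance(forest: Forest, n_features: int | None = None) -> np.ndarray:
    """Selection-frequency importance: how often each feature is chosen
    for a split, summed over all trees and normalised to sum to 1.
    A forest of pure stumps yields the zero vector (with a warning)."""
    if n_features is None:
        n_features = max(_max_feature(t) for t in forest.trees) + 1
    counts = np.zeros(max(n_features, 1))

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        counts[node.feature] += 1
        walk(node.left)
        walk(node.right)

    for tree in forest.trees:
        walk(tree)
    total = counts.sum()
    if total == 0:
        import warnings

        warnings.warn("forest contains no splits; importance is the zero vector")
        return counts
    return counts / total


def _max_feature(node: TreeNode) -> int:
    if node.is_leaf:
        return -1
    return max(node.feature, _max_feature(node.left), _max_feature(node.right))


# ---------------------------------------------------------------------------
# JSON persistence (self-describing, diffable)


def _node_to_obj(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"members": [int(i) for i in node.members]}
    return {
        "feature": int(node.feature),
        "threshold": float(node.threshold),
        "left": _node_to_obj(node.left),
        "right": _node_to_obj(node.right),
    }


def _node_from_obj(obj: dict) -> TreeNode:
    if "members" in obj:
        return TreeNode(members=np.asarray(obj["members"], dtype=np.intp))
    return TreeNode(
        feature=obj["feature"],
        threshold=obj["threshold"],
        left=_node_from_obj(obj["left"]),
        right=_node_from_obj(obj["right"]),
    )


def forest_to_json(forest: Forest, Y_train: np.ndarray | None = None,
                   extra: dict | None = None) -> str:
    """Serialise a forest (and optionally its training responses, which
    make the document a self-contained predictor) to JSON text."""
    doc = {
        "format": "copulaforest-model",
        "version": 1,
        "params": forest.params,
        "n_train": forest.n_train,
        "trees": [
            {"bootstrap_rows": [int(i) for i in b], "root": _node_to_obj(t)}
            for t, b in zip(forest.trees, forest.bootstrap_rows)
        ],
    }
    if Y_train is not None:
        doc["Y_train"] = np.asarray(Y_train, dtype=float).tolist()
    if extra:
        doc.update(extra)
    return json.dumps(doc, indent=1, sort_keys=True)


def forest_from_json(text: str) -> tuple[Forest, np.ndarray | None]:
    """Inverse of :func:`forest_to_json`; returns (forest, Y_train or None)."""
    doc = json.loads(text)
    if doc.get("format") != "copulaforest-model":
        raise ValueError("not a copulaforest model document")
    forest = Forest(
        trees=[_node_from_obj(t["root"]) for t in doc["trees"]],
        bootstrap_rows=[np.asarray(t["bootstrap_rows"], dtype=np.intp) for t in doc["trees"]],
        params=doc["params"],
        n_train=doc["n_train"],
    )
    Y = np.asarray(doc["Y_train"], dtype=float) if "Y_train" in doc else None
    return forest, Y
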