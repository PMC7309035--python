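"""Gini decision tree over register feature vectors, rule export, evaluation.

The tree is a plain CART-style greedy learner: at each node every
(feature, threshold) candidate is scored by the size-weighted Gini impurity
of the two children, with thresholds at midpoints between consecutive
distinct feature values.  Ties among equal-score splits break
deterministically (lowest feature index, then lowest threshold) unless a seed
is given, in which case one of the tied splits is drawn uniformly — repeated
fits that vary only the seed therefore explore exactly the tie structure of
the feature table.

The tree is deliberately written out rather than wrapped around a library
estimator so that tie-break semantics, rule export and the exhaustive-search
equivalence used in tests are pinned by this module alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import (
    auc,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_curve,
)

from .data import ClassLabel, N_CLASSES
from .features import FEATURE_NAMES

__all__ = [
    "TreeConfig",
    "TreeNode",
    "TreeModel",
    "EvalReport",
    "gini_impurity",
    "fit_tree",
    "predict",
    "export_rules",
    "apply_rules",
    "tree_to_json",
    "tree_from_json",
    "evaluate",
    "repeated_fit_report",
]


@dataclass(frozen=True)
class TreeConfig:
    """Decision-tree settings; the split criterion is Gini impurity, always."""

    max_depth: int | None = 4
    min_samples_leaf: int = 1
    seed: int | None = None
    n_repeats: int = 100

    def __post_init__(self) -> None:
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def gini_impurity(class_counts) -> float:
    """Gini impurity 1 - sum((c_k / n)^2) of a node's class counts."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("class counts are all zero")
    p = counts / n
    return float(1.0 - np.sum(p * p))


@dataclass
class TreeNode:
    counts: np.ndarray  # class counts of the training rows reaching this node
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def label(self) -> int:
        return int(np.argmax(self.counts))  # ties -> lowest class index


@dataclass
class TreeModel:
    root: TreeNode
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))


def _counts(y: np.ndarray) -> np.ndarray:
    return np.bincount(y, minlength=N_CLASSES).astype(np.float64)


def _best_split(x: np.ndarray, y: np.ndarray, min_leaf: int,
                rng: np.random.Generator | None):
    """Best (feature index, threshold) by weighted child Gini; None if no split.

    All candidates within 1e-12 of the best score are collected; the winner is
    the first in (feature, threshold) order, or a uniform draw when rng given.
    """
    n, n_feat = x.shape
    parent = gini_impurity(_counts(y))
    best_score = np.inf
    ties: list[tuple[int, float]] = []
    for j in range(n_feat):
        order = np.argsort(x[:, j], kind="stable")
        xs, ys = x[order, j], y[order]
        left_counts = np.zeros(N_CLASSES)
        right_counts = _counts(ys)
        for i in range(n - 1):
            left_counts[ys[i]] += 1
            right_counts[ys[i]] -= 1
            if xs[i] == xs[i + 1]:
                continue
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            score = (
                n_left * gini_impurity(left_counts)
                + n_right * gini_impurity(right_counts)
            ) / n
            threshold = (xs[i] + xs[i + 1]) / 2.0
            if score < best_score - 1e-12:
                best_score = score
                ties = [(j, threshold)]
            elif score <= best_score + 1e-12:
                ties.append((j, threshold))
    if not ties or best_score >= parent - 1e-12:
        return None
    if rng is not None and len(ties) > 1:
        return ties[int(rng.integers(len(ties)))]
    return ties[0]


def _grow(x, y, depth, cfg: TreeConfig, rng) -> TreeNode:
    node = TreeNode(counts=_counts(y))
    if (cfg.max_depth is not None and depth >= cfg.max_depth) or len(np.unique(y)) == 1:
        return node
    split = _best_split(x, y, cfg.min_samples_leaf, rng)
    if split is None:
        return node
    j, threshold = split
    mask = x[:, j] <= threshold
    node.feature = FEATURE_NAMES[j]
    node.threshold = float(threshold)
    node.left = _grow(x[mask], y[mask], depth + 1, cfg, rng)
    node.right = _grow(x[~mask], y[~mask], depth + 1, cfg, rng)
    return node


def _table_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise KeyError(f"feature table lacks canonical columns: {missing}")
    x = table[FEATURE_NAMES].to_numpy(dtype=np.float64)
    y = np.array([int(ClassLabel.from_string(s)) for s in table["true_label"]])
    return x, y


def fit_tree(table: pd.DataFrame, cfg: TreeConfig | None = None) -> TreeModel:
    """Greedy Gini tree on a register feature table.

    A single-class table yields a degenerate single-leaf tree with a warning.
    """
    cfg = cfg or TreeConfig()
    x, y = _table_xy(table)
    if len(np.unique(y)) < 2:
        warnings.warn("feature table has a single class; fitting a one-leaf tree",
                      stacklevel=2)
    rng = None if cfg.seed is None else np.random.default_rng(cfg.seed)
    return TreeModel(root=_grow(x, y, 0, cfg, rng))


def predict(model: TreeModel, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Root-to-leaf descent; returns (labels, leaf class proportions).

    Leaf proportions are the class mix of the training registers that reached
    the leaf and serve as prediction scores (e.g. for ROC curves).
    """
    missing = [c for c in model.feature_names if c not in table.columns]
    if missing:
        raise KeyError(f"feature table lacks canonical columns: {missing}")
    x = table[model.feature_names].to_numpy(dtype=np.float64)
    col = {name: k for k, name in enumerate(model.feature_names)}
    labels = np.empty(len(x), dtype=np.int64)
    scores = np.empty((len(x), N_CLASSES))
    for i, row in enumerate(x):
        node = model.root
        while not node.is_leaf:
            node = node.left if row[col[node.feature]] <= node.threshold else node.right
        labels[i] = node.label
        scores[i] = node.proportions
    return labels, scores


def export_rules(model: TreeModel) -> list[str]:
    """One IF-THEN line per leaf (full-precision thresholds, so the rule
    interpreter in :func:`apply_rules` reproduces :func:`predict` exactly)."""
    rules: list[str] = []

    def descend(node: TreeNode, conditions: list[str]) -> None:
        if node.is_leaf:
            counts = ", ".join(
                f"{c.name}={int(node.counts[int(c)])}" for c in ClassLabel
            )
            cond = " AND ".join(conditions) if conditions else "TRUE"
            rules.append(
                f"IF {cond} THEN class={ClassLabel(node.label).name} [{counts}]"
            )
            return
        descend(node.left, conditions + [f"{node.feature} <= {node.threshold!r}"])
        descend(node.right, conditions + [f"{node.feature} > {node.threshold!r}"])

    descend(model.root, [])
    return rules


def apply_rules(rules: list[str], table: pd.DataFrame) -> np.ndarray:
    """Independent rule interpreter: evaluate the exported IF-THEN list."""
    parsed = []
    for rule in rules:
        body, _, tail = rule.partition(" THEN class=")
        label = ClassLabel.from_string(tail.split(" ")[0])
        cond_text = body[len("IF "):]
        conditions = []
        if cond_text != "TRUE":
            for clause in cond_text.split(" AND "):
                if " <= " in clause:
                    name, value = clause.split(" <= ")
                    conditions.append((name, "<=", float(value)))
                else:
                    name, value = clause.split(" > ")
                    conditions.append((name, ">", float(value)))
        parsed.append((conditions, int(label)))
    out = np.empty(len(table), dtype=np.int64)
    for i, (_, row) in enumerate(table.iterrows()):
        for conditions, label in parsed:
            if all(
                (row[name] <= v) if op == "<=" else (row[name] > v)
                for name, op, v in conditions
            ):
                out[i] = label
                break
        else:  # pragma: no cover - leaves partition the feature space
            raise RuntimeError("no rule matched; exported rules are not exhaustive")
    return out


def tree_to_json(model: TreeModel, path=None) -> str:
    """Machine-readable tree: nested nodes with feature, threshold, counts."""

    def node_dict(node: TreeNode) -> dict:
        d: dict = {"counts": [int(c) for c in node.counts]}
        if not node.is_leaf:
            d.update(
                feature=node.feature,
                threshold=node.threshold,
                left=node_dict(node.left),
                right=node_dict(node.right),
            )
        else:
            d["class"] = ClassLabel(node.label).name
        return d

    text = json.dumps({"criterion": "gini", "root": node_dict(model.root)}, indent=2)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def tree_from_json(source) -> TreeModel:
    """Inverse of :func:`tree_to_json` (accepts a path or a JSON string)."""
    text = source if str(source).lstrip().startswith("{") else Path(source).read_text()
    data = json.loads(text)

    def node_from(d: dict) -> TreeNode:
        node = TreeNode(counts=np.asarray(d["counts"], dtype=np.float64))
        if "feature" in d:
            node.feature = d["feature"]
            node.threshold = float(d["threshold"])
            node.left = node_from(d["left"])
            node.right = node_from(d["right"])
        return node

    return TreeModel(root=node_from(data["root"]))


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvalReport:
    accuracy: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    confusion: np.ndarray  # rows = truth, columns = prediction, class order C,P,S
    roc: dict  # per-class / micro / macro: {fpr, tpr, auc}; absent class -> None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision_weighted": self.precision_weighted,
            "recall_weighted": self.recall_weighted,
            "f1_weighted": self.f1_weighted,
            "confusion": self.confusion.tolist(),
            "roc_auc": {
                k: (None if v is None else v["auc"]) for k, v in self.roc.items()
            },
        }


def evaluate(predictions, scores, true_labels) -> EvalReport:
    """Accuracy, weighted precision/recall/F1, confusion matrix and ROC curves.

    ROC is one-vs-rest per class using the score column of that class, with a
    micro-average over pooled decisions and a macro-average over the defined
    per-class curves.  A class absent from the truth has no ROC and is
    excluded from the macro average with a warning.
    """
    y_true = np.asarray(true_labels, dtype=np.int64)
    y_pred = np.asarray(predictions, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if not (len(y_true) == len(y_pred) == len(scores)):
        raise ValueError("predictions, scores and true_labels must align")
    classes = list(range(N_CLASSES))
    accuracy = float((y_true == y_pred).mean())
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="weighted", zero_division=0
    )
    conf = confusion_matrix(y_true, y_pred, labels=classes)
    y_bin = np.zeros((len(y_true), N_CLASSES))
    y_bin[np.arange(len(y_true)), y_true] = 1.0
    roc: dict = {}
    defined = []
    for c in ClassLabel:
        k = int(c)
        if y_bin[:, k].sum() in (0, len(y_true)):
            warnings.warn(f"class {c.name} absent from truth; its ROC is undefined",
                          stacklevel=2)
            roc[c.name] = None
            continue
        fpr, tpr, _ = roc_curve(y_bin[:, k], scores[:, k])
        roc[c.name] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}
        defined.append(c.name)
    fpr_mi, tpr_mi, _ = roc_curve(y_bin.ravel(), scores.ravel())
    roc["micro"] = {"fpr": fpr_mi, "tpr": tpr_mi, "auc": float(auc(fpr_mi, tpr_mi))}
    if defined:
        grid = np.unique(np.concatenate([roc[name]["fpr"] for name in defined]))
        mean_tpr = np.mean(
            [np.interp(grid, roc[name]["fpr"], roc[name]["tpr"]) for name in defined],
            axis=0,
        )
        roc["macro"] = {"fpr": grid, "tpr": mean_tpr, "auc": float(auc(grid, mean_tpr))}
    else:
        roc["macro"] = None
    return EvalReport(
        accuracy=accuracy,
        precision_weighted=float(precision),
        recall_weighted=float(recall),
        f1_weighted=float(f1),
        confusion=conf,
        roc=roc,
    )


def repeated_fit_report(train_table: pd.DataFrame, test_table: pd.DataFrame,
                        cfg: TreeConfig | None = None) -> dict:
    """Fit the tree ``n_repeats`` times varying only the seed; summarize test
    accuracy as mean / sd (population) / min / max."""
    cfg = cfg or TreeConfig()
    base_seed = 0 if cfg.seed is None else cfg.seed
    _, y_test = _table_xy(test_table)
    accuracies = []
    for r in range(cfg.n_repeats):
        run_cfg = TreeConfig(max_depth=cfg.max_depth,
                             min_samples_leaf=cfg.min_samples_leaf,
                             seed=base_seed + r, n_repeats=1)
        model = fit_tree(train_table, run_cfg)
        labels, _ = predict(model, test_table)
        accuracies.append(float((labels == y_test).mean()))
    acc = np.asarray(accuracies)
    return {
        "mean": float(acc.mean()),
        "sd": float(acc.std()),
        "min": float(acc.min()),
        "max": float(acc.max()),
        "accuracies": accuracies,
    }
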