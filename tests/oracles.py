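"""Independent brute-force oracles used by the tests.

Each oracle recomputes a quantity by the most naive route available (explicit
loops, exhaustive enumeration) and stays independent of the library code it
checks.
"""

from __future__ import annotations

import numpy as np


def naive_ensemble_probabilities(tensor: np.ndarray) -> np.ndarray:
    """Two-loop mean over the run axis."""
    n_runs, n_sacc, n_cls = tensor.shape
    out = np.zeros((n_sacc, n_cls))
    for i in range(n_sacc):
        for k in range(n_cls):
            total = 0.0
            for r in range(n_runs):
                total += tensor[r, i, k]
            out[i, k] = total / n_runs
    return out


def naive_per_run_accuracies(tensor: np.ndarray, truths) -> tuple[np.ndarray, float]:
    n_runs, n_sacc, _ = tensor.shape
    accs = np.zeros(n_runs)
    for r in range(n_runs):
        hits = 0
        for i in range(n_sacc):
            row = tensor[r, i]
            best = 0
            for k in range(1, len(row)):
                if row[k] > row[best]:
                    best = k
            hits += best == truths[i]
        accs[r] = hits / n_sacc
    return accs, float(accs.mean())


def naive_register_features(labels, mean_probs, impute=0.0) -> np.ndarray:
    """Per-group cardinal/mean/population-std, computed with explicit loops."""
    labels = np.asarray(labels)
    mean_probs = np.asarray(mean_probs, dtype=float)
    cards, means, stds = [], [], []
    for x in range(3):
        idx = [i for i in range(len(labels)) if labels[i] == x]
        cards.append(len(idx))
        for y in range(3):
            if not idx:
                means.append(impute)
            else:
                means.append(sum(mean_probs[i, y] for i in idx) / len(idx))
    for x in range(3):
        idx = [i for i in range(len(labels)) if labels[i] == x]
        for y in range(3):
            if not idx:
                stds.append(impute)
            else:
                mu = sum(mean_probs[i, y] for i in idx) / len(idx)
                var = sum((mean_probs[i, y] - mu) ** 2 for i in idx) / len(idx)
                stds.append(np.sqrt(var))
    return np.array(cards + means + stds, dtype=float)


def gini_by_simulation_free_enumeration(counts) -> float:
    """Gini = probability that two independent draws (with replacement) from
    the node's class distribution disagree."""
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    prob_disagree = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            if i != j:
                prob_disagree += p[i] * p[j]
    return prob_disagree


def _gini(counts) -> float:
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    return 1.0 - float((p * p).sum())


def exhaustive_best_split(x: np.ndarray, y: np.ndarray, min_leaf: int = 1):
    """Enumerate every (feature, midpoint threshold); return the split with the
    smallest weighted child Gini (ties: lowest feature, then lowest threshold),
    or None when no split improves on the parent."""
    n, n_feat = x.shape
    parent = _gini(np.bincount(y, minlength=3))
    candidates = []
    for j in range(n_feat):
        values = np.unique(x[:, j])
        for a, b in zip(values[:-1], values[1:]):
            thr = (a + b) / 2.0
            mask = x[:, j] <= thr
            nl, nr = int(mask.sum()), int((~mask).sum())
            if nl < min_leaf or nr < min_leaf:
                continue
            score = (
                nl * _gini(np.bincount(y[mask], minlength=3))
                + nr * _gini(np.bincount(y[~mask], minlength=3))
            ) / n
            candidates.append((score, j, thr))
    if not candidates:
        return None
    best = min(c[0] for c in candidates)
    if best >= parent - 1e-12:
        return None
    tied = sorted((j, t) for s, j, t in candidates if s <= best + 1e-12)
    return tied[0]


def exhaustive_greedy_tree(x: np.ndarray, y: np.ndarray, max_depth: int,
                           min_leaf: int = 1) -> dict:
    """Greedy tree by exhaustive split search; nested-dict representation."""
    node: dict = {"counts": np.bincount(y, minlength=3).tolist()}
    if max_depth == 0 or len(np.unique(y)) == 1:
        return node
    split = exhaustive_best_split(x, y, min_leaf)
    if split is None:
        return node
    j, thr = split
    mask = x[:, j] <= thr
    node["feature"] = j
    node["threshold"] = thr
    node["left"] = exhaustive_greedy_tree(x[mask], y[mask], max_depth - 1, min_leaf)
    node["right"] = exhaustive_greedy_tree(x[~mask], y[~mask], max_depth - 1, min_leaf)
    return node
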