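"""Register-level uncertainty features from MCD-ensemble saccade predictions.

Within one register the saccades are partitioned into three *prediction
groups* by their ensemble label (Cpred, Ppred, Spred).  For every group X and
every class Y the mean and population standard deviation of the group
members' ensemble probability for Y are computed.  Together with the three
group cardinals this yields the fixed 21-feature register vector::

    card_C, card_P, card_S,
    mean_C_C, mean_C_P, mean_C_S, mean_P_C, ..., mean_S_S,
    std_C_C,  std_C_P,  std_C_S,  std_P_C,  ..., std_S_S

A group with no saccades has cardinal 0 and all six of its statistics imputed
(default 0.0, which no softmax mean over a non-empty group can attain, so the
imputation is unambiguous; -1.0 is available as an alternative).

The module also provides the majority-vote baseline: a register labeled by
the class of the majority of its saccades.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import ClassLabel, N_CLASSES
from .mcd import EnsembleResult

__all__ = [
    "FEATURE_NAMES",
    "group_by_prediction",
    "register_feature_vector",
    "build_feature_table",
    "majority_vote_label",
    "write_feature_table",
    "read_feature_table",
]

_CLASSES = [c.name for c in ClassLabel]

FEATURE_NAMES: list[str] = (
    [f"card_{x}" for x in _CLASSES]
    + [f"mean_{x}_{y}" for x in _CLASSES for y in _CLASSES]
    + [f"std_{x}_{y}" for x in _CLASSES for y in _CLASSES]
)


def group_by_prediction(labels) -> dict[ClassLabel, np.ndarray]:
    """Partition saccade indices by predicted class; empty groups permitted."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.ndim != 1 or labels.shape[0] < 1:
        raise ValueError("need at least one predicted label")
    if labels.min() < 0 or labels.max() >= N_CLASSES:
        raise ValueError("labels must be class codes 0..2")
    return {c: np.flatnonzero(labels == int(c)) for c in ClassLabel}


def register_feature_vector(labels, mean_probs, impute: float = 0.0) -> np.ndarray:
    """The 21-entry feature vector of one register.

    Parameters
    ----------
    labels
        Ensemble labels of the register's saccades (length n).
    mean_probs
        Ensemble mean probabilities, shape (n, 3), class order C, P, S.
    impute
        Value used for the six statistics of an empty prediction group.
    """
    mean_probs = np.asarray(mean_probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if mean_probs.ndim != 2 or mean_probs.shape[1] != N_CLASSES:
        raise ValueError(f"mean_probs must be (n, {N_CLASSES}), got {mean_probs.shape}")
    if labels.shape[0] != mean_probs.shape[0]:
        raise ValueError("labels and mean_probs disagree on saccade count")
    groups = group_by_prediction(labels)
    cards = np.array([len(groups[c]) for c in ClassLabel], dtype=np.float64)
    means = np.full((N_CLASSES, N_CLASSES), impute, dtype=np.float64)
    stds = np.full((N_CLASSES, N_CLASSES), impute, dtype=np.float64)
    for x in ClassLabel:
        idx = groups[x]
        if len(idx):
            sub = mean_probs[idx]
            means[int(x)] = sub.mean(axis=0)
            stds[int(x)] = sub.std(axis=0)  # population std: singleton -> 0
    return np.concatenate([cards, means.ravel(), stds.ravel()])


def majority_vote_label(labels) -> ClassLabel:
    """Register label = class of the majority of its saccades; ties -> lowest index."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape[0] < 1:
        raise ValueError("need at least one saccade label")
    counts = np.bincount(labels, minlength=N_CLASSES)
    return ClassLabel(int(np.argmax(counts)))


def build_feature_table(per_register: dict[str, tuple[EnsembleResult, ClassLabel]],
                        impute: float = 0.0) -> pd.DataFrame:
    """One 21-feature row per register, ordered by register_id.

    ``per_register`` maps register_id -> (ensemble result restricted to that
    register's saccades, true label).  The returned frame has columns
    register_id, true_label, then FEATURE_NAMES; the imputation policy is
    recorded in ``frame.attrs['impute']``.
    """
    if not per_register:
        raise ValueError("need at least one register")
    rows = []
    for rid in sorted(per_register):
        ens, truth = per_register[rid]
        vec = register_feature_vector(ens.labels, ens.mean_probs, impute=impute)
        rows.append([rid, ClassLabel(truth).name, *vec])
    frame = pd.DataFrame(rows, columns=["register_id", "true_label", *FEATURE_NAMES])
    for c in ("card_C", "card_P", "card_S"):
        frame[c] = frame[c].astype(np.int64)
    frame.attrs["impute"] = impute
    return frame


def write_feature_table(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_feature_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    expected = ["register_id", "true_label", *FEATURE_NAMES]
    if list(frame.columns) != expected:
        raise ValueError(f"feature table columns do not match the 23-column schema")
    return frame
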