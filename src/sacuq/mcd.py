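"""Monte Carlo dropout inference at the saccade level.

Running the dropout-active network N times over a set of saccades yields an
N x n_saccades x 3 probability tensor.  From it two summaries are computed:

* per-run accuracies and their mean (``MCDaccmean``): each run labels every
  saccade by the argmax of its own probability row;
* the MCD ensemble (``MCDE``): per-saccade probabilities averaged over the N
  runs, labels as the argmax of the averages, and the resulting ensemble
  accuracy (``MCDEacc``).

Argmax ties break toward the lowest class index (C before P before S).
Accuracies pool all saccades of the evaluated split.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import ClassLabel, N_CLASSES
from .net import SaccadeNet, stochastic_forward

__all__ = [
    "McdRunSummary",
    "EnsembleResult",
    "run_mcd",
    "per_run_accuracies",
    "ensemble_probabilities",
    "label_from_probabilities",
    "labels_from_probabilities",
    "ensemble_accuracy",
    "ensemble_from_tensor",
    "McdStreamingAccumulator",
    "export_ensemble_tsv",
]

_SIMPLEX_ATOL = 1e-5


def _check_tensor(tensor: np.ndarray) -> np.ndarray:
    tensor = np.asarray(tensor, dtype=np.float64)
    if tensor.ndim != 3 or tensor.shape[2] != N_CLASSES:
        raise ValueError(
            f"expected (N, n_saccades, {N_CLASSES}) tensor, got shape {tensor.shape}"
        )
    sums = tensor.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=_SIMPLEX_ATOL):
        raise ValueError("tensor rows must each sum to 1 (probability simplex)")
    return tensor


@dataclass
class McdRunSummary:
    """Per-run accuracies over the N MCD passes and their arithmetic mean."""

    per_run_accuracy: np.ndarray
    mean_accuracy: float


@dataclass
class EnsembleResult:
    """MCD-ensemble per-saccade mean probabilities, labels and accuracy."""

    mean_probs: np.ndarray  # (n_saccades, 3), class order C, P, S
    labels: np.ndarray  # (n_saccades,) integer class codes
    ensemble_accuracy: float | None = None


def run_mcd(model: SaccadeNet, saccades, n_passes: int, seed: int = 0,
            batch_size: int = 512) -> np.ndarray:
    """N stochastic forward passes -> (N, n_saccades, 3) probability tensor.

    Dropout is the only stochastic layer and sits above the conv+LSTM trunk,
    so the trunk features are computed once and each pass draws only a fresh
    dropout mask over them; the result is identical to N full dropout-active
    forward passes.  With dropout rate 0 all N slices are identical.
    """
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    if not model.trained:
        raise RuntimeError("model is untrained; call train() first")
    x = np.asarray(saccades, dtype=model.dtype)
    if x.ndim == 1:
        x = x[None, :]
    rng = np.random.default_rng(seed)
    feats = np.concatenate(
        [model.features(x[i : i + batch_size]) for i in range(0, x.shape[0], batch_size)],
        axis=0,
    ) if x.shape[0] else np.empty((0, model.cfg.lstm_units), dtype=model.dtype)
    tensor = np.empty((n_passes, x.shape[0], model.cfg.n_classes), dtype=np.float64)
    for r in range(n_passes):
        tensor[r] = model.head(feats, rng=rng, dropout_active=True)
    return tensor


def label_from_probabilities(p) -> ClassLabel:
    """Argmax label of one probability vector; ties -> lowest class index."""
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (N_CLASSES,) or not np.isclose(p.sum(), 1.0, atol=_SIMPLEX_ATOL) \
            or np.any(p < -_SIMPLEX_ATOL):
        raise ValueError(f"not a {N_CLASSES}-class probability vector: {p}")
    return ClassLabel(int(np.argmax(p)))


def labels_from_probabilities(probs: np.ndarray) -> np.ndarray:
    """Row-wise argmax labels; np.argmax already breaks ties to the lowest index."""
    return np.argmax(probs, axis=-1)


def per_run_accuracies(tensor: np.ndarray, true_labels) -> McdRunSummary:
    """Accuracy of each MCD run against the truth, plus the mean over runs."""
    tensor = _check_tensor(tensor)
    true_labels = np.asarray(true_labels, dtype=np.int64)
    if true_labels.shape[0] != tensor.shape[1]:
        raise ValueError(
            f"{true_labels.shape[0]} labels for {tensor.shape[1]} saccades"
        )
    run_labels = labels_from_probabilities(tensor)  # (N, n)
    acc = (run_labels == true_labels[None, :]).mean(axis=1)
    return McdRunSummary(per_run_accuracy=acc, mean_accuracy=float(acc.mean()))


def ensemble_probabilities(tensor: np.ndarray) -> np.ndarray:
    """Per-saccade mean probabilities over the run axis; rows stay on the simplex."""
    tensor = _check_tensor(tensor)
    return tensor.mean(axis=0)


def ensemble_accuracy(labels: np.ndarray, true_labels) -> float:
    true_labels = np.asarray(true_labels, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape != true_labels.shape:
        raise ValueError("label arrays have different lengths")
    return float((labels == true_labels).mean())


def ensemble_from_tensor(tensor: np.ndarray, true_labels=None) -> EnsembleResult:
    """The full MCD-ensemble computation from a run tensor."""
    mean_probs = ensemble_probabilities(tensor)
    labels = labels_from_probabilities(mean_probs)
    acc = ensemble_accuracy(labels, true_labels) if true_labels is not None else None
    return EnsembleResult(mean_probs=mean_probs, labels=labels, ensemble_accuracy=acc)


class McdStreamingAccumulator:
    """Out-of-core MCD summaries: feed one run at a time.

    Maintains a running mean of the probability tensor and per-run accuracy
    counts, producing results identical to the in-memory path without holding
    all N x n x 3 values at once.
    """

    def __init__(self, true_labels=None):
        self.true_labels = (
            None if true_labels is None else np.asarray(true_labels, dtype=np.int64)
        )
        self._sum: np.ndarray | None = None
        self._accs: list[float] = []
        self.n_runs = 0

    def add_run(self, run_probs: np.ndarray) -> None:
        run_probs = np.asarray(run_probs, dtype=np.float64)
        if run_probs.ndim != 2 or run_probs.shape[1] != N_CLASSES:
            raise ValueError(f"expected (n_saccades, {N_CLASSES}), got {run_probs.shape}")
        if self._sum is None:
            self._sum = np.zeros_like(run_probs)
        elif self._sum.shape != run_probs.shape:
            raise ValueError("run shape changed between add_run calls")
        self._sum += run_probs
        self.n_runs += 1
        if self.true_labels is not None:
            labels = labels_from_probabilities(run_probs)
            self._accs.append(float((labels == self.true_labels).mean()))

    def run_summary(self) -> McdRunSummary:
        if self.true_labels is None:
            raise ValueError("accumulator was built without true labels")
        acc = np.asarray(self._accs)
        return McdRunSummary(per_run_accuracy=acc, mean_accuracy=float(acc.mean()))

    def ensemble(self) -> EnsembleResult:
        if self.n_runs == 0:
            raise ValueError("no runs accumulated")
        mean_probs = self._sum / self.n_runs
        labels = labels_from_probabilities(mean_probs)
        acc = (
            ensemble_accuracy(labels, self.true_labels)
            if self.true_labels is not None
            else None
        )
        return EnsembleResult(mean_probs=mean_probs, labels=labels,
                              ensemble_accuracy=acc)


def export_ensemble_tsv(path, register_ids, ensemble: EnsembleResult,
                        true_labels=None) -> Path:
    """TSV export: register_id, saccade_index, true/predicted label, p_C, p_P, p_S."""
    path = Path(path)
    n = ensemble.mean_probs.shape[0]
    if len(register_ids) != n:
        raise ValueError("register_ids length must match number of saccades")
    with path.open("w", encoding="utf-8") as fh:
        fh.write("register_id\tsaccade_index\ttrue_label\tpredicted_label\t"
                 "p_C\tp_P\tp_S\n")
        counter: dict[str, int] = {}
        for i in range(n):
            rid = register_ids[i]
            counter[rid] = counter.get(rid, -1) + 1
            truth = (
                ClassLabel(int(true_labels[i])).name if true_labels is not None else "-"
            )
            pred = ClassLabel(int(ensemble.labels[i])).name
            p = ensemble.mean_probs[i]
            fh.write(f"{rid}\t{counter[rid]}\t{truth}\t{pred}\t"
                     f"{p[0]:.12g}\t{p[1]:.12g}\t{p[2]:.12g}\n")
    return path
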