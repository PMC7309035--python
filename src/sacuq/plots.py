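"""Generic diagnostic plots: MCD accuracy distribution, per-register ensemble
probability box plots, confusion matrix and ROC curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .data import ClassLabel
from .mcd import EnsembleResult, McdRunSummary
from .tree import EvalReport

__all__ = [
    "plot_mcd_accuracy_distribution",
    "plot_register_probability_boxes",
    "plot_confusion",
    "plot_roc",
]


def _save(fig, path):
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_mcd_accuracy_distribution(summary: McdRunSummary, ensemble_accuracy: float,
                                   path, title: str = "MCD run accuracies"):
    """Histogram of per-run accuracies with the ensemble accuracy marked."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(summary.per_run_accuracy, bins=30, color="steelblue", alpha=0.8)
    ax.axvline(ensemble_accuracy, color="crimson", lw=2,
               label=f"ensemble {ensemble_accuracy:.3f}")
    ax.axvline(summary.mean_accuracy, color="black", ls="--",
               label=f"run mean {summary.mean_accuracy:.3f}")
    ax.set_xlabel("accuracy")
    ax.set_ylabel("runs")
    ax.set_title(title)
    ax.legend()
    return _save(fig, path)


def plot_register_probability_boxes(ensemble: EnsembleResult, path,
                                    title: str = "register"):
    """Per prediction group, box plots of the ensemble class probabilities."""
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2), sharey=True)
    for ax, group in zip(axes, ClassLabel):
        idx = np.flatnonzero(ensemble.labels == int(group))
        if len(idx):
            ax.boxplot([ensemble.mean_probs[idx, int(c)] for c in ClassLabel],
                       tick_labels=[c.name for c in ClassLabel])
        ax.set_title(f"{title}: predicted {group.name} (n={len(idx)})")
    axes[0].set_ylabel("ensemble probability")
    return _save(fig, path)


def plot_confusion(report: EvalReport, path):
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(report.confusion, cmap="Blues")
    names = [c.name for c in ClassLabel]
    ax.set_xticks(range(3), names)
    ax.set_yticks(range(3), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(3):
        for j in range(3):
            ax.text(j, i, str(report.confusion[i, j]), ha="center", va="center")
    fig.colorbar(im, ax=ax)
    return _save(fig, path)


def plot_roc(report: EvalReport, path):
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for name, curve in report.roc.items():
        if curve is None:
            continue
        style = {"micro": {"ls": ":", "lw": 2}, "macro": {"ls": "--", "lw": 2}}
        ax.plot(curve["fpr"], curve["tpr"],
                label=f"{name} (AUC {curve['auc']:.3f})", **style.get(name, {}))
    ax.plot([0, 1], [0, 1], color="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    return _save(fig, path)
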