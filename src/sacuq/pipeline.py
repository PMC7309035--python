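"""End-to-end experiment: train with MCD, ensemble-infer, build register
features, fit the decision tree on validation registers, evaluate on test.

The flow per deep-learning repeat:

1. train the CNN-LSTM on the train-split saccades (labels inherited from
   registers);
2. run N Monte Carlo dropout passes over the validation and test saccades;
   summarize per-run accuracies and the MCD ensemble; also record the
   dropout-off deterministic baseline;
3. group each register's saccades by ensemble label and build the 21-feature
   register tables (validation and test).  The validation set plays two
   roles: it measures saccade-level performance and its feature table is the
   decision tree's training data;
4. fit the Gini tree ``n_dt_repeats`` times (seed-varied tie-breaking) on the
   validation table, evaluate on the test table; keep one representative tree
   for rules, confusion matrix and ROC;
5. compute the majority-vote register baseline from the ensemble labels.

Stage seeds derive from the global seed by fixed offsets so any stage can be
rerun in isolation.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .data import ClassLabel, DataSet, SplitSpec, load_dataset, split_registers, write_manifest
from .features import build_feature_table, majority_vote_label, write_feature_table
from .mcd import (
    ensemble_from_tensor,
    export_ensemble_tsv,
    labels_from_probabilities,
    per_run_accuracies,
    run_mcd,
)
from .net import ArchitectureConfig, TrainConfig, build_model, train
from .synthetic import ClassGeneratorConfig, generate_dataset
from .tree import TreeConfig, evaluate, export_rules, fit_tree, predict, repeated_fit_report, tree_to_json

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment"]

# fixed stage-seed offsets (global seed + offset)
_SPLIT_OFFSET = 1
_TRAIN_OFFSET = 1_000
_MCD_OFFSET = 2_000
_DT_OFFSET = 3_000


@dataclass
class ExperimentConfig:
    """Serializable description of one full experiment."""

    # data: either a directory of .reg.csv files or a synthetic generator draw
    data_dir: str | None = None
    synthetic_n_per_class: tuple[int, int, int] = (20, 20, 20)
    synthetic_register_size_bounds: tuple[int, int] | None = None
    presym_sick_fraction_range: tuple[float, float] = (0.2, 0.5)
    split_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    # architecture
    n_filters: int = 128
    kernel_size: int = 3
    lstm_units: int = 100
    dropout_rate: float = 0.5
    # training
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    # inference / tree / repetition
    n_mcd_passes: int = 500
    max_depth: int | None = 4
    min_samples_leaf: int = 1
    n_dt_repeats: int = 100
    n_dl_repeats: int = 10
    seed: int = 0

    def architecture(self) -> ArchitectureConfig:
        return ArchitectureConfig(
            n_filters=self.n_filters, kernel_size=self.kernel_size,
            lstm_units=self.lstm_units, dropout_rate=self.dropout_rate,
        )

    def generator(self) -> ClassGeneratorConfig:
        kwargs: dict = {"presym_sick_fraction_range": tuple(self.presym_sick_fraction_range)}
        if self.synthetic_register_size_bounds is not None:
            mn, mx = self.synthetic_register_size_bounds
            kwargs["register_size_bounds"] = {c.name: (mn, mx) for c in ClassLabel}
            # wide sd over the bounds: effectively near-uniform sizes
            kwargs["register_size_mean_sd"] = {
                c.name: ((mn + mx) / 2.0, float(mx - mn)) for c in ClassLabel
            }
        return ClassGeneratorConfig(**kwargs)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        for key in ("synthetic_n_per_class", "synthetic_register_size_bounds",
                    "presym_sick_fraction_range", "split_fractions"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ExperimentReport:
    """Per-repeat saccade and register metrics plus pooled summaries."""

    repeats: list[dict] = field(default_factory=list)
    pooled: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"config": self.config, "repeats": self.repeats, "pooled": self.pooled}

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")
        return path


def _per_register(split: DataSet, ensemble) -> dict:
    """Restrict an ensemble result to each register of the split."""
    out = {}
    start = 0
    for reg in split:
        stop = start + reg.n_saccades
        from .mcd import EnsembleResult

        out[reg.register_id] = (
            EnsembleResult(
                mean_probs=ensemble.mean_probs[start:stop],
                labels=ensemble.labels[start:stop],
            ),
            reg.label,
        )
        start = stop
    return out


def _register_baselines(split: DataSet, saccade_labels: np.ndarray) -> dict:
    """Majority-vote register labels from per-saccade labels; overall and
    per-class accuracy."""
    votes, truths = [], []
    start = 0
    for reg in split:
        stop = start + reg.n_saccades
        votes.append(int(majority_vote_label(saccade_labels[start:stop])))
        truths.append(int(reg.label))
        start = stop
    votes_arr, truths_arr = np.asarray(votes), np.asarray(truths)
    per_class = {}
    for c in ClassLabel:
        mask = truths_arr == int(c)
        per_class[c.name] = float((votes_arr[mask] == int(c)).mean()) if mask.any() else None
    return {
        "accuracy": float((votes_arr == truths_arr).mean()),
        "per_class_accuracy": per_class,
        "labels": [ClassLabel(v).name for v in votes],
    }


def _saccade_stage(model, split: DataSet, n_passes: int, seed: int):
    """MCD + ensemble + deterministic baseline for one split."""
    x, y, _ = split.saccade_matrix()
    tensor = run_mcd(model, x, n_passes, seed=seed)
    summary = per_run_accuracies(tensor, y)
    ens = ensemble_from_tensor(tensor, y)
    det_probs = model.predict_proba(x)
    det_labels = labels_from_probabilities(det_probs)
    metrics = {
        "mcd_mean_accuracy": summary.mean_accuracy,
        "mcd_ensemble_accuracy": ens.ensemble_accuracy,
        "dropout_off_accuracy": float((det_labels == y).mean()),
    }
    return metrics, ens, det_labels, y


def run_experiment(cfg: ExperimentConfig, out_dir=None, verbose: bool = False
                   ) -> ExperimentReport:
    """Run the full pipeline; archives intermediates under ``out_dir`` if given."""
    t_start = time.perf_counter()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out_dir / "config.yaml")

    if cfg.data_dir is not None:
        dataset = load_dataset(cfg.data_dir)
    else:
        dataset = generate_dataset(cfg.synthetic_n_per_class, cfg.generator(),
                                   seed=cfg.seed)
    train_ds, val_ds, test_ds = split_registers(
        dataset, SplitSpec(tuple(cfg.split_fractions), seed=cfg.seed + _SPLIT_OFFSET)
    )
    if out_dir is not None:
        write_manifest(out_dir, {"train": train_ds, "validation": val_ds,
                                 "test": test_ds})

    report = ExperimentReport(config=asdict(cfg))
    all_dt_accuracies: list[float] = []
    pooled_confusion = np.zeros((3, 3), dtype=np.int64)

    for k in range(cfg.n_dl_repeats):
        stage = f"repeat {k}"
        rep_dir = None
        if out_dir is not None:
            rep_dir = out_dir / f"repeat_{k}"
            rep_dir.mkdir(exist_ok=True)
        try:
            model = build_model(cfg.architecture())
            train(model, train_ds,
                  TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                              learning_rate=cfg.learning_rate,
                              seed=cfg.seed + _TRAIN_OFFSET + k),
                  verbose=verbose)

            stage = f"repeat {k}: MCD inference"
            per_split = {}
            ensembles = {}
            for offset, (name, split) in enumerate(
                [("validation", val_ds), ("test", test_ds)]
            ):
                metrics, ens, det_labels, y = _saccade_stage(
                    model, split, cfg.n_mcd_passes,
                    seed=cfg.seed + _MCD_OFFSET + 10 * k + offset,
                )
                per_split[name] = metrics
                ensembles[name] = ens
                if rep_dir is not None:
                    _, _, ids = split.saccade_matrix()
                    export_ensemble_tsv(rep_dir / f"ensemble_{name}.tsv", ids, ens, y)

            stage = f"repeat {k}: feature extraction"
            val_table = build_feature_table(_per_register(val_ds, ensembles["validation"]))
            test_table = build_feature_table(_per_register(test_ds, ensembles["test"]))
            if rep_dir is not None:
                write_feature_table(val_table, rep_dir / "features_validation.tsv")
                write_feature_table(test_table, rep_dir / "features_test.tsv")

            stage = f"repeat {k}: decision tree"
            tree_cfg = TreeConfig(max_depth=cfg.max_depth,
                                  min_samples_leaf=cfg.min_samples_leaf,
                                  seed=cfg.seed + _DT_OFFSET + k * cfg.n_dt_repeats,
                                  n_repeats=cfg.n_dt_repeats)
            dt_summary = repeated_fit_report(val_table, test_table, tree_cfg)
            all_dt_accuracies.extend(dt_summary.pop("accuracies"))
            rep_tree = fit_tree(val_table, tree_cfg)
            labels, scores = predict(rep_tree, test_table)
            y_test = np.array([int(ClassLabel.from_string(s))
                               for s in test_table["true_label"]])
            eval_report = evaluate(labels, scores, y_test)
            pooled_confusion += eval_report.confusion
            baseline = _register_baselines(test_ds, ensembles["test"].labels)
            if rep_dir is not None:
                (rep_dir / "rules.txt").write_text(
                    "\n".join(export_rules(rep_tree)) + "\n", encoding="utf-8")
                tree_to_json(rep_tree, rep_dir / "tree.json")
                (rep_dir / "evaluation.json").write_text(
                    json.dumps(eval_report.to_dict(), indent=2), encoding="utf-8")

            report.repeats.append({
                "repeat": k,
                "saccade_metrics": per_split,
                "dt_test_accuracy": dt_summary,
                "representative_tree": eval_report.to_dict(),
                "majority_vote_baseline": baseline,
                "training_final_accuracy": model.training_log[-1]["accuracy"],
            })
        except Exception as exc:
            if out_dir is not None:
                (out_dir / "FAILED.txt").write_text(
                    f"stage: {stage}\nerror: {exc!r}\n", encoding="utf-8")
            raise RuntimeError(f"experiment failed at stage '{stage}': {exc}") from exc

    acc = np.asarray(all_dt_accuracies)
    report.pooled = {
        "register_accuracy": {
            "mean": float(acc.mean()), "sd": float(acc.std()),
            "min": float(acc.min()), "max": float(acc.max()),
            "n_fits": int(acc.size),
        },
        "register_precision_weighted_mean": float(np.mean(
            [r["representative_tree"]["precision_weighted"] for r in report.repeats])),
        "register_recall_weighted_mean": float(np.mean(
            [r["representative_tree"]["recall_weighted"] for r in report.repeats])),
        "register_f1_weighted_mean": float(np.mean(
            [r["representative_tree"]["f1_weighted"] for r in report.repeats])),
        "pooled_confusion": pooled_confusion.tolist(),
        "majority_vote_accuracy_mean": float(np.mean(
            [r["majority_vote_baseline"]["accuracy"] for r in report.repeats])),
        "elapsed_seconds": time.perf_counter() - t_start,
    }
    if out_dir is not None:
        report.save(out_dir / "report.json")
    return report
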