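"""Full pipeline on a small synthetic cohort: register-level decision rules.

Runs training, MCD ensemble inference, 21-feature extraction and the Gini
decision tree, then prints the learned IF-THEN rules and the test confusion
matrix.  The majority-vote baseline is shown for contrast: it labels most
presymptomatic registers as control because their sick-like saccades are a
minority.
"""

from sacuq import ExperimentConfig, run_experiment

cfg = ExperimentConfig(
    synthetic_n_per_class=(20, 20, 20),
    synthetic_register_size_bounds=(20, 40),
    epochs=10,
    n_mcd_passes=50,
    n_dl_repeats=1,
    n_dt_repeats=100,
    seed=1,
)
report = run_experiment(cfg, out_dir="scratch_example_run")

rep = report.repeats[0]
print("saccade-level metrics:")
for split, metrics in rep["saccade_metrics"].items():
    print(f"  {split}: " + "  ".join(f"{k}={v:.3f}" for k, v in metrics.items()))

pooled = report.pooled["register_accuracy"]
print(f"\nregister accuracy over {pooled['n_fits']} tree fits: "
      f"mean {pooled['mean']:.3f}  sd {pooled['sd']:.3f} "
      f"(min {pooled['min']:.3f}, max {pooled['max']:.3f})")
print(f"majority-vote baseline accuracy: "
      f"{rep['majority_vote_baseline']['accuracy']:.3f} "
      f"(per class: {rep['majority_vote_baseline']['per_class_accuracy']})")
print("\nconfusion matrix (rows = true C/P/S):")
for row in rep["representative_tree"]["confusion"]:
    print(f"  {row}")

print("\ndecision rules (from scratch_example_run/repeat_0/rules.txt):")
with open("scratch_example_run/repeat_0/rules.txt") as fh:
    print(fh.read())
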