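# Methods

## Problem and model

A register is one patient's bag of saccades; the diagnostic label (control,
presymptomatic, sick — encoded 0/1/2, and in that order in every probability
vector) attaches to the bag, not to its instances. Presymptomatic registers
contain a minority of pathological-looking saccades among healthy-looking
ones, so no instance-level classifier can recover the register label
directly. The package's pipeline therefore has two levels:

* **instance level** — a CNN-LSTM maps one 192-sample saccade to a 3-class
  softmax. Saccades inherit their register's label for training; for
  presymptomatic registers this deliberately injects label noise, which the
  downstream stage exploits rather than avoids.
* **bag level** — Monte Carlo dropout turns the trained network into a
  sampler of predictive distributions; summary statistics of those
  distributions, grouped by predicted class within each register, form a
  21-dimensional register descriptor classified by a small decision tree.

### Network

conv1d(k=3, 128 filters, ReLU) → maxpool(2,2) → conv1d(k=3, 128, ReLU) →
maxpool(2,2) → LSTM(100) → dropout(0.5) → dense(3, softmax). Convolutions use
'same' padding, so the time axis goes 192 → 96 → 48 and the LSTM consumes 48
steps of 128 channels; the final hidden state feeds the head. Dropout is the
single stochastic layer and sits after the LSTM.

The backend is a compact NumPy implementation (`nn_ops.py`): im2col
convolution, non-overlapping max pooling, full backpropagation through time
for the LSTM (gate order i, f, g, o; forget-gate bias initialized to 1),
inverted dropout, softmax cross-entropy, Adam. Gradients are verified against
central finite differences to ~1e-8 in float64 (`test_net.py`). Training
defaults — Adam at learning rate 1e-3, 30 epochs, batch 64, Glorot-uniform
initialization — are conventional for this model family and fully
configurable; parameters are float32 for speed, float64 is available for
numerical work.

Because everything below the dropout layer is deterministic at inference, the
conv+LSTM features of a saccade are computed once and each MCD pass applies
only a fresh mask, the dense layer and the softmax. This is an exact
optimization, not an approximation; a test confirms pass-for-pass equality
with literal repeated forward passes. A streaming accumulator reproduces the
in-memory ensemble (running sum of probabilities plus per-run accuracy
counts) for out-of-core use.

### MCD summaries

For N passes: per-run accuracy MCDaccᵣ (argmax within the run), their
arithmetic mean MCDaccmean, ensemble probabilities p̄ᵢ = mean over runs,
ensemble labels argmax p̄ᵢ and ensemble accuracy MCDEacc. Argmax ties break
toward the lowest class index (C before P before S) everywhere — an arbitrary
but fixed convention. Accuracies pool all saccades of a split rather than
averaging per register. With dropout rate 0 all passes coincide and
MCDaccmean = MCDEacc exactly; the dropout-off forward pass is also reported
separately as the deterministic CNN-LSTM baseline.

### Register features

Group a register's saccades by ensemble label; for each group X ∈ {C, P, S}
and class Y record mean and standard deviation of the members' p̄(Y). Feature
order is fixed: `card_C, card_P, card_S`, then the nine means row-major in X,
then the nine standard deviations. Conventions chosen here (configurable or
documented where the choice was open):

* **population** standard deviation, so singleton groups give 0 rather than
  an undefined value;
* empty groups impute 0.0 for all six statistics (a softmax mean over a
  non-empty group can never be exactly 0, so imputed values are
  unambiguous); −1.0 is available, and the policy is recorded in the table's
  metadata.

### Decision tree

CART-style greedy binary splits minimizing size-weighted child Gini impurity,
thresholds at midpoints between consecutive distinct values, default depth
limit 4 (the rule sets of interest use about four decision attributes),
min_samples_leaf 1. Split-score ties are combinatorial (the score depends
only on the induced label partition), so the tie rule matters: deterministic
default (lowest feature index, then lowest threshold), or a seeded uniform
draw among ties. Repeated fits (`n_repeats`, default 100) vary only this
seed, and their test accuracies are summarized as mean/sd/min/max. Splitting
stops when no candidate strictly reduces impurity (tolerance 1e-12). Rules
are exported as one IF-THEN line per leaf with full-precision thresholds so
that an independent rule interpreter reproduces `predict` exactly; a
machine-readable JSON tree is also written. ROC curves use leaf class
proportions as scores (one-vs-rest per class, pooled micro-average,
macro-average over defined classes; a class absent from the truth is excluded
from the macro with a warning). Confusion matrices have truth in rows.

The tree is implemented in the package rather than delegated to a library
estimator so that tie-break semantics, stopping rules and rule export are
pinned; a test cross-checks it against scikit-learn's CART on a tie-free
table, and another against exhaustive split enumeration on small tables.

## Pipeline

Registers are split 40/40/20 (train/validation/test), stratified by class,
with per-class floor allocation and remainders assigned train-first
(maximizing training data). The validation split plays two roles: it measures
saccade-level performance and its feature table is the tree's training data;
the test split is used only for register-level evaluation. Per deep-learning
repeat the pipeline trains the network, runs N MCD passes on validation and
test, builds both feature tables, fits the tree `n_dt_repeats` times and
keeps one representative tree for rules/confusion/ROC. Defaults follow the
reference protocol: N = 500 passes, 10 deep-learning repeats, 100 tree fits
per repeat, with pooled summaries over all 10 × 100 accuracies (the
per-repeat summaries are also reported). Stage seeds derive from the global
seed by fixed offsets (split +1, training +1000+k, MCD +2000+10k, tree
+3000+100k), so stages can be rerun in isolation; one global seed fixes the
whole run.

## Synthetic cohort generator

The generator emulates the class-conditional structure the method assumes,
not oculomotor physiology. A saccade is an endpoint-normalized logistic
transition between gaze levels ∓0.45 (direction ±1 equiprobable), plus
damped post-transition ringing (overshoot), a sinusoidal tremor of random
period 6–15 samples, and Gaussian noise, clipped to [−0.5, 0.5]. Class
conditions: control transitions are fast (width 1.5–4 samples, low tremor),
sick transitions are slow (width 18–45) with stronger tremor and noise.
Presymptomatic registers draw a sick fraction f once per register from
(0.2, 0.5) — chosen to reflect observed presymptomatic registers in which
roughly a fifth to a half of saccades behave pathologically — and each
saccade is independently sick-like with probability f.

Register sizes come from per-class truncated normals matching the summary
statistics of the 85-register screening cohort the method was developed on:
mean/sd/min/max C (78.3, 21.6, 38, 169), P (76.7, 25, 28, 172),
S (54, 49, 6, 172); truncation is by resampling of the rounded draw.

What passing tests on this cohort do and do not show: the generator's classes
are separable by transition shape, so end-to-end tests demonstrate that the
pipeline *mechanics* (uncertainty aggregation, mixture detection, rule
recovery) work when the instance signal exists; they do not certify
performance on recorded EOG data, where class overlap, artifacts and
inter-patient variability are harsher. The published accuracies on the
recorded cohort are not reproducible here without that dataset and full-scale
retraining.

## Scaled study conditions

Tests and the acceptance script run a reduced protocol chosen as the smallest
cohort on which the register stage is statistically meaningful: 60 registers
(20 per class, sizes near-uniform in 20–40 via a wide truncated normal), 10
training epochs, 50 MCD passes, 1 deep-learning repeat, 100 tree fits. Under
these conditions the register-level tree reaches perfect test accuracy while
the majority-vote baseline fails every presymptomatic register — the
qualitative signature of the method.

## Known limitations

* Saccades are treated as opaque normalized signals; whether they represent
  position or velocity profiles is irrelevant to the code but matters for
  interpreting the waveform generator.
* The loader reads only the package's own `.reg.csv` layout; adapting a
  recorded deposit requires a small conversion script against its actual
  format.
* Class imbalance is not reweighted during training.
* No uncertainty decomposition (aleatoric vs epistemic); the MCD spread is
  used only through the group statistics. Counting very-low / very-high
  uncertainty saccades per register is a natural extension point of the
  feature builder.
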