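"""Monte Carlo dropout inference: run tensors, summaries, ensemble, streaming."""

import numpy as np
import pytest

from sacuq import (
    ArchitectureConfig,
    ClassLabel,
    McdStreamingAccumulator,
    TrainConfig,
    build_model,
    ensemble_from_tensor,
    ensemble_probabilities,
    label_from_probabilities,
    per_run_accuracies,
    run_mcd,
    train,
)
from sacuq.mcd import ensemble_accuracy, export_ensemble_tsv, labels_from_probabilities
from conftest import small_generator_config
from sacuq.synthetic import generate_dataset
from oracles import naive_ensemble_probabilities, naive_per_run_accuracies


def random_tensor(rng, n_runs, n_sacc):
    raw = rng.random((n_runs, n_sacc, 3))
    return raw / raw.sum(axis=2, keepdims=True)


# ------------------------------------------------------------------- run_mcd

def test_run_mcd_rejects_nonpositive_passes(trained_tiny_model, rng):
    with pytest.raises(ValueError, match="n_passes"):
        run_mcd(trained_tiny_model, rng.uniform(-0.5, 0.5, (2, 192)), 0)


def test_run_mcd_reproducible_from_seed(trained_tiny_model, rng):
    x = rng.uniform(-0.5, 0.5, (4, 192))
    t1 = run_mcd(trained_tiny_model, x, 6, seed=5)
    t2 = run_mcd(trained_tiny_model, x, 6, seed=5)
    np.testing.assert_array_equal(t1, t2)
    assert t1.shape == (6, 4, 3)


def test_run_mcd_without_dropout_gives_identical_slices(small_dataset, rng):
    model = build_model(ArchitectureConfig(n_filters=6, lstm_units=8, dropout_rate=0.0))
    train(model, small_dataset, TrainConfig(epochs=1, batch_size=32, seed=0))
    x = rng.uniform(-0.5, 0.5, (5, 192))
    tensor = run_mcd(model, x, 4, seed=1)
    for r in range(1, 4):
        np.testing.assert_array_equal(tensor[r], tensor[0])


def test_run_mcd_matches_stochastic_forward_passes(trained_tiny_model, rng):
    """The feature-caching fast path equals N literal dropout-active passes."""
    from sacuq import stochastic_forward

    x = rng.uniform(-0.5, 0.5, (3, 192))
    tensor = run_mcd(trained_tiny_model, x, 5, seed=11)
    rng2 = np.random.default_rng(11)
    for r in range(5):
        np.testing.assert_allclose(
            tensor[r], stochastic_forward(trained_tiny_model, x, rng2), atol=1e-6
        )


# ------------------------------------------------------------------ summaries

def test_per_run_accuracy_trivial_cases():
    t = np.array([[[0.8, 0.1, 0.1], [0.1, 0.1, 0.8]]])
    s = per_run_accuracies(t, [0, 2])
    assert s.per_run_accuracy.tolist() == [1.0]
    assert s.mean_accuracy == 1.0

    # two runs with accuracies 0.6 and 0.8 have mean 0.7
    rng = np.random.default_rng(0)
    n = 10
    truths = np.zeros(n, dtype=int)
    t = np.zeros((2, n, 3))
    t[:, :, :] = [0.1, 0.8, 0.1]  # predicted P (wrong)
    t[0, :6] = [0.8, 0.1, 0.1]  # 6 correct in run 0
    t[1, :8] = [0.8, 0.1, 0.1]  # 8 correct in run 1
    s = per_run_accuracies(t, truths)
    np.testing.assert_allclose(s.per_run_accuracy, [0.6, 0.8])
    assert s.mean_accuracy == pytest.approx(0.7)


def test_all_wrong_run_scores_zero():
    t = np.array([[[0.1, 0.8, 0.1], [0.1, 0.8, 0.1]]])
    assert per_run_accuracies(t, [0, 2]).per_run_accuracy[0] == 0.0


def test_per_run_accuracy_length_mismatch():
    t = np.full((1, 2, 3), 1 / 3)
    with pytest.raises(ValueError, match="labels"):
        per_run_accuracies(t, [0, 1, 2])


def test_ensemble_probabilities_examples(rng):
    t = np.array([[[0.6, 0.3, 0.1]], [[0.4, 0.5, 0.1]]])
    np.testing.assert_allclose(ensemble_probabilities(t), [[0.5, 0.4, 0.1]])
    # all runs identical -> mean equals any run
    one = random_tensor(rng, 1, 4)
    rep = np.repeat(one, 5, axis=0)
    np.testing.assert_allclose(ensemble_probabilities(rep), one[0], atol=1e-15)
    # rows stay on the simplex
    t = random_tensor(rng, 7, 20)
    np.testing.assert_allclose(ensemble_probabilities(t).sum(axis=1), 1.0, atol=1e-9)


def test_ensemble_matches_naive_two_loop_oracle(rng):
    for _ in range(20):
        n_runs = int(rng.integers(1, 21))
        n_sacc = int(rng.integers(1, 51))
        t = random_tensor(rng, n_runs, n_sacc)
        truths = rng.integers(0, 3, n_sacc)
        np.testing.assert_allclose(
            ensemble_probabilities(t), naive_ensemble_probabilities(t), atol=1e-12
        )
        accs, mean = naive_per_run_accuracies(t, truths)
        s = per_run_accuracies(t, truths)
        np.testing.assert_allclose(s.per_run_accuracy, accs, atol=1e-12)
        assert s.mean_accuracy == pytest.approx(mean, abs=1e-12)


def test_run_axis_permutation_leaves_ensemble_unchanged(rng):
    t = random_tensor(rng, 9, 12)
    truths = rng.integers(0, 3, 12)
    perm = rng.permutation(9)
    a = ensemble_from_tensor(t, truths)
    b = ensemble_from_tensor(t[perm], truths)
    np.testing.assert_allclose(a.mean_probs, b.mean_probs, atol=1e-12)
    np.testing.assert_array_equal(a.labels, b.labels)
    assert a.ensemble_accuracy == b.ensemble_accuracy


# --------------------------------------------------------------------- labels

def test_label_from_probabilities():
    assert label_from_probabilities([0.5, 0.4, 0.1]) == ClassLabel.C
    assert label_from_probabilities([0.1, 0.2, 0.7]) == ClassLabel.S
    assert label_from_probabilities([0.4, 0.4, 0.2]) == ClassLabel.C  # tie rule
    assert label_from_probabilities([0.3, 0.35, 0.35]) == ClassLabel.P
    with pytest.raises(ValueError):
        label_from_probabilities([0.9, 0.9, 0.9])


def test_ensemble_accuracy_examples():
    assert ensemble_accuracy(np.array([0, 1, 2]), [0, 0, 2]) == pytest.approx(2 / 3)
    assert ensemble_accuracy(np.array([0, 1, 2]), [0, 1, 2]) == 1.0


def test_degenerate_dropout_collapses_all_summaries(small_dataset, rng):
    """With dropout off, every pass is the same forward map, so every per-run
    accuracy, their mean, and the ensemble accuracy coincide exactly."""
    model = build_model(ArchitectureConfig(n_filters=6, lstm_units=8, dropout_rate=0.0))
    train(model, small_dataset, TrainConfig(epochs=1, batch_size=32, seed=0))
    x, y, _ = small_dataset.saccade_matrix()
    tensor = run_mcd(model, x[:40], 5, seed=3)
    s = per_run_accuracies(tensor, y[:40])
    ens = ensemble_from_tensor(tensor, y[:40])
    assert np.all(s.per_run_accuracy == s.per_run_accuracy[0])
    assert s.mean_accuracy == ens.ensemble_accuracy


# ------------------------------------------------------------------ streaming

def test_streaming_accumulator_matches_in_memory(rng):
    t = random_tensor(rng, 15, 30)
    truths = rng.integers(0, 3, 30)
    acc = McdStreamingAccumulator(truths)
    for r in range(15):
        acc.add_run(t[r])
    s_mem = per_run_accuracies(t, truths)
    s_str = acc.run_summary()
    np.testing.assert_allclose(s_str.per_run_accuracy, s_mem.per_run_accuracy,
                               atol=1e-15)
    assert s_str.mean_accuracy == pytest.approx(s_mem.mean_accuracy, abs=1e-15)
    e_mem = ensemble_from_tensor(t, truths)
    e_str = acc.ensemble()
    np.testing.assert_allclose(e_str.mean_probs, e_mem.mean_probs, atol=1e-12)
    np.testing.assert_array_equal(e_str.labels, e_mem.labels)
    assert e_str.ensemble_accuracy == e_mem.ensemble_accuracy


def test_export_ensemble_tsv(tmp_path, rng):
    import pandas as pd

    t = random_tensor(rng, 3, 6)
    truths = rng.integers(0, 3, 6)
    ens = ensemble_from_tensor(t, truths)
    ids = ["r1"] * 4 + ["r2"] * 2
    path = export_ensemble_tsv(tmp_path / "e.tsv", ids, ens, truths)
    frame = pd.read_csv(path, sep="\t")
    assert list(frame.columns) == ["register_id", "saccade_index", "true_label",
                                   "predicted_label", "p_C", "p_P", "p_S"]
    assert len(frame) == 6
    assert frame["saccade_index"].tolist() == [0, 1, 2, 3, 0, 1]
    np.testing.assert_allclose(frame[["p_C", "p_P", "p_S"]].to_numpy(),
                               ens.mean_probs, atol=1e-9)
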