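"""Gini decision tree: splits, rules, evaluation metrics, repeated fits."""

import numpy as np
import pandas as pd
import pytest

from sacuq import (
    ClassLabel,
    FEATURE_NAMES,
    TreeConfig,
    apply_rules,
    evaluate,
    export_rules,
    fit_tree,
    gini_impurity,
    predict,
    repeated_fit_report,
    tree_from_json,
    tree_to_json,
)
from oracles import exhaustive_greedy_tree, gini_by_simulation_free_enumeration


def make_table(x: np.ndarray, y, feature_subset=None) -> pd.DataFrame:
    """Embed a small (n, k) matrix into the canonical 21-feature schema;
    unused features are constant zero so they can never split."""
    n = len(x)
    frame = pd.DataFrame(0.0, index=range(n), columns=FEATURE_NAMES)
    names = feature_subset or FEATURE_NAMES[: x.shape[1]]
    for k, name in enumerate(names):
        frame[name] = x[:, k]
    frame.insert(0, "true_label", [ClassLabel(int(v)).name for v in y])
    frame.insert(0, "register_id", [f"r{i:03d}" for i in range(n)])
    return frame


def random_table(rng, n_rows=20):
    x = rng.random((n_rows, 21))
    y = rng.integers(0, 3, n_rows)
    return make_table(x, y, feature_subset=FEATURE_NAMES)


# ----------------------------------------------------------------------- gini

def test_gini_closed_forms():
    assert gini_impurity((5, 5, 0)) == pytest.approx(0.5)
    assert gini_impurity((7, 0, 0)) == pytest.approx(0.0)
    assert gini_impurity((1, 1, 1)) == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        gini_impurity((0, 0, 0))


def test_gini_matches_two_draw_disagreement_probability(rng):
    for _ in range(30):
        counts = rng.integers(0, 20, 3)
        if counts.sum() == 0:
            counts[0] = 1
        assert gini_impurity(counts) == pytest.approx(
            gini_by_simulation_free_enumeration(counts), abs=1e-12
        )


# ------------------------------------------------------------------- fitting

def tree_structure(node):
    if node.is_leaf:
        return {"counts": node.counts.tolist()}
    return {
        "counts": node.counts.tolist(),
        "feature": FEATURE_NAMES.index(node.feature),
        "threshold": node.threshold,
        "left": tree_structure(node.left),
        "right": tree_structure(node.right),
    }


def oracle_structure(node):
    if "feature" not in node:
        return {"counts": node["counts"]}
    return {
        "counts": node["counts"],
        "feature": node["feature"],
        "threshold": node["threshold"],
        "left": oracle_structure(node["left"]),
        "right": oracle_structure(node["right"]),
    }


def test_fit_tree_matches_exhaustive_greedy_search(rng):
    """On small tables with two active features the greedy fit coincides with
    brute-force enumeration of every split at every node."""
    import warnings

    for _ in range(30):
        n = int(rng.integers(3, 9))
        x = np.round(rng.random((n, 2)), 3)
        y = rng.integers(0, 3, n)
        table = make_table(x, y, feature_subset=["card_C", "mean_S_S"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # single-class draws
            model = fit_tree(table, TreeConfig(max_depth=2))
        # remap oracle feature indices 0,1 onto the two active columns
        expected = exhaustive_greedy_tree(x, y, max_depth=2)

        def remap(node):
            out = {"counts": node["counts"]}
            if "feature" in node:
                out["feature"] = [FEATURE_NAMES.index("card_C"),
                                  FEATURE_NAMES.index("mean_S_S")][node["feature"]]
                out["threshold"] = node["threshold"]
                out["left"] = remap(node["left"])
                out["right"] = remap(node["right"])
            return out

        assert tree_structure(model.root) == oracle_structure(remap(expected))


def test_two_row_table_gives_depth_one_perfect_tree():
    table = make_table(np.array([[0.0], [1.0]]), [0, 2], ["card_C"])
    model = fit_tree(table, TreeConfig())
    assert model.root.feature == "card_C"
    labels, _ = predict(model, table)
    assert labels.tolist() == [0, 2]


def test_fit_tree_deterministic_given_seed(rng):
    table = random_table(rng)
    cfg = TreeConfig(seed=5)
    a = fit_tree(table, cfg)
    b = fit_tree(table, cfg)
    assert tree_structure(a.root) == tree_structure(b.root)


def test_single_class_table_degenerates_with_warning():
    table = make_table(np.random.default_rng(0).random((4, 2)), [1, 1, 1, 1])
    with pytest.warns(UserWarning, match="single class"):
        model = fit_tree(table)
    assert model.root.is_leaf
    labels, scores = predict(model, table)
    assert np.all(labels == 1)
    np.testing.assert_allclose(scores.sum(axis=1), 1.0)


def test_root_rule_recovery_low_control_count_means_sick(rng):
    """A feature table in which sick registers are exactly those with fewer
    than 22 control-labeled saccades: the root must split card_C near 22."""
    card_c = np.array([5, 8, 11, 14, 16, 18, 19, 20, 21, 21,  # sick: < 22
                       22, 25, 28, 31, 35, 40, 45, 50, 55, 59,  # control
                       23, 26, 30, 33, 37, 42, 47, 52, 56, 58])  # presymptomatic
    y = np.array([2] * 10 + [0] * 10 + [1] * 10)
    # C vs P separable on a second feature; S rows scattered on it
    mean_ss = np.concatenate([rng.uniform(0.4, 0.9, 10),
                              rng.uniform(0.0, 0.3, 10),
                              rng.uniform(0.5, 0.9, 10)])
    table = make_table(np.column_stack([card_c, mean_ss]), y,
                       ["card_C", "mean_S_S"])
    model = fit_tree(table, TreeConfig(max_depth=4))
    assert model.root.feature == "card_C"
    assert 21.0 < model.root.threshold < 22.0
    labels, _ = predict(model, table)
    assert (labels == y).mean() == 1.0


def test_predictions_reach_training_labels_at_pure_leaves(rng):
    table = random_table(rng, n_rows=15)
    model = fit_tree(table, TreeConfig(max_depth=None))
    labels, scores = predict(model, table)
    truth = np.array([int(ClassLabel.from_string(s)) for s in table["true_label"]])
    assert np.all(labels == truth)  # unlimited depth + unique rows -> purity
    np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-12)


def test_sklearn_cross_check_on_tie_free_table(rng):
    """Independent CART implementation agrees on a table with a unique best
    split at the root and pure training predictions at full depth."""
    from sklearn.tree import DecisionTreeClassifier

    table = random_table(rng, n_rows=25)
    x = table[FEATURE_NAMES].to_numpy()
    y = np.array([int(ClassLabel.from_string(s)) for s in table["true_label"]])
    mine = fit_tree(table, TreeConfig(max_depth=None))
    ref = DecisionTreeClassifier(criterion="gini", random_state=0).fit(x, y)
    assert FEATURE_NAMES.index(mine.root.feature) == ref.tree_.feature[0]
    # sklearn stores features as float32, so thresholds agree only to ~1e-7
    assert mine.root.threshold == pytest.approx(ref.tree_.threshold[0], abs=1e-6)
    labels, _ = predict(mine, table)
    np.testing.assert_array_equal(labels, ref.predict(x))


# ---------------------------------------------------------------------- rules

def test_rules_round_trip_equals_predict(rng):
    for _ in range(25):
        train = random_table(rng, n_rows=int(rng.integers(4, 25)))
        test = random_table(rng, n_rows=10)
        model = fit_tree(train, TreeConfig(max_depth=3))
        rules = export_rules(model)
        labels, _ = predict(model, test)
        np.testing.assert_array_equal(apply_rules(rules, test), labels)


def test_depth_one_tree_exports_two_rules():
    table = make_table(np.array([[10.0], [30.0], [40.0]]), [2, 0, 0], ["card_C"])
    model = fit_tree(table, TreeConfig(max_depth=1))
    rules = export_rules(model)
    assert len(rules) == 2
    assert rules[0].startswith("IF card_C <= 20.0 THEN class=S")
    assert rules[1].startswith("IF card_C > 20.0 THEN class=C")


def test_single_leaf_tree_exports_unconditional_rule():
    table = make_table(np.zeros((3, 1)), [1, 1, 1], ["card_C"])
    with pytest.warns(UserWarning):
        model = fit_tree(table)
    rules = export_rules(model)
    assert rules == ["IF TRUE THEN class=P [C=0, P=3, S=0]"]


def test_tree_json_round_trip(rng):
    table = random_table(rng)
    model = fit_tree(table, TreeConfig(max_depth=3))
    back = tree_from_json(tree_to_json(model))
    l1, s1 = predict(model, table)
    l2, s2 = predict(back, table)
    np.testing.assert_array_equal(l1, l2)
    np.testing.assert_allclose(s1, s2, atol=1e-15)


# ----------------------------------------------------------------- evaluation

def perfect_scores(y):
    scores = np.zeros((len(y), 3))
    scores[np.arange(len(y)), y] = 1.0
    return scores


def test_evaluate_perfect_predictions():
    y = np.array([0, 0, 1, 2, 2])
    rep = evaluate(y, perfect_scores(y), y)
    assert rep.accuracy == 1.0 and rep.f1_weighted == 1.0
    assert np.all(rep.confusion == np.diag([2, 1, 2]))
    assert rep.roc["micro"]["auc"] == 1.0


def test_evaluate_confusion_rows_are_truth():
    y_true = np.array([0, 0, 2, 2])
    y_pred = np.array([0, 2, 2, 2])
    with pytest.warns(UserWarning, match="absent"):  # no P registers in truth
        rep = evaluate(y_pred, perfect_scores(y_pred), y_true)
    assert rep.accuracy == 0.75
    assert rep.confusion[0].tolist() == [1, 0, 1]
    assert rep.confusion.sum() == 4
    # row sums equal per-class supports
    assert rep.confusion.sum(axis=1).tolist() == [2, 0, 2]


def test_weighted_metrics_match_long_hand_computation():
    # confusion: C:(2,1,0), P:(0,1,1), S:(1,0,3); supports (3,2,4)
    y_true = np.array([0, 0, 0, 1, 1, 2, 2, 2, 2])
    y_pred = np.array([0, 0, 1, 1, 2, 2, 2, 0, 2])
    rep = evaluate(y_pred, perfect_scores(y_pred), y_true)
    # per-class precision = recall = (2/3, 1/2, 3/4); weighted by support:
    expected = (3 * (2 / 3) + 2 * (1 / 2) + 4 * (3 / 4)) / 9
    assert rep.precision_weighted == pytest.approx(expected)
    assert rep.recall_weighted == pytest.approx(expected)
    assert rep.f1_weighted == pytest.approx(expected)
    assert rep.accuracy == pytest.approx(6 / 9)


def test_absent_class_roc_is_undefined_with_warning():
    y_true = np.array([0, 0, 2, 2])  # no presymptomatic registers in truth
    y_pred = np.array([0, 0, 2, 2])
    with pytest.warns(UserWarning, match="absent"):
        rep = evaluate(y_pred, perfect_scores(y_pred), y_true)
    assert rep.roc["P"] is None
    assert rep.roc["macro"] is not None  # macro over the defined classes


# -------------------------------------------------------------- repeated fits

def test_repeated_fit_single_repeat(rng):
    train, test = random_table(rng, 12), random_table(rng, 8)
    rep = repeated_fit_report(train, test, TreeConfig(n_repeats=1, seed=0))
    assert rep["sd"] == 0.0 and rep["min"] == rep["max"] == rep["mean"]


def test_repeated_fit_deterministic_table_has_zero_spread():
    # class fully determined by card_C: every seed reaches the same pure
    # partition, so all repeat accuracies coincide
    train = make_table(np.arange(1.0, 13.0)[:, None],
                       [2] * 4 + [1] * 4 + [0] * 4, ["card_C"])
    test = make_table(np.array([[2.0], [6.0], [11.0]]), [2, 1, 0], ["card_C"])
    rep = repeated_fit_report(train, test, TreeConfig(n_repeats=20, seed=3))
    assert rep["sd"] == 0.0
    assert rep["min"] == rep["mean"] == rep["max"] == 1.0


def test_repeated_fit_mean_within_range(rng):
    # integer-valued features induce ties, so repeats can genuinely differ
    x = rng.integers(0, 3, (14, 21)).astype(float)
    y = rng.integers(0, 3, 14)
    train = make_table(x, y, feature_subset=FEATURE_NAMES)
    test = random_table(rng, 10)
    rep = repeated_fit_report(train, test, TreeConfig(n_repeats=25, seed=1))
    assert rep["min"] <= rep["mean"] <= rep["max"]
    assert len(rep["accuracies"]) == 25
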