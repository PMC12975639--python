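"""Information gain, deterministic tree/forest learning, category evaluation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from murzyme.featml import (
    FeatureTable,
    entropy,
    evaluate_category,
    information_gain,
    summarize_predictions,
    train_forest,
    train_tree,
)


def table_from(rows, feature_names=None):
    names = feature_names or [f"x{i}" for i in range(len(rows[0]) - 1)]
    df = pd.DataFrame([r[:-1] for r in rows], columns=names)
    df["label"] = [r[-1] for r in rows]
    return FeatureTable(df)


@pytest.mark.parametrize(
    "feature, labels, expected",
    [
        ([0, 0, 1, 1], ["m", "m", "c", "c"], 1.0),      # perfect split, balanced
        ([1, 1, 1, 1], ["m", "m", "c", "c"], 0.0),      # constant feature
        ([1, 1, 1, 0], ["m", "m", "c", "c"], 0.31127812),  # 1 - 3/4 * H(1/3)
    ],
)
def test_information_gain_hand_examples(feature, labels, expected):
    assert information_gain(feature, labels) == pytest.approx(expected, abs=1e-6)


def test_information_gain_errors():
    with pytest.raises(ValueError):
        information_gain([], [])
    with pytest.raises(ValueError):
        information_gain([1, 2], [1])


@given(
    data=st.lists(
        st.tuples(st.integers(0, 1), st.sampled_from(["m", "c"])),
        min_size=1, max_size=30,
    )
)
@settings(max_examples=80, derandomize=True)
def test_information_gain_bounds(data):
    x = [d[0] for d in data]
    y = [d[1] for d in data]
    ig = information_gain(x, y)
    h = entropy(y)
    assert -1e-12 <= ig <= h + 1e-12
    # IG saturates exactly when the feature separates the classes perfectly
    groups = {v: {yy for xx, yy in zip(x, y) if xx == v} for v in set(x)}
    separates = all(len(g) == 1 for g in groups.values())
    if separates:
        assert ig == pytest.approx(h)


def test_single_separating_feature_gives_depth_one_tree():
    t = table_from([(0, 1, "classical"), (0, 0, "classical"),
                    (1, 1, "murzyme"), (1, 0, "murzyme")])
    tree = train_tree(t)
    assert tree.depth == 1
    assert tree.root.feature == "x0"
    assert (tree.predict(t.X) == t.y.to_numpy()).all()


def test_xor_table_needs_depth_two_and_is_learned_exactly():
    t = table_from([(0, 0, "classical"), (1, 1, "classical"),
                    (0, 1, "murzyme"), (1, 0, "murzyme")])
    tree = train_tree(t)
    assert tree.depth == 2
    assert (tree.predict(t.X) == t.y.to_numpy()).all()


def test_tie_break_prefers_first_feature():
    # both features separate perfectly: equal gain, lowest id must win
    t = table_from([(0, 0, "classical"), (0, 0, "classical"),
                    (1, 1, "murzyme"), (1, 1, "murzyme")])
    assert train_tree(t).root.feature == "x0"


def test_single_class_table_warns_and_returns_leaf():
    t = table_from([(0, "murzyme"), (1, "murzyme")], ["x0"])
    with pytest.warns(UserWarning, match="single class"):
        tree = train_tree(t)
    assert tree.depth == 0
    assert (tree.predict(t.X) == "murzyme").all()


def _best_achievable_accuracy(table):
    """Brute-force oracle: the best training accuracy ANY classifier over these
    features can reach is bounded by per-feature-vector label majorities."""
    df = table.df
    correct = 0
    for _, group in df.groupby(table.features):
        correct += group["label"].value_counts().max()
    return correct / len(df)


@given(
    n_features=st.integers(1, 4),
    seed=st.integers(0, 10_000),
)
@settings(max_examples=40, derandomize=True, deadline=None)
def test_greedy_tree_reaches_exhaustive_optimum(n_features, seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 16))
    rows = [
        tuple(int(b) for b in rng.integers(0, 2, n_features))
        + (["classical", "murzyme"][int(rng.integers(0, 2))],)
        for _ in range(n)
    ]
    if len({r[-1] for r in rows}) < 2:
        rows[0] = rows[0][:-1] + ("classical",)
        rows[-1] = rows[-1][:-1] + ("murzyme",)
    t = table_from(rows)
    tree = train_tree(t)
    acc = float(np.mean(tree.predict(t.X) == t.y.to_numpy()))
    assert acc == pytest.approx(_best_achievable_accuracy(t))


def test_tree_agrees_with_sklearn_on_clean_cohort(clean_table):
    """Independent cross-check: an entropy decision tree from scikit-learn
    makes identical training predictions on the trend-clean cohort."""
    from sklearn.tree import DecisionTreeClassifier

    ours = train_tree(clean_table).predict(clean_table.X)
    sk = DecisionTreeClassifier(criterion="entropy", random_state=0)
    sk.fit(clean_table.X, clean_table.y)
    assert (ours == sk.predict(clean_table.X)).all()
    assert (ours == clean_table.y.to_numpy()).all()


def test_degenerate_forest_equals_tree(clean_table):
    forest = train_forest(clean_table, n_trees=1, max_features=None,
                          bootstrap=False, seed=0)
    tree = train_tree(clean_table)
    assert (forest.predict(clean_table.X) == tree.predict(clean_table.X)).all()


def test_forest_is_reproducible_and_accurate(clean_table, holdout_table):
    f1 = train_forest(clean_table, n_trees=30, seed=123)
    f2 = train_forest(clean_table, n_trees=30, seed=123)
    assert (f1.predict(holdout_table.X) == f2.predict(holdout_table.X)).all()
    assert (f1.predict(holdout_table.X) == holdout_table.y.to_numpy()).all()


def test_evaluate_category_clean_cohort(clean_table):
    for category in ("theoretical", "experimental"):
        s = evaluate_category(clean_table, category, n_reps=20, train_frac=0.6, seed=5)
        assert s.accuracy_mean == 1.0
    s = evaluate_category(clean_table, "structural", n_reps=20, train_frac=0.6, seed=5)
    assert 0.9 <= s.accuracy_mean <= 1.0


def test_evaluate_category_unknown_category(clean_table):
    with pytest.raises(ValueError, match="unknown category"):
        evaluate_category(clean_table, "imaginary")


def test_evaluate_shuffled_labels_near_chance(clean_table):
    rng = np.random.default_rng(0)
    df = clean_table.df.copy()
    df["label"] = rng.permutation(df["label"].to_numpy())
    s = evaluate_category(FeatureTable(df), "theoretical", n_reps=20, seed=1)
    assert abs(s.accuracy_mean - 0.5) < 0.15


def test_evaluate_is_seed_deterministic(clean_table):
    a = evaluate_category(clean_table, "structural", n_reps=1, seed=9)
    b = evaluate_category(clean_table, "structural", n_reps=1, seed=9)
    assert a == b


def test_metrics_identities_match_sklearn():
    from sklearn.metrics import precision_recall_fscore_support

    y_true = np.array(["m", "m", "m", "c", "c", "c", "c"])
    y_pred = np.array(["m", "c", "m", "c", "c", "m", "c"])
    s = summarize_predictions([(y_true, y_pred)])
    prec, rec, f1, supp = precision_recall_fscore_support(
        y_true, y_pred, labels=["c", "m"], zero_division=0
    )
    for i, label in enumerate(["c", "m"]):
        d = s.per_class[label]
        assert d["precision"] == pytest.approx(prec[i])
        assert d["recall"] == pytest.approx(rec[i])
        assert d["f1"] == pytest.approx(f1[i])
        assert d["support"] == supp[i]
    assert sum(d["support"] for d in s.per_class.values()) == len(y_true)
    weighted_recall = sum(
        d["recall"] * d["support"] for d in s.per_class.values()
    ) / len(y_true)
    assert s.accuracy_mean == pytest.approx(weighted_recall)
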