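"""Decision-tree and random-forest learning on binary biochemical feature tables.

Systems are described by 20 binary features split into three categories —
structural (heme, flavin, FeS, active-site access, substrate size),
theoretical (redox nature, exergonicity, oxygen need, DRS involvement,
reversibility) and experimental (selectivity, specificity, stoichiometry,
kinetic anomalies, etc.) — with a murzyme/classical label per row.

The tree is grown greedily by maximum information gain

    IG(X) = H(Y) - sum_v p(X=v) * H(Y | X=v),     (log base 2)

with fully deterministic semantics: ties among equal-gain features go to the
left-most (lowest-numbered) feature, growth stops only on leaf purity or
feature exhaustion (so a zero-gain split is still taken while the node is
impure — this is what lets XOR-style tables be learned exactly), and leaf
majority ties resolve to the lexicographically smaller label.  The forest
bags bootstrap replicas of the rows and restricts each split to a random
feature subset; prediction is by majority vote.

Category-wise evaluation repeats stratified train/test splits, retrains on
the training share and averages accuracy and per-class precision/recall/F1
over the repetitions.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "CATEGORIES",
    "FEATURES",
    "FeatureTable",
    "MetricsSummary",
    "TreeModel",
    "ForestModel",
    "entropy",
    "information_gain",
    "train_tree",
    "train_forest",
    "evaluate_category",
]

#: The 20 features by category, in canonical column order.
CATEGORIES: dict[str, tuple[str, ...]] = {
    "structural": (
        "heme",
        "flavin",
        "fes",
        "constrained_access",
        "substrate_larger_than_site",
    ),
    "theoretical": (
        "redox_reaction",
        "exergonic",
        "oxygen_needed",
        "drs_involvement",
        "reversible",
    ),
    "experimental": (
        "substrate_selectivity",
        "product_specificity",
        "modulator_diversity",
        "nonintegral_stoichiometry",
        "variable_stoichiometry",
        "unusual_kinetic_values",
        "kcat_exceeds_diffusion",
        "atypical_substrate_dependence",
        "bulk_phase_dependency",
        "atypical_temperature_dependence",
    ),
}

FEATURES: tuple[str, ...] = sum((CATEGORIES[c] for c in CATEGORIES), ())

LABELS = ("classical", "murzyme")


@dataclass
class FeatureTable:
    """A labeled binary feature table (rows = systems).

    ``df`` holds one column per feature plus a ``label`` column; extra
    columns (beyond the canonical 20) are allowed and treated as features.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "label" not in self.df.columns:
            raise ValueError("feature table needs a 'label' column")
        if len(self.df) == 0:
            raise ValueError("feature table is empty")
        bad = set(self.df["label"]) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @property
    def features(self) -> list[str]:
        return [c for c in self.df.columns if c != "label"]

    @property
    def X(self) -> pd.DataFrame:
        return self.df[self.features]

    @property
    def y(self) -> pd.Series:
        return self.df["label"]

    def restrict(self, category: str) -> "FeatureTable":
        """Keep only one category's feature columns (plus the label)."""
        if category not in CATEGORIES:
            raise ValueError(
                f"unknown category {category!r}; expected one of {list(CATEGORIES)}"
            )
        cols = [c for c in CATEGORIES[category] if c in self.df.columns]
        if not cols:
            raise ValueError(f"table has no columns from category {category!r}")
        return FeatureTable(self.df[cols + ["label"]].copy())

    @classmethod
    def read_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Entropy / information gain
# ---------------------------------------------------------------------------

def entropy(labels: Sequence) -> float:
    """Shannon entropy of a label vector, in bits."""
    n = len(labels)
    if n == 0:
        raise ValueError("entropy of an empty vector is undefined")
    counts = Counter(labels)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def information_gain(feature_column: Sequence, labels: Sequence) -> float:
    """Reduction in label entropy from conditioning on a feature, in bits."""
    x = list(feature_column)
    y = list(labels)
    if len(x) != len(y):
        raise ValueError("feature and label vectors must have equal length")
    if not x:
        raise ValueError("information gain of empty input is undefined")
    n = len(y)
    cond = 0.0
    for v in set(x):
        idx = [i for i, xv in enumerate(x) if xv == v]
        cond += (len(idx) / n) * entropy([y[i] for i in idx])
    return entropy(y) - cond


def _gini_gain(feature_column: Sequence, labels: Sequence) -> float:
    def gini(ys):
        n = len(ys)
        return 1.0 - sum((c / n) ** 2 for c in Counter(ys).values())

    x, y = list(feature_column), list(labels)
    n = len(y)
    cond = 0.0
    for v in set(x):
        idx = [i for i, xv in enumerate(x) if xv == v]
        cond += (len(idx) / n) * gini([y[i] for i in idx])
    return gini(y) - cond


_GAIN = {"information-gain": information_gain, "gini": _gini_gain}


# ---------------------------------------------------------------------------
# Decision tree
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    label: Optional[str] = None  # leaf prediction
    feature: Optional[str] = None  # internal split feature
    children: dict = field(default_factory=dict)  # feature value -> _Node
    majority: Optional[str] = None  # fallback for unseen branch values

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(c.depth() for c in self.children.values())


def _majority(labels: Sequence[str]) -> str:
    counts = Counter(labels)
    top = max(counts.values())
    return min(l for l, c in counts.items() if c == top)  # deterministic tie-break


@dataclass
class TreeModel:
    """A fitted decision tree over discrete features."""

    root: _Node
    features: tuple[str, ...]
    criterion: str

    def predict_one(self, row) -> str:
        node = self.root
        while not node.is_leaf:
            child = node.children.get(row[node.feature])
            if child is None:
                return node.majority
            node = child
        return node.label

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.array([self.predict_one(r) for _, r in X.iterrows()])

    @property
    def depth(self) -> int:
        return self.root.depth()


def _grow(
    X: pd.DataFrame,
    y: list[str],
    features: list[str],
    gain_fn,
    rng: Optional[np.random.Generator],
    max_features: Optional[int],
) -> _Node:
    majority = _majority(y)
    if len(set(y)) == 1 or not features:
        return _Node(label=majority)
    if rng is not None and max_features is not None and max_features < len(features):
        pool_idx = sorted(rng.choice(len(features), size=max_features, replace=False))
        pool = [features[i] for i in pool_idx]
    else:
        pool = features
    # max gain; ties go to the first (lowest-numbered) feature in column order
    gains = [gain_fn(X[f].tolist(), y) for f in pool]
    best = pool[int(np.argmax(gains))]
    node = _Node(feature=best, majority=majority)
    remaining = [f for f in features if f != best]
    values = sorted(set(X[best]))
    for v in values:
        mask = X[best] == v
        node.children[v] = _grow(
            X[mask], [yy for yy, m in zip(y, mask) if m], remaining, gain_fn, rng, max_features
        )
    # a binary feature seen single-valued here: route the unseen value via majority
    return node


def train_tree(
    table: FeatureTable,
    criterion: str = "information-gain",
    _rng: Optional[np.random.Generator] = None,
    _max_features: Optional[int] = None,
) -> TreeModel:
    """Grow a deterministic greedy decision tree on a labeled table.

    Growth stops on leaf purity or feature exhaustion; each feature is used
    at most once per root-to-leaf path.  A single-class table yields a
    degenerate one-leaf tree (with a warning).
    """
    if criterion not in _GAIN:
        raise ValueError(f"unknown criterion {criterion!r}; expected one of {list(_GAIN)}")
    y = table.y.tolist()
    if len(set(y)) < 2:
        warnings.warn("training table contains a single class; tree is one leaf")
    root = _grow(table.X, y, table.features, _GAIN[criterion], _rng, _max_features)
    return TreeModel(root=root, features=tuple(table.features), criterion=criterion)


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------

@dataclass
class ForestModel:
    trees: tuple[TreeModel, ...]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        votes = np.stack([t.predict(X) for t in self.trees])
        out = []
        for j in range(votes.shape[1]):
            out.append(_majority(list(votes[:, j])))
        return np.array(out)


def train_forest(
    table: FeatureTable,
    n_trees: int = 100,
    max_features: int | str | None = "sqrt",
    seed: int = 0,
    bootstrap: bool = True,
    criterion: str = "information-gain",
) -> ForestModel:
    """Bagged ensemble of randomized trees with majority-vote prediction.

    Defaults follow standard practice: 100 trees, sqrt(p) features considered
    per split, bootstrap resampling of rows.  Fully reproducible under
    ``seed``.  With ``n_trees=1``, ``max_features=None`` and ``bootstrap``
    off this degenerates to :func:`train_tree`.
    """
    p = len(table.features)
    if max_features == "sqrt":
        mf: Optional[int] = max(1, int(math.sqrt(p)))
    elif max_features is None:
        mf = None
    else:
        mf = int(max_features)
    rng = np.random.default_rng(seed)
    trees = []
    n = len(table.df)
    for _ in range(n_trees):
        if bootstrap:
            idx = rng.integers(0, n, size=n)
            sub = FeatureTable(table.df.iloc[idx].reset_index(drop=True))
        else:
            sub = table
        trees.append(train_tree(sub, criterion=criterion, _rng=rng, _max_features=mf))
    return ForestModel(trees=tuple(trees))


# ---------------------------------------------------------------------------
# Repeated-split evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricsSummary:
    """Accuracy and per-class precision/recall/F1/support over repeated splits."""

    accuracy_mean: float
    accuracy_std: float
    n_reps: int
    per_class: dict[str, dict[str, float]]  # label -> precision/recall/f1/support

    def to_dict(self) -> dict:
        return {
            "accuracy_mean": self.accuracy_mean,
            "accuracy_std": self.accuracy_std,
            "n_reps": self.n_reps,
            "per_class": self.per_class,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_text(self) -> str:
        """Plain-text report: one row per metric, one column per class."""
        labels = sorted(self.per_class)
        lines = [
            "{:<22}".format("Metric") + "".join(f"{l:>12}" for l in labels)
        ]
        for metric in ("precision", "recall", "f1"):
            lines.append(
                "{:<22}".format(metric.capitalize())
                + "".join(f"{self.per_class[l][metric]:>12.4f}" for l in labels)
            )
        lines.append(
            "{:<22}".format("Support")
            + "".join(f"{self.per_class[l]['support']:>12.1f}" for l in labels)
        )
        lines.append(f"Accuracy (mean of {self.n_reps}): {self.accuracy_mean:.4f}"
                     f" (sd {self.accuracy_std:.4f})")
        return "\n".join(lines)


def summarize_predictions(reps: list[tuple[np.ndarray, np.ndarray]]) -> MetricsSummary:
    """Average accuracy and per-class metrics over (y_true, y_pred) pairs.

    Precision for a class absent from the predictions (zero division) counts
    as 0, with a warning.
    """
    labels = sorted({str(l) for yt, _ in reps for l in yt})
    accs = []
    agg = {l: {"precision": [], "recall": [], "f1": [], "support": []} for l in labels}
    zero_div = False
    for y_true, y_pred in reps:
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        accs.append(float(np.mean(y_true == y_pred)))
        for l in labels:
            tp = int(np.sum((y_pred == l) & (y_true == l)))
            pred_p = int(np.sum(y_pred == l))
            true_p = int(np.sum(y_true == l))
            if pred_p == 0 or true_p == 0:
                zero_div = zero_div or (pred_p == 0 and true_p > 0)
            prec = tp / pred_p if pred_p else 0.0
            rec = tp / true_p if true_p else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            agg[l]["precision"].append(prec)
            agg[l]["recall"].append(rec)
            agg[l]["f1"].append(f1)
            agg[l]["support"].append(float(true_p))
    if zero_div:
        warnings.warn("a class was never predicted in at least one repetition; "
                      "its precision was taken as 0")
    per_class = {
        l: {k: float(np.mean(v)) for k, v in d.items()} for l, d in agg.items()
    }
    return MetricsSummary(
        accuracy_mean=float(np.mean(accs)),
        accuracy_std=float(np.std(accs)),
        n_reps=len(reps),
        per_class=per_class,
    )


def evaluate_category(
    table: FeatureTable,
    category: str,
    n_reps: int = 20,
    train_frac: float = 0.6,
    seed: int = 0,
    model: str = "tree",
    **model_kw,
) -> MetricsSummary:
    """Repeated stratified-split evaluation restricted to one feature category.

    For each repetition the rows are split ``train_frac`` / ``1 - train_frac``
    with class proportions preserved, a fresh tree (or forest) is trained on
    the training share, and test-set metrics are recorded; results are
    averaged over ``n_reps`` repetitions.
    """
    sub = table.restrict(category) if category != "all" else table
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        split_seed = int(rng.integers(0, 2**31 - 1))
        train_idx, test_idx = train_test_split(
            np.arange(len(sub.df)),
            train_size=train_frac,
            random_state=split_seed,
            stratify=sub.y,
        )
        train = FeatureTable(sub.df.iloc[train_idx].reset_index(drop=True))
        test = FeatureTable(sub.df.iloc[test_idx].reset_index(drop=True))
        if model == "tree":
            fitted = train_tree(train, **model_kw)
        elif model == "forest":
            fitted = train_forest(train, seed=int(rng.integers(0, 2**31 - 1)), **model_kw)
        else:
            raise ValueError(f"unknown model {model!r}")
        reps.append((test.y.to_numpy(), fitted.predict(test.X)))
    return summarize_predictions(reps)
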