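"""Confusion-matrix metrics, cross-validation, tree learners, coverage curves.

Metrics follow the usual conventions, reported as percentages:
precision = 100*TP/(TP+FP), recall = 100*TP/(TP+FN), F1 the harmonic mean of
the two, accuracy = 100*(TP+TN)/total, with zero-denominator cases defined
as zero.  Printed values round half-up to two decimals.

Cross-validation is stratified k-fold; the per-fold test confusion matrices
are summed into one aggregate whose total equals the corpus size, which is
how whole-corpus TP/FP/FN/TN tables are produced.

Two interchangeable tree learners satisfy the two-method fit/predict
contract: a scikit-learn CART wrapper (the default) and a minimal
dependency-free gini-split implementation retained as a cross-check.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Optional, Protocol, Sequence

import numpy as np

from ratechange_miner.feature_extraction import FeatureVector
from ratechange_miner.lexicon_ontology import Ontology, TextualPattern

__all__ = [
    "ConfusionMatrix", "Metrics", "CVConfig", "round_half_up",
    "compute_metrics", "vectorize_features", "train_tree",
    "SklearnTreeLearner", "MinimalCART", "run_cv", "coverage_curve",
]

POSITIVE = "positive"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching conventional table printing."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )

    @classmethod
    def from_labels(
        cls, y_true: Sequence[str], y_pred: Sequence[str], positive: str = POSITIVE
    ) -> "ConfusionMatrix":
        if len(y_true) != len(y_pred):
            raise ValueError("label sequences differ in length")
        tp = fp = fn = tn = 0
        for t, p in zip(y_true, y_pred):
            if p == positive:
                if t == positive:
                    tp += 1
                else:
                    fp += 1
            else:
                if t == positive:
                    fn += 1
                else:
                    tn += 1
        return cls(tp, fp, fn, tn)


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float
    accuracy: float

    def rounded(self, ndigits: int = 2) -> "Metrics":
        return Metrics(*(round_half_up(v, ndigits) for v in
                         (self.precision, self.recall, self.f1, self.accuracy)))


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Precision/recall/F1/accuracy percentages from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precision = 100.0 * cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else 0.0
    recall = 100.0 * cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    return Metrics(precision, recall, f1, accuracy)


# ---------------------------------------------------------------------------
# Tree learners (fit/predict contract)


class Learner(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Learner": ...
    def predict(self, X: np.ndarray) -> np.ndarray: ...


class SklearnTreeLearner:
    """CART decision tree via scikit-learn, deterministic under a fixed seed."""

    def __init__(self, seed: int = 0, **kwargs):
        from sklearn.tree import DecisionTreeClassifier

        self._tree = DecisionTreeClassifier(random_state=seed, **kwargs)
        self._constant: Optional[int] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SklearnTreeLearner":
        if len(np.unique(y)) < 2:
            warnings.warn("single-class training set: constant predictor")
            self._constant = int(y[0]) if len(y) else 0
            return self
        self._tree.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._constant is not None:
            return np.full(X.shape[0], self._constant, dtype=int)
        return self._tree.predict(X)


class MinimalCART:
    """Minimal binary gini-split decision tree (dependency-free cross-check).

    Splits on one binary feature at a time, greedily by gini impurity
    reduction, ties broken by lowest feature index; leaves predict the
    majority class (ties -> class 0).
    """

    def __init__(self, max_depth: int = 12, min_samples_split: int = 2, seed: int = 0):
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self._root: Optional[dict] = None

    @staticmethod
    def _gini(y: np.ndarray) -> float:
        if len(y) == 0:
            return 0.0
        p = np.bincount(y, minlength=2) / len(y)
        return 1.0 - float(np.sum(p * p))

    @staticmethod
    def _majority(y: np.ndarray) -> int:
        counts = np.bincount(y, minlength=2)
        return int(np.argmax(counts))  # argmax -> lowest index on ties

    def _build(self, X: np.ndarray, y: np.ndarray, depth: int) -> dict:
        if (
            depth >= self.max_depth
            or len(y) < self.min_samples_split
            or len(np.unique(y)) == 1
        ):
            return {"leaf": self._majority(y)}
        parent = self._gini(y)
        best_gain, best_j = 0.0, -1
        for j in range(X.shape[1]):
            mask = X[:, j] == 1
            n1 = int(mask.sum())
            if n1 == 0 or n1 == len(y):
                continue
            w = n1 / len(y)
            gain = parent - w * self._gini(y[mask]) - (1 - w) * self._gini(y[~mask])
            if gain > best_gain + 1e-12:
                best_gain, best_j = gain, j
        if best_j < 0:
            return {"leaf": self._majority(y)}
        mask = X[:, best_j] == 1
        return {
            "feature": best_j,
            "on": self._build(X[mask], y[mask], depth + 1),
            "off": self._build(X[~mask], y[~mask], depth + 1),
        }

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MinimalCART":
        X = np.asarray(X)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            warnings.warn("single-class training set: constant predictor")
        self._root = self._build(X, y, 0)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        out = np.empty(X.shape[0], dtype=int)
        for i, row in enumerate(X):
            node = self._root
            while "leaf" not in node:
                node = node["on"] if row[node["feature"]] == 1 else node["off"]
            out[i] = node["leaf"]
        return out


def train_tree(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    learner_factory: Optional[Callable[[int], Learner]] = None,
) -> Learner:
    """Fit a decision tree (default: scikit-learn CART) under a fixed seed."""
    factory = learner_factory or (lambda s: SklearnTreeLearner(seed=s))
    return factory(seed).fit(np.asarray(X), np.asarray(y, dtype=int))


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass(frozen=True)
class CVConfig:
    k: int = 10
    seed: int = 7
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


def vectorize_features(
    vectors: Sequence[FeatureVector] | Sequence[frozenset[str]],
) -> tuple[np.ndarray, list[str]]:
    """Binary design matrix over the sorted union of feature keys."""
    sets = [
        fv.features if isinstance(fv, FeatureVector) else frozenset(fv)
        for fv in vectors
    ]
    keys = sorted(set().union(*sets)) if sets else []
    idx = {k: j for j, k in enumerate(keys)}
    X = np.zeros((len(sets), len(keys)), dtype=np.int8)
    for i, s in enumerate(sets):
        for k in s:
            X[i, idx[k]] = 1
    return X, keys


def run_cv(
    vectors: Sequence[FeatureVector] | Sequence[frozenset[str]] | np.ndarray,
    labels: Sequence[str] | Sequence[int],
    config: CVConfig = CVConfig(),
    learner_factory: Optional[Callable[[int], Learner]] = None,
) -> tuple[ConfusionMatrix, Metrics, list[ConfusionMatrix]]:
    """Stratified k-fold CV; per-fold test confusion matrices summed.

    The aggregate total equals the instance count, so whole-corpus
    TP/FP/FN/TN tables fall out directly.  Fold assignment is deterministic
    under the config seed.
    """
    if isinstance(vectors, np.ndarray):
        X = vectors
    else:
        X, _ = vectorize_features(vectors)
    y = np.array([1 if lab in (1, POSITIVE) else 0 for lab in labels], dtype=int)
    n = len(y)
    if config.k > n:
        raise ValueError(f"k={config.k} exceeds instance count {n}")

    from sklearn.model_selection import KFold, StratifiedKFold

    if config.stratified and min(np.bincount(y, minlength=2)) >= config.k:
        splitter = StratifiedKFold(n_splits=config.k, shuffle=True,
                                   random_state=config.seed)
    else:
        splitter = KFold(n_splits=config.k, shuffle=True, random_state=config.seed)

    folds: list[ConfusionMatrix] = []
    for train_idx, test_idx in splitter.split(X, y):
        learner = train_tree(X[train_idx], y[train_idx], seed=config.seed,
                             learner_factory=learner_factory)
        pred = learner.predict(X[test_idx])
        folds.append(ConfusionMatrix(
            tp=int(np.sum((pred == 1) & (y[test_idx] == 1))),
            fp=int(np.sum((pred == 1) & (y[test_idx] == 0))),
            fn=int(np.sum((pred == 0) & (y[test_idx] == 1))),
            tn=int(np.sum((pred == 0) & (y[test_idx] == 0))),
        ))
    aggregate = sum(folds[1:], folds[0])
    return aggregate, compute_metrics(aggregate), folds


# ---------------------------------------------------------------------------
# Ontology coverage curve


def coverage_curve(
    sentences: Sequence[Sequence[str]],
    patterns: Sequence[TextualPattern] | Ontology,
    n_shuffles: int = 100,
    seed: int = 7,
) -> np.ndarray:
    """Average cumulative fraction of textual patterns seen vs sentences read.

    Sentences (as normalized token sequences) are shuffled ``n_shuffles``
    times; for each shuffle the curve at prefix length j is the fraction of
    patterns firing in at least one of the first j sentences.  The returned
    average curve has one entry per prefix length 1..len(sentences).
    """
    pats = patterns.patterns if isinstance(patterns, Ontology) else tuple(patterns)
    if not pats:
        raise ValueError("patterns must be nonempty")
    fired_sets = [
        frozenset(i for i, p in enumerate(pats) if p.fires(tuple(toks)))
        for toks in sentences
    ]
    n = len(fired_sets)
    rng = random.Random(seed)
    total = np.zeros(n)
    order = list(range(n))
    for _ in range(n_shuffles):
        rng.shuffle(order)
        seen: set[int] = set()
        for j, idx in enumerate(order):
            seen |= fired_sets[idx]
            total[j] += len(seen)
    return total / (n_shuffles * len(pats))
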