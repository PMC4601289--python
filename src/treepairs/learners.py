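"""Tree-ensemble base learner shared by the global and local approaches.

Both approaches reduce network inference to binary classification with
class-probability outputs.  The base learner is an ensemble of extremely
randomized trees (extra-trees): each internal node picks the best of K
fully random candidate splits, with K defaulting to the square root of the
number of candidate attributes, 100 trees, and no bootstrap resampling.
Bootstrapping is recommended (and exposed) when all features are binary,
where random cut-points alone cannot produce tree diversity.

Trees natively extend to vector outputs (the split score averages the
impurity reduction over outputs), which the local multiple-output variant
relies on; ``train_ensemble`` accepts a label vector or a 0/1 label matrix
and the same contract covers both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier

__all__ = [
    "LearnerParams",
    "EnsembleModel",
    "train_ensemble",
    "predict_proba",
    "feature_importances",
    "leaf_assignments",
]


@dataclass(frozen=True)
class LearnerParams:
    """Hyper-parameters of the extra-trees ensemble.

    ``k_features`` may be an integer or ``"sqrt"``, which resolves to
    round(sqrt(p)) for the p columns actually seen at fit time (for the
    global approach p is the concatenated row+column dimension).
    ``laplace`` > 0 applies additive smoothing (n1+a)/(n+2a) to leaf
    class frequencies; the default is the raw frequency.
    """

    n_trees: int = 100
    k_features: int | str = "sqrt"
    bootstrap: bool = False
    seed: int = 0
    min_samples_split: int = 2
    laplace: float = 0.0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.k_features != "sqrt" and (
            not isinstance(self.k_features, (int, np.integer)) or self.k_features < 1
        ):
            raise ValueError("k_features must be 'sqrt' or a positive integer")

    def resolve_k(self, n_features: int) -> int:
        if self.k_features == "sqrt":
            return max(1, round(float(np.sqrt(n_features))))
        if self.k_features > n_features:
            raise ValueError(
                f"k_features={self.k_features} exceeds {n_features} attributes"
            )
        return int(self.k_features)

    def with_seed(self, seed: int) -> "LearnerParams":
        return LearnerParams(
            self.n_trees, self.k_features, self.bootstrap, int(seed),
            self.min_samples_split, self.laplace,
        )


@dataclass
class EnsembleModel:
    """A fitted ensemble with its probability/importance/leaf contracts."""

    estimator: ExtraTreesClassifier = field(repr=False)
    n_outputs: int
    n_features: int
    prevalence: np.ndarray  # training P(y=1) per output
    params: LearnerParams
    feature_names: list[str] | None = None


def train_ensemble(X, Y, params: LearnerParams) -> EnsembleModel:
    """Fit an extra-trees ensemble on labels ``Y`` (vector or 0/1 matrix).

    Deterministic for a given seed.  Single-class labels (overall or in any
    output column) are not an error: the fitted model is constant at the
    observed prevalence for that output.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y row counts differ")
    if X.shape[0] < 1:
        raise ValueError("need at least one training sample")
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if Y.ndim == 2 and Y.shape[1] == 1:
        Y = Y[:, 0]
    est = ExtraTreesClassifier(
        n_estimators=params.n_trees,
        max_features=params.resolve_k(X.shape[1]),
        bootstrap=params.bootstrap,
        min_samples_split=params.min_samples_split,
        criterion="gini",
        random_state=params.seed,
        n_jobs=1,
    )
    est.fit(X, Y.astype(int))
    prevalence = np.atleast_1d(np.asarray(Y, dtype=float).mean(axis=0))
    n_outputs = 1 if Y.ndim == 1 else Y.shape[1]
    return EnsembleModel(est, n_outputs, X.shape[1], prevalence, params)


def _proba_one_output(proba: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Extract P(y=1) from an sklearn (n, n_classes) probability block."""
    classes = np.asarray(classes)
    where = np.flatnonzero(classes == 1)
    if where.size:
        return proba[:, where[0]]
    return np.zeros(proba.shape[0])


def predict_proba(model: EnsembleModel, X) -> np.ndarray:
    """Predicted probability of class 1: mean over trees of leaf frequencies.

    Returns shape (n,) for single-output models and (n, n_outputs)
    otherwise; values are in [0, 1].
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} feature columns, got {X.shape}"
        )
    if model.params.laplace > 0:
        return _predict_proba_smoothed(model, X)
    raw = model.estimator.predict_proba(X)
    if model.n_outputs == 1:
        return _proba_one_output(raw, model.estimator.classes_)
    return np.column_stack(
        [_proba_one_output(p, c) for p, c in zip(raw, model.estimator.classes_)]
    )


def _predict_proba_smoothed(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Laplace-smoothed leaf frequencies, averaged over trees."""
    a = model.params.laplace
    est = model.estimator
    out = np.zeros((X.shape[0], model.n_outputs))
    for tree in est.estimators_:
        leaves = tree.apply(X)
        t = tree.tree_
        n = t.weighted_n_node_samples[leaves]
        for k in range(model.n_outputs):
            classes = est.classes_ if model.n_outputs == 1 else est.classes_[k]
            frac = _proba_one_output(t.value[leaves, k, :], classes)
            out[:, k] += (frac * n + a) / (n + 2 * a)
    out /= est.n_estimators
    return out[:, 0] if model.n_outputs == 1 else out


def feature_importances(model: EnsembleModel) -> np.ndarray:
    """Impurity-reduction importances, normalized to sum to 1.

    A model that never splits (constant labels) returns the all-zero
    vector.
    """
    imp = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = imp.sum()
    return imp / total if total > 0 else imp


def leaf_assignments(model: EnsembleModel, X) -> np.ndarray:
    """Leaf index of each sample in each tree, shape (n_samples, n_trees)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} feature columns, got {X.shape}"
        )
    return model.estimator.apply(X)
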