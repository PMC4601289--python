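"""Global approach: one ensemble over concatenated node-feature pairs.

A pair (n_r, n_c) becomes a single instance whose input vector is the
concatenation x(n_r) | x(n_c); one tree ensemble is trained over all
labeled pairs.  For homogeneous (symmetric) networks each training pair is
presented in both orderings, and predictions are symmetrized by combining
the two orderings' probabilities, so that predict(a, b) == predict(b, a)
exactly.

The trained trees carry an interpretable structure: every leaf collects a
set of training pairs forming a rectangular submatrix (bicluster) of the
adjacency matrix, characterized by the root-to-leaf feature tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .learners import (
    EnsembleModel,
    LearnerParams,
    feature_importances,
    leaf_assignments,
    predict_proba,
    train_ensemble,
)
from .network import Network, PairSample, known_pairs

__all__ = [
    "GlobalPairModel",
    "GlobalPairResults",
    "build_pair_matrix",
    "train_global",
    "predict_pairs_global",
]


def build_pair_matrix(
    net: Network, pairs: PairSample, duplicate_symmetric: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated feature matrix and labels for a sample of pairs.

    Row i of X is concat(x(row_i), x(col_i)).  If the network is
    homogeneous and ``duplicate_symmetric`` is set, every pair additionally
    contributes the swapped ordering with the same label (2*len(pairs)
    rows, originals first).
    """
    Xr = net.rows.features[pairs.row_idx]
    Xc = net.cols.features[pairs.col_idx]
    X = np.hstack([Xr, Xc])
    y = pairs.labels.astype(int)
    if net.homogeneous and duplicate_symmetric:
        X = np.vstack([X, np.hstack([Xc, Xr])])
        y = np.concatenate([y, y])
    return X, y


@dataclass
class GlobalPairModel:
    """Model specification for the global approach on one network.

    Parameters
    ----------
    net : Network
    params : LearnerParams
        Ensemble hyper-parameters (trees, K, bootstrap, seed).
    symmetric_combine : {"mean", "max"}
        How the two orderings' probabilities are combined on homogeneous
        networks; the arithmetic mean keeps predictions exactly
        swap-invariant and is the default.
    """

    net: Network
    params: LearnerParams = field(default_factory=LearnerParams)
    symmetric_combine: str = "mean"

    def __post_init__(self) -> None:
        if self.symmetric_combine not in ("mean", "max"):
            raise ValueError("symmetric_combine must be 'mean' or 'max'")

    def fit(self, pairs: PairSample | None = None) -> "GlobalPairResults":
        """Train the ensemble on ``pairs`` (default: all known pairs)."""
        if pairs is None:
            pairs = known_pairs(self.net)
        if len(pairs) == 0:
            raise ValueError("empty learning sample")
        X, y = build_pair_matrix(self.net, pairs, duplicate_symmetric=True)
        ensemble = train_ensemble(X, y, self.params)
        ensemble.feature_names = [
            f"r:{n}" for n in self.net.rows.feature_names
        ] + [f"c:{n}" for n in self.net.cols.feature_names]
        return GlobalPairResults(self, ensemble, pairs)


@dataclass
class GlobalPairResults:
    """Fitted global model: pair scoring, importances, leaf biclusters."""

    model: GlobalPairModel
    ensemble: EnsembleModel
    train_pairs: PairSample

    @property
    def net(self) -> Network:
        return self.model.net

    def predict(self, row_idx, col_idx) -> np.ndarray:
        """Probability of an edge for each (row, col) index pair."""
        return predict_pairs_global(self, row_idx, col_idx)

    @property
    def feature_importances_(self) -> pd.Series:
        """Global ranking over concatenated row+column features (sums to 1)."""
        return pd.Series(
            feature_importances(self.ensemble), index=self.ensemble.feature_names
        )

    def biclusters(self, tree_index: int = 0) -> pd.DataFrame:
        """Leaf biclusters of one tree over the training pairs.

        Each leaf of a global tree gathers a set of training pairs — a
        rectangular submatrix of the adjacency — that the tree tried to
        make all-connected or all-disconnected.  Returns one row per leaf
        with member nodes, edge count, edge purity (fraction of label-1
        pairs) and the root-to-leaf feature tests, sorted by edge count.
        """
        X, y = build_pair_matrix(self.net, self.train_pairs, duplicate_symmetric=False)
        leaves = leaf_assignments(self.ensemble, X)[:, tree_index]
        tree = self.ensemble.estimator.estimators_[tree_index].tree_
        paths = _leaf_paths(tree, self.ensemble.feature_names)
        rows = []
        for leaf in np.unique(leaves):
            mask = leaves == leaf
            rows.append(
                {
                    "leaf": int(leaf),
                    "n_pairs": int(mask.sum()),
                    "n_edges": int(y[mask].sum()),
                    "purity": float(y[mask].mean()),
                    "row_nodes": ";".join(
                        self.net.rows.ids[i]
                        for i in sorted(set(self.train_pairs.row_idx[mask]))
                    ),
                    "col_nodes": ";".join(
                        self.net.cols.ids[j]
                        for j in sorted(set(self.train_pairs.col_idx[mask]))
                    ),
                    "path": paths[int(leaf)],
                }
            )
        return (
            pd.DataFrame(rows)
            .sort_values("n_edges", ascending=False)
            .reset_index(drop=True)
        )

    def summary(self) -> str:
        net = self.net
        kind = "homogeneous" if net.homogeneous else "bipartite"
        top = self.feature_importances_.sort_values(ascending=False).head(5)
        lines = [
            "Global pairwise extra-trees model",
            f"  network: {kind} {net.shape[0]}x{net.shape[1]}",
            f"  training pairs: {len(self.train_pairs)} "
            f"(prevalence {self.train_pairs.prevalence:.4f})",
            f"  trees: {self.ensemble.params.n_trees}, "
            f"K: {self.ensemble.params.resolve_k(self.ensemble.n_features)}",
            "  top features: "
            + ", ".join(f"{n}={v:.3f}" for n, v in top.items()),
        ]
        return "\n".join(lines)


def train_global(
    net: Network, ls: PairSample, params: LearnerParams
) -> GlobalPairResults:
    """Functional form of :meth:`GlobalPairModel.fit`."""
    return GlobalPairModel(net, params).fit(ls)


def predict_pairs_global(results: GlobalPairResults, row_idx, col_idx) -> np.ndarray:
    """Score query pairs with a fitted global model.

    Bipartite: f(x_r | x_c).  Homogeneous: the two orderings' probabilities
    are combined (mean by default) so the output is swap-invariant.
    """
    net = results.net
    row_idx = np.asarray(row_idx, dtype=np.intp)
    col_idx = np.asarray(col_idx, dtype=np.intp)
    Xr = net.rows.features[row_idx]
    Xc = net.cols.features[col_idx]
    p1 = predict_proba(results.ensemble, np.hstack([Xr, Xc]))
    if not net.homogeneous:
        return p1
    p2 = predict_proba(results.ensemble, np.hstack([Xc, Xr]))
    if results.model.symmetric_combine == "max":
        return np.maximum(p1, p2)
    return 0.5 * (p1 + p2)


def _leaf_paths(tree, feature_names) -> dict[int, str]:
    """Human-readable root-to-leaf test conjunction for every leaf."""
    paths: dict[int, str] = {}

    def descend(node: int, conds: list[str]) -> None:
        if tree.children_left[node] == -1:
            paths[node] = " & ".join(conds) if conds else "(root)"
            return
        feat = feature_names[tree.feature[node]]
        thr = tree.threshold[node]
        descend(tree.children_left[node], conds + [f"{feat} <= {thr:.4g}"])
        descend(tree.children_right[node], conds + [f"{feat} > {thr:.4g}"])

    descend(0, [])
    return paths
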