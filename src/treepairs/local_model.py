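"""Local approach: per-node (single-output) or per-family (multi-output)
interaction-profile models, with a two-step procedure for pairs of unseen
nodes.

Single-output variant: for every column node seen in the learning sample a
separate classifier is trained on the row-feature vectors of its labeled
partners (and symmetrically per row node).  A pair of two seen nodes is
scored by the arithmetic mean of its two per-node predictions; a pair with
one unseen node uses the seen node's model alone.

Multi-output variant: two ensembles only — row features -> interaction
profile over the seen columns, and column features -> profile over the seen
rows.  It requires the seen-rows x seen-columns adjacency block to be fully
observed, because multi-output trees cannot handle missing outputs.

Two-step procedure for pairs of two unseen nodes: first-step models fill
in the unseen-row x seen-column (and seen-row x unseen-column) blocks;
those scores are binarized so that the predicted edge proportion matches
the learning sample's edge prevalence; second-step models are then trained
on the binarized blocks and their predictions averaged.  With the
multi-output variant this makes four tree ensembles in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from ._seeds import child_seed
from .learners import EnsembleModel, LearnerParams, predict_proba, train_ensemble
from .network import Network, PairSample

__all__ = [
    "ThresholdRule",
    "ThresholdChoice",
    "LocalSOModel",
    "LocalMOModel",
    "TwoStepModels",
    "LocalPairModel",
    "LocalPairResults",
    "train_local_so",
    "train_local_mo",
    "predict_lsls_local",
    "predict_lsts_local",
    "predict_tsts_local",
    "choose_threshold",
    "binarize_scores",
    "two_step_train",
]


# --------------------------------------------------------------------------
# thresholding


@dataclass(frozen=True)
class ThresholdRule:
    """Binarization rule for step-1 scores: keep the predicted edge
    proportion equal to ``target_proportion`` (the learning sample's edge
    prevalence)."""

    target_proportion: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_proportion <= 1.0:
            raise ValueError("target_proportion must be in [0, 1]")


class ThresholdChoice(NamedTuple):
    cutoff: float
    n_positive: int


def choose_threshold(scores, rule: ThresholdRule) -> ThresholdChoice:
    """Cutoff so the fraction of scores strictly above it is the largest
    fraction not exceeding the target proportion.

    Returns the cutoff and the count m = floor(target * N) of pairs that
    binarization will mark positive (ties at the cutoff are resolved by
    :func:`binarize_scores`).
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n == 0:
        raise ValueError("empty score list")
    m = int(np.floor(rule.target_proportion * n + 1e-12))
    if m == 0:
        return ThresholdChoice(float(scores.max()), 0)
    if m >= n:
        return ThresholdChoice(-np.inf, n)
    order = np.sort(scores)[::-1]
    return ThresholdChoice(float(order[m]), m)


def binarize_scores(
    scores, row_idx, col_idx, rule: ThresholdRule
) -> np.ndarray:
    """0/1 labels for step-1 scores under the proportion-matching rule.

    Exactly m = floor(target * N) scores are marked positive: all scores
    strictly above the cutoff, then scores tied at the cutoff admitted in
    ascending (row index, col index) order until m is reached.
    """
    scores = np.asarray(scores, dtype=float)
    row_idx = np.asarray(row_idx)
    col_idx = np.asarray(col_idx)
    cutoff, m = choose_threshold(scores, rule)
    out = np.zeros(scores.size, dtype=np.int8)
    if m == 0:
        return out
    above = scores > cutoff
    out[above] = 1
    remaining = m - int(above.sum())
    if remaining > 0:
        tied = np.flatnonzero(scores == cutoff)
        order = np.lexsort((col_idx[tied], row_idx[tied]))
        out[tied[order[:remaining]]] = 1
    return out


# --------------------------------------------------------------------------
# model containers


@dataclass
class LocalSOModel:
    """Per-node single-output models.

    ``col_models[j]`` predicts interaction with column node j from row
    features; ``row_models[i]`` predicts interaction with row node i from
    column features.  Homogeneous networks hold a single family in
    ``col_models`` (== ``row_models``): one model per node over node
    features.
    """

    net: Network = field(repr=False)
    params: LearnerParams
    col_models: dict[int, EnsembleModel] = field(repr=False)
    row_models: dict[int, EnsembleModel] = field(repr=False)
    ls_rows: np.ndarray = field(default=None, repr=False)
    ls_cols: np.ndarray = field(default=None, repr=False)

    @property
    def n_models(self) -> int:
        if self.net.homogeneous:
            return len(self.col_models)
        return len(self.col_models) + len(self.row_models)


@dataclass
class LocalMOModel:
    """Two multi-output models, one per node family.

    ``model_rows``: row features -> profile over seen columns (ls_cols).
    ``model_cols``: column features -> profile over seen rows (ls_rows).
    Homogeneous networks share one profile model in both slots.
    """

    net: Network = field(repr=False)
    params: LearnerParams
    model_rows: EnsembleModel = field(repr=False)
    model_cols: EnsembleModel = field(repr=False)
    ls_rows: np.ndarray = field(repr=False, default=None)
    ls_cols: np.ndarray = field(repr=False, default=None)


@dataclass
class TwoStepModels:
    """Second-step models enabling predictions between two unseen nodes.

    Single-output: one model per unseen row (over column features) and per
    unseen column (over row features).  Multi-output: one joint model per
    side.  ``step1_row_labels`` / ``step1_col_labels`` keep the binarized
    step-1 blocks (ts_rows x ls_cols and ls_rows x ts_cols).
    """

    first_step: LocalSOModel | LocalMOModel = field(repr=False)
    ts_rows: np.ndarray
    ts_cols: np.ndarray
    row_side_models: dict[int, EnsembleModel] | EnsembleModel | None = field(repr=False, default=None)
    col_side_models: dict[int, EnsembleModel] | EnsembleModel | None = field(repr=False, default=None)
    step1_row_labels: np.ndarray | None = None
    step1_col_labels: np.ndarray | None = None


# --------------------------------------------------------------------------
# training


def _pairs_involving(ls: PairSample, axis_idx: np.ndarray, axis: str):
    if axis == "col":
        return {j: np.flatnonzero(ls.col_idx == j) for j in axis_idx}
    return {i: np.flatnonzero(ls.row_idx == i) for i in axis_idx}


def train_local_so(
    net: Network, ls: PairSample, params: LearnerParams
) -> LocalSOModel:
    """One single-output ensemble per node appearing in the learning sample.

    Nodes whose labeled partners are all of one class get constant models,
    not errors.  Homogeneous networks train one family of models over node
    features (each node's sample collects both orientations of its pairs).
    """
    if len(ls) == 0:
        raise ValueError("empty learning sample")
    ls_rows = np.unique(ls.row_idx)
    ls_cols = np.unique(ls.col_idx)
    if net.homogeneous:
        nodes = np.unique(np.concatenate([ls_rows, ls_cols]))
        models: dict[int, EnsembleModel] = {}
        for n in nodes:
            as_row = ls.row_idx == n
            as_col = ls.col_idx == n
            partners = np.concatenate([ls.col_idx[as_row], ls.row_idx[as_col]])
            y = np.concatenate([ls.labels[as_row], ls.labels[as_col]])
            X = net.rows.features[partners]
            models[int(n)] = train_ensemble(
                X, y, params.with_seed(child_seed(params.seed, "node", int(n)))
            )
        return LocalSOModel(net, params, models, models, nodes, nodes)
    col_models = {}
    for j, idx in _pairs_involving(ls, ls_cols, "col").items():
        col_models[int(j)] = train_ensemble(
            net.rows.features[ls.row_idx[idx]],
            ls.labels[idx],
            params.with_seed(child_seed(params.seed, "col", int(j))),
        )
    row_models = {}
    for i, idx in _pairs_involving(ls, ls_rows, "row").items():
        row_models[int(i)] = train_ensemble(
            net.cols.features[ls.col_idx[idx]],
            ls.labels[idx],
            params.with_seed(child_seed(params.seed, "row", int(i))),
        )
    return LocalSOModel(net, params, col_models, row_models, ls_rows, ls_cols)


def train_local_mo(
    net: Network, ls: PairSample, params: LearnerParams
) -> LocalMOModel:
    """Two multi-output ensembles over the fully observed seen-node block.

    Raises if any entry of the seen-rows x seen-columns submatrix is
    unknown (multi-output trees cannot handle missing outputs; use the
    single-output variant then).  Homogeneous networks train one profile
    model with diagonal outputs fixed at 0 (no self-interaction).
    """
    if len(ls) == 0:
        raise ValueError("empty learning sample")
    ls_rows = np.unique(ls.row_idx)
    ls_cols = np.unique(ls.col_idx)
    if net.homogeneous:
        nodes = np.unique(np.concatenate([ls_rows, ls_cols]))
        block = net.adjacency[np.ix_(nodes, nodes)].copy()
        np.fill_diagonal(block, 0.0)
        if np.isnan(block).any():
            raise ValueError(
                "seen-node adjacency block has unknown entries; the "
                "multi-output variant needs a fully observed block — use "
                "the single-output variant instead"
            )
        model = train_ensemble(
            net.rows.features[nodes],
            block.astype(int),
            params.with_seed(child_seed(params.seed, "mo", "nodes")),
        )
        return LocalMOModel(net, params, model, model, nodes, nodes)
    block = net.adjacency[np.ix_(ls_rows, ls_cols)]
    if np.isnan(block).any():
        raise ValueError(
            "LS_r x LS_c adjacency block has unknown entries; the "
            "multi-output variant needs a fully observed block — use the "
            "single-output variant instead"
        )
    model_rows = train_ensemble(
        net.rows.features[ls_rows],
        block.astype(int),
        params.with_seed(child_seed(params.seed, "mo", "rows")),
    )
    model_cols = train_ensemble(
        net.cols.features[ls_cols],
        block.T.astype(int),
        params.with_seed(child_seed(params.seed, "mo", "cols")),
    )
    return LocalMOModel(net, params, model_rows, model_cols, ls_rows, ls_cols)


# --------------------------------------------------------------------------
# prediction: seen x seen and seen x unseen


def _so_score_col(model: LocalSOModel, col: int, row_feats: np.ndarray) -> np.ndarray:
    return predict_proba(model.col_models[int(col)], row_feats)


def _so_score_row(model: LocalSOModel, row: int, col_feats: np.ndarray) -> np.ndarray:
    return predict_proba(model.row_models[int(row)], col_feats)



def _profile2d(model: EnsembleModel, X) -> np.ndarray:
    """Predicted profiles as a 2-D (n_samples, n_outputs) array."""
    p = predict_proba(model, X)
    return p[:, None] if p.ndim == 1 else p

def _grouped_scores(groups, feats, models, key_idx, other_idx, out) -> None:
    """Score pairs batched per node model: one predict call per node."""
    for key in groups:
        mask = key_idx == key
        out[mask] = predict_proba(models[int(key)], feats[other_idx[mask]])


def predict_lsls_local(model: LocalSOModel, row_idx, col_idx) -> np.ndarray:
    """Score pairs of two seen nodes: mean of the two per-node predictions.

    Homogeneous pair (a, b): mean of f_a(x(b)) and f_b(x(a)), hence
    swap-invariant by construction.
    """
    net = model.net
    row_idx = np.asarray(row_idx, dtype=np.intp)
    col_idx = np.asarray(col_idx, dtype=np.intp)
    p_col = np.empty(row_idx.size)
    p_row = np.empty(row_idx.size)
    _grouped_scores(
        np.unique(col_idx), net.rows.features, model.col_models, col_idx, row_idx, p_col
    )
    _grouped_scores(
        np.unique(row_idx), net.cols.features, model.row_models, row_idx, col_idx, p_row
    )
    return 0.5 * (p_col + p_row)


def predict_lsts_local(model: LocalSOModel, row_idx, col_idx) -> np.ndarray:
    """Score pairs with exactly one seen node: that node's model alone.

    For each pair, whichever side has a trained model is applied to the
    unseen node's features; no averaging is involved.
    """
    net = model.net
    row_idx = np.asarray(row_idx, dtype=np.intp)
    col_idx = np.asarray(col_idx, dtype=np.intp)
    row_seen = np.array([int(i) in model.row_models for i in row_idx])
    col_seen = np.array([int(j) in model.col_models for j in col_idx])
    if not net.homogeneous and (row_seen == col_seen).any():
        k = int(np.flatnonzero(row_seen == col_seen)[0])
        raise ValueError(
            f"pair ({row_idx[k]}, {col_idx[k]}) does not have exactly one "
            "seen node"
        )
    if net.homogeneous:
        # either orientation may carry the seen node
        if not (row_seen ^ col_seen).all():
            k = int(np.flatnonzero(~(row_seen ^ col_seen))[0])
            raise ValueError(
                f"pair ({row_idx[k]}, {col_idx[k]}) does not have exactly "
                "one seen node"
            )
    out = np.empty(row_idx.size)
    m = row_seen
    if m.any():
        _grouped_scores(
            np.unique(row_idx[m]), net.cols.features, model.row_models,
            row_idx, col_idx, out,
        )
    if (~m).any():
        _grouped_scores(
            np.unique(col_idx[~m]), net.rows.features, model.col_models,
            col_idx, row_idx, out,
        )
    return out


def predict_lsts_mo(model: LocalMOModel, row_idx, col_idx) -> np.ndarray:
    """Multi-output scores for pairs with exactly one seen node.

    A pair (seen row i, unseen col j) is scored by ``model_cols`` applied
    to x(j), reading off output i; symmetrically for unseen rows.
    """
    net = model.net
    row_idx = np.asarray(row_idx, dtype=np.intp)
    col_idx = np.asarray(col_idx, dtype=np.intp)
    row_pos = {int(r): k for k, r in enumerate(model.ls_rows)}
    col_pos = {int(c): k for k, c in enumerate(model.ls_cols)}
    out = np.empty(row_idx.size)
    unseen_col = np.array([int(j) not in col_pos for j in col_idx])
    for k in np.flatnonzero(unseen_col):
        if int(row_idx[k]) not in row_pos:
            raise ValueError(
                f"pair ({row_idx[k]}, {col_idx[k]}) does not have exactly "
                "one seen node"
            )
    # seen row, unseen col: profile of the unseen column over seen rows
    if unseen_col.any():
        cols = np.unique(col_idx[unseen_col])
        profiles = _profile2d(model.model_cols, net.cols.features[cols])
        pos_of = {int(c): a for a, c in enumerate(cols)}
        for k in np.flatnonzero(unseen_col):
            out[k] = profiles[pos_of[int(col_idx[k])], row_pos[int(row_idx[k])]]
    if (~unseen_col).any():
        rows = np.unique(row_idx[~unseen_col])
        for r in rows:
            if int(r) in row_pos:
                raise ValueError(
                    f"row {r} is a seen node; pair must have exactly one "
                    "seen node"
                )
        profiles = _profile2d(model.model_rows, net.rows.features[rows])
        pos_of = {int(r): a for a, r in enumerate(rows)}
        for k in np.flatnonzero(~unseen_col):
            out[k] = profiles[pos_of[int(row_idx[k])], col_pos[int(col_idx[k])]]
    return out


# --------------------------------------------------------------------------
# two-step procedure


def _score_block_so_cols(model: LocalSOModel, ts_rows: np.ndarray) -> np.ndarray:
    """Step-1 scores on ts_rows x ls_cols with the per-column models."""
    feats = model.net.rows.features[ts_rows]
    cols = model.ls_cols
    block = np.empty((ts_rows.size, cols.size))
    for a, j in enumerate(cols):
        block[:, a] = _so_score_col(model, j, feats)
    return block


def _score_block_so_rows(model: LocalSOModel, ts_cols: np.ndarray) -> np.ndarray:
    """Step-1 scores on ls_rows x ts_cols with the per-row models."""
    feats = model.net.cols.features[ts_cols]
    rows = model.ls_rows
    block = np.empty((rows.size, ts_cols.size))
    for a, i in enumerate(rows):
        block[a, :] = _so_score_row(model, i, feats)
    return block


def two_step_train(
    model: LocalSOModel | LocalMOModel,
    net: Network,
    ts_rows,
    ts_cols,
    rule: ThresholdRule,
) -> TwoStepModels:
    """Build second-step models for the given unseen rows and columns.

    Step 1 scores the unseen-row x seen-column block with the first-step
    column-side models (and the seen-row x unseen-column block with the
    row-side models) and binarizes each block so its predicted edge
    proportion matches ``rule.target_proportion``.  Step 2 trains, per
    unseen row, a model from seen-column features to that row's binarized
    labels (symmetrically per unseen column); the multi-output variant
    trains one joint model per side.

    Homogeneous networks pass the unseen nodes as ``ts_rows`` (``ts_cols``
    ignored): each unseen node's second-step model maps seen-node features
    to its binarized predicted neighborhood.
    """
    params = model.params
    single = isinstance(model, LocalSOModel)
    if net.homogeneous:
        ts_nodes = np.asarray(ts_rows, dtype=np.intp)
        if ts_nodes.size == 0:
            return TwoStepModels(model, ts_nodes, ts_nodes)
        ls_nodes = model.ls_cols
        if single:
            block = _score_block_so_cols(model, ts_nodes)
        else:
            block = _profile2d(model.model_rows, net.rows.features[ts_nodes])
        rr, cc = np.meshgrid(ts_nodes, ls_nodes, indexing="ij")
        labels = binarize_scores(
            block.ravel(), rr.ravel(), cc.ravel(), rule
        ).reshape(block.shape)
        X = net.rows.features[ls_nodes]
        if single:
            models = {
                int(t): train_ensemble(
                    X, labels[a], params.with_seed(child_seed(params.seed, "ts", int(t)))
                )
                for a, t in enumerate(ts_nodes)
            }
            return TwoStepModels(model, ts_nodes, ts_nodes, models, models, labels, labels)
        joint = train_ensemble(
            X, labels.T, params.with_seed(child_seed(params.seed, "ts", "nodes"))
        )
        return TwoStepModels(model, ts_nodes, ts_nodes, joint, joint, labels, labels)

    ts_rows = np.asarray(ts_rows, dtype=np.intp)
    ts_cols = np.asarray(ts_cols, dtype=np.intp)
    row_side = col_side = None
    row_labels = col_labels = None
    if ts_rows.size:
        if single:
            block = _score_block_so_cols(model, ts_rows)
        else:
            block = _profile2d(model.model_rows, net.rows.features[ts_rows])
        rr, cc = np.meshgrid(ts_rows, model.ls_cols, indexing="ij")
        row_labels = binarize_scores(
            block.ravel(), rr.ravel(), cc.ravel(), rule
        ).reshape(block.shape)
        Xc = net.cols.features[model.ls_cols]
        if single:
            row_side = {
                int(t): train_ensemble(
                    Xc,
                    row_labels[a],
                    params.with_seed(child_seed(params.seed, "ts_row", int(t))),
                )
                for a, t in enumerate(ts_rows)
            }
        else:
            row_side = train_ensemble(
                Xc,
                row_labels.T,
                params.with_seed(child_seed(params.seed, "ts_row", "joint")),
            )
    if ts_cols.size:
        if single:
            block = _score_block_so_rows(model, ts_cols)
        else:
            block = _profile2d(model.model_cols, net.cols.features[ts_cols]).T
        rr, cc = np.meshgrid(model.ls_rows, ts_cols, indexing="ij")
        col_labels = binarize_scores(
            block.ravel(), rr.ravel(), cc.ravel(), rule
        ).reshape(block.shape)
        Xr = net.rows.features[model.ls_rows]
        if single:
            col_side = {
                int(t): train_ensemble(
                    Xr,
                    col_labels[:, a],
                    params.with_seed(child_seed(params.seed, "ts_col", int(t))),
                )
                for a, t in enumerate(ts_cols)
            }
        else:
            col_side = train_ensemble(
                Xr,
                col_labels,
                params.with_seed(child_seed(params.seed, "ts_col", "joint")),
            )
    return TwoStepModels(
        model, ts_rows, ts_cols, row_side, col_side, row_labels, col_labels
    )


def predict_tsts_local(two_step: TwoStepModels, row_idx, col_idx) -> np.ndarray:
    """Score pairs of two unseen nodes: mean of the two second-step models.

    For a bipartite pair (r, c): average of the unseen-row model applied to
    x(c) and the unseen-column model applied to x(r).  Homogeneous pairs
    average the two node models, so predictions are swap-invariant.
    """
    model = two_step.first_step
    net = model.net
    row_idx = np.asarray(row_idx, dtype=np.intp)
    col_idx = np.asarray(col_idx, dtype=np.intp)
    single = isinstance(model, LocalSOModel)
    p_row = np.empty(row_idx.size)
    p_col = np.empty(row_idx.size)
    if net.homogeneous:
        if single:
            _grouped_scores(
                np.unique(row_idx), net.rows.features, two_step.row_side_models,
                row_idx, col_idx, p_row,
            )
            _grouped_scores(
                np.unique(col_idx), net.rows.features, two_step.row_side_models,
                col_idx, row_idx, p_col,
            )
        else:
            ts_pos = {int(t): a for a, t in enumerate(two_step.ts_rows)}
            nodes = np.unique(np.concatenate([row_idx, col_idx]))
            profiles = _profile2d(two_step.row_side_models, net.rows.features[nodes])
            pos_of = {int(n): a for a, n in enumerate(nodes)}
            for k, (i, j) in enumerate(zip(row_idx, col_idx)):
                p_row[k] = profiles[pos_of[int(j)], ts_pos[int(i)]]
                p_col[k] = profiles[pos_of[int(i)], ts_pos[int(j)]]
        return 0.5 * (p_row + p_col)
    if single:
        _grouped_scores(
            np.unique(row_idx), net.cols.features, two_step.row_side_models,
            row_idx, col_idx, p_row,
        )
        _grouped_scores(
            np.unique(col_idx), net.rows.features, two_step.col_side_models,
            col_idx, row_idx, p_col,
        )
    else:
        ts_row_pos = {int(t): a for a, t in enumerate(two_step.ts_rows)}
        ts_col_pos = {int(t): a for a, t in enumerate(two_step.ts_cols)}
        cols = np.unique(col_idx)
        rows = np.unique(row_idx)
        prof_r = _profile2d(two_step.row_side_models, net.cols.features[cols])
        prof_c = _profile2d(two_step.col_side_models, net.rows.features[rows])
        cpos = {int(c): a for a, c in enumerate(cols)}
        rpos = {int(r): a for a, r in enumerate(rows)}
        for k, (i, j) in enumerate(zip(row_idx, col_idx)):
            p_row[k] = prof_r[cpos[int(j)], ts_row_pos[int(i)]]
            p_col[k] = prof_c[rpos[int(i)], ts_col_pos[int(j)]]
    return 0.5 * (p_row + p_col)


# --------------------------------------------------------------------------
# Model / Results wrappers


@dataclass
class LocalPairModel:
    """Model specification for the local approach on one network.

    ``variant`` selects single-output ("so", one ensemble per seen node)
    or multi-output ("mo", one ensemble per node family).
    """

    net: Network
    params: LearnerParams = field(default_factory=LearnerParams)
    variant: str = "so"

    def __post_init__(self) -> None:
        if self.variant not in ("so", "mo"):
            raise ValueError("variant must be 'so' or 'mo'")

    def fit(self, pairs: PairSample | None = None) -> "LocalPairResults":
        from .network import known_pairs

        if pairs is None:
            pairs = known_pairs(self.net)
        if self.variant == "so":
            fitted = train_local_so(self.net, pairs, self.params)
        else:
            fitted = train_local_mo(self.net, pairs, self.params)
        rule = ThresholdRule(pairs.prevalence)
        return LocalPairResults(self, fitted, pairs, rule)


@dataclass
class LocalPairResults:
    """Fitted local model with family-aware scoring and the two-step hook."""

    model: LocalPairModel
    fitted: LocalSOModel | LocalMOModel
    train_pairs: PairSample
    rule: ThresholdRule
    two_step: TwoStepModels | None = None

    @property
    def net(self) -> Network:
        return self.model.net

    def fit_two_step(self, ts_rows, ts_cols=None) -> "LocalPairResults":
        """Train second-step models for the given unseen nodes (in place)."""
        self.two_step = two_step_train(
            self.fitted, self.net, ts_rows, ts_cols, self.rule
        )
        return self

    def predict(self, row_idx, col_idx, family: str) -> np.ndarray:
        """Score pairs of a given family (LSxLS, LSxTS, TSxLS or TSxTS)."""
        single = isinstance(self.fitted, LocalSOModel)
        if family == "LSxLS":
            if not single:
                raise ValueError(
                    "multi-output variant cannot score seen x seen pairs"
                )
            return predict_lsls_local(self.fitted, row_idx, col_idx)
        if family in ("LSxTS", "TSxLS"):
            if single:
                return predict_lsts_local(self.fitted, row_idx, col_idx)
            return predict_lsts_mo(self.fitted, row_idx, col_idx)
        if family == "TSxTS":
            if self.two_step is None:
                raise ValueError("call fit_two_step before scoring TSxTS pairs")
            return predict_tsts_local(self.two_step, row_idx, col_idx)
        raise ValueError(f"unknown family {family!r}")

    def feature_importance_rankings(self) -> dict[str, np.ndarray]:
        """Multi-output variant: two rankings, one per node-feature family."""
        from .learners import feature_importances

        if isinstance(self.fitted, LocalMOModel):
            return {
                "row_features": feature_importances(self.fitted.model_rows),
                "col_features": feature_importances(self.fitted.model_cols),
            }
        raise ValueError(
            "single-output variant has one ranking per node; inspect "
            "fitted.col_models / fitted.row_models directly"
        )

    def summary(self) -> str:
        net = self.net
        kind = "homogeneous" if net.homogeneous else "bipartite"
        if isinstance(self.fitted, LocalSOModel):
            detail = f"{self.fitted.n_models} per-node ensembles"
        else:
            detail = "2 multi-output ensembles (+2 with two-step)"
        return "\n".join(
            [
                f"Local ({self.model.variant}) extra-trees model",
                f"  network: {kind} {net.shape[0]}x{net.shape[1]}",
                f"  training pairs: {len(self.train_pairs)} "
                f"(prevalence {self.train_pairs.prevalence:.4f})",
                f"  models: {detail}",
                f"  binarization target: {self.rule.target_proportion:.4f}",
            ]
        )
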