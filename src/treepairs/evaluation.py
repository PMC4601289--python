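"""Four-family evaluation protocol for supervised network inference.

Test pairs are split into families by whether each node of the pair occurs
in some training pair (LS, "learning set") or is entirely unseen (TS,
"test set"): LSxLS, LSxTS, TSxLS and TSxTS.  Two cross-validation schemes
cover them: CV on pairs (randomly partitions the known pairs; evaluates
LSxLS) and CV on nodes (independently partitions the row and column node
sets; evaluates LSxTS, TSxLS and TSxTS; homogeneous networks have LSxTS
and TSxTS only).  Scores are summarized per family by the areas under the
ROC and precision-recall curves (AUROC, AUPR), computed per fold and
averaged over folds and runs.

Because interaction networks are sparse, a constant (random) ranking
already attains AUROC 0.5 and AUPR equal to the edge prevalence, and node
degree alone is predictive — high-degree nodes are more likely to gain new
edges.  Both baselines are implemented for comparison: the degree baseline
ranks LSxLS pairs by the sum of the two training degrees and LSxTS/TSxLS
pairs by the seen node's training degree; TSxTS has no degree information
and falls back to the random baseline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from ._seeds import child_seed
from .learners import LearnerParams
from .network import Network, PairSample, node_degrees

__all__ = [
    "UndefinedMetricError",
    "auroc",
    "aupr",
    "FoldPlan",
    "EvalReport",
    "pair_fold_plans",
    "node_fold_plans",
    "cv_on_pairs",
    "cv_on_nodes",
    "degree_baseline",
    "get_method",
    "FAMILIES",
]

FAMILIES = ("LSxLS", "LSxTS", "TSxLS", "TSxTS")


class UndefinedMetricError(ValueError):
    """Metric undefined for the given labels (single class / no positives)."""


def auroc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney statistic P(score_pos > score_neg) +
    0.5 P(tie), so a constant ranking scores exactly 0.5.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise average precision).

    No interpolation between operating points; a constant ranking scores
    exactly the positive-class prevalence.
    """
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise UndefinedMetricError("AUPR needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


# --------------------------------------------------------------------------
# fold plans


@dataclass
class FoldPlan:
    """One CV iteration: training pairs plus per-family test pairs."""

    run: int
    fold: int
    train: PairSample
    tests: dict[str, PairSample]
    ts_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.intp))
    ts_cols: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.intp))


def pair_fold_plans(net: Network, pairs: PairSample, folds: int, runs: int, seed: int):
    """CV on pairs: per run, the known pairs are split into ``folds``
    random groups; each group is the LSxLS test set once."""
    n = len(pairs)
    if n < folds:
        raise ValueError(f"need at least {folds} known pairs, have {n}")
    for run in range(runs):
        rng = np.random.default_rng(child_seed(seed, "cv-pairs", run))
        perm = rng.permutation(n)
        groups = np.array_split(perm, folds)
        for fold, test_idx in enumerate(groups):
            mask = np.zeros(n, dtype=bool)
            mask[test_idx] = True
            yield FoldPlan(
                run, fold, pairs.subset(~mask), {"LSxLS": pairs.subset(mask)}
            )


def node_fold_plans(net: Network, pairs: PairSample, folds: int, runs: int, seed: int):
    """CV on nodes: per run, rows and columns are independently split into
    ``folds`` groups; fold i holds out row-group i and column-group i
    jointly.  Homogeneous networks use a single node partition and the
    LSxTS / TSxLS families merge."""
    n_r, n_c = net.shape
    if n_r < folds or (not net.homogeneous and n_c < folds):
        raise ValueError("fewer nodes than folds")
    for run in range(runs):
        rng = np.random.default_rng(child_seed(seed, "cv-nodes", run))
        row_groups = np.array_split(rng.permutation(n_r), folds)
        if net.homogeneous:
            col_groups = row_groups
        else:
            col_groups = np.array_split(rng.permutation(n_c), folds)
        for fold in range(folds):
            ts_r = np.sort(row_groups[fold])
            ts_c = np.sort(col_groups[fold])
            row_is_ts = np.zeros(n_r, dtype=bool)
            row_is_ts[ts_r] = True
            col_is_ts = np.zeros(n_c, dtype=bool)
            col_is_ts[ts_c] = True
            r_ts = row_is_ts[pairs.row_idx]
            c_ts = col_is_ts[pairs.col_idx]
            train = pairs.subset(~r_ts & ~c_ts)
            if net.homogeneous:
                tests = {
                    "LSxTS": pairs.subset(r_ts ^ c_ts),
                    "TSxTS": pairs.subset(r_ts & c_ts),
                }
            else:
                tests = {
                    "LSxTS": pairs.subset(~r_ts & c_ts),
                    "TSxLS": pairs.subset(r_ts & ~c_ts),
                    "TSxTS": pairs.subset(r_ts & c_ts),
                }
            yield FoldPlan(run, fold, train, tests, ts_r, ts_c)


# --------------------------------------------------------------------------
# inference-method adapters


class _Fitted:
    def predict(self, family: str, row_idx, col_idx) -> np.ndarray:
        raise NotImplementedError


class InferenceMethod:
    """Adapter contract: fit on a fold's training pairs, score test pairs."""

    name: str = "?"
    trains_ensembles = True

    def fit_fold(
        self, net: Network, train: PairSample, ts_rows, ts_cols, seed: int
    ) -> _Fitted:
        raise NotImplementedError


class GlobalMethod(InferenceMethod):
    name = "global"

    def __init__(self, params: LearnerParams, symmetric_combine: str = "mean"):
        self.params = params
        self.symmetric_combine = symmetric_combine

    def fit_fold(self, net, train, ts_rows, ts_cols, seed):
        from .global_model import GlobalPairModel

        model = GlobalPairModel(
            net, self.params.with_seed(seed), self.symmetric_combine
        )
        res = model.fit(train)

        class F(_Fitted):
            def predict(self, family, row_idx, col_idx):
                return res.predict(row_idx, col_idx)

        return F()


class _LocalFitted(_Fitted):
    def __init__(self, res, train: PairSample):
        self.res = res
        self.train = train

    def predict(self, family, row_idx, col_idx):
        from .local_model import LocalSOModel

        if family != "LSxLS" or not isinstance(self.res.fitted, LocalSOModel):
            return self.res.predict(row_idx, col_idx, family)
        # CV on pairs can hold out every pair of a node; fall back to the
        # one available per-node model (or the training prevalence).
        fitted = self.res.fitted
        row_idx = np.asarray(row_idx, dtype=np.intp)
        col_idx = np.asarray(col_idx, dtype=np.intp)
        have_r = np.array([int(i) in fitted.row_models for i in row_idx])
        have_c = np.array([int(j) in fitted.col_models for j in col_idx])
        out = np.empty(row_idx.size)
        both = have_r & have_c
        if both.any():
            out[both] = self.res.predict(row_idx[both], col_idx[both], "LSxLS")
        one = have_r ^ have_c
        if one.any():
            out[one] = self.res.predict(row_idx[one], col_idx[one], "LSxTS")
        neither = ~(both | one)
        out[neither] = self.train.prevalence
        return out


class LocalMethod(InferenceMethod):
    def __init__(self, params: LearnerParams, variant: str = "so"):
        self.params = params
        self.variant = variant
        self.name = f"local-{variant}"

    def fit_fold(self, net, train, ts_rows, ts_cols, seed):
        from .local_model import LocalPairModel

        res = LocalPairModel(net, self.params.with_seed(seed), self.variant).fit(train)
        if ts_rows is not None and (len(ts_rows) or (ts_cols is not None and len(ts_cols))):
            res.fit_two_step(ts_rows, ts_cols)
        return _LocalFitted(res, train)


class DegreeBaseline(InferenceMethod):
    """Rank pairs by training degrees; random ranking where no degree is
    available (TSxTS)."""

    name = "baseline"
    trains_ensembles = False

    def __init__(self, params=None):
        pass

    def fit_fold(self, net, train, ts_rows, ts_cols, seed):
        row_deg, col_deg = node_degrees(train)

        class F(_Fitted):
            def predict(self, family, row_idx, col_idx):
                return degree_baseline_scores(
                    family, row_deg, col_deg, row_idx, col_idx, net.homogeneous
                )

        return F()


def degree_baseline_scores(
    family: str, row_deg, col_deg, row_idx, col_idx, homogeneous: bool
) -> np.ndarray:
    """Degree-derived scores for one family of pairs.

    LSxLS: deg(row) + deg(col).  LSxTS / TSxLS: the seen node's degree;
    for homogeneous networks the seen side of each pair is the node with
    nonzero presence in the training sample, so the maximum of the two
    degrees is used (the unseen node's training degree is 0).  TSxTS:
    constant scores (random baseline).
    """
    row_idx = np.asarray(row_idx, dtype=np.intp)
    col_idx = np.asarray(col_idx, dtype=np.intp)
    if family == "LSxLS":
        return row_deg[row_idx] + col_deg[col_idx]
    if family == "LSxTS":
        if homogeneous:
            return np.maximum(row_deg[row_idx], col_deg[col_idx])
        return row_deg[row_idx]
    if family == "TSxLS":
        return col_deg[col_idx]
    if family == "TSxTS":
        return np.zeros(row_idx.size)
    raise ValueError(f"unknown family {family!r}")


def degree_baseline(fold: FoldPlan) -> dict[str, np.ndarray]:
    """Degree-baseline scores for every family of one fold plan."""
    net = fold.train.source
    row_deg, col_deg = node_degrees(fold.train)
    return {
        fam: degree_baseline_scores(
            fam, row_deg, col_deg, test.row_idx, test.col_idx, net.homogeneous
        )
        for fam, test in fold.tests.items()
    }


_METHODS = {
    "global": GlobalMethod,
    "local-so": lambda params: LocalMethod(params, "so"),
    "local-mo": lambda params: LocalMethod(params, "mo"),
    "baseline": DegreeBaseline,
}


def get_method(name: str, params: LearnerParams | None = None) -> InferenceMethod:
    if name not in _METHODS:
        raise ValueError(f"unknown method {name!r}; choose from {sorted(_METHODS)}")
    return _METHODS[name](params or LearnerParams())


# --------------------------------------------------------------------------
# report


@dataclass
class EvalReport:
    """Per-family AUPR/AUROC over all runs and folds of one evaluation."""

    records: pd.DataFrame
    metadata: dict
    skipped: list = field(default_factory=list)
    pooled: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def summary(self) -> pd.DataFrame:
        """Mean AUPR/AUROC per family, averaged over folds and runs."""
        if self.records.empty:
            return pd.DataFrame(columns=["family", "aupr", "auroc"])
        out = (
            self.records.groupby("family")[["aupr", "auroc"]]
            .mean()
            .reindex([f for f in FAMILIES if f in set(self.records["family"])])
            .reset_index()
        )
        return out

    def summary_text(self) -> str:
        meta = self.metadata
        lines = [
            f"Evaluation: method={meta.get('method')} cv={meta.get('cv')} "
            f"runs={meta.get('runs')} folds={meta.get('folds')} "
            f"seed={meta.get('seed')}",
            self.summary().to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        if self.skipped:
            lines.append(f"  ({len(self.skipped)} single-class fold/family skipped)")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "metadata": self.metadata,
            "summary": {
                row["family"]: {"aupr": row["aupr"], "auroc": row["auroc"]}
                for _, row in self.summary().iterrows()
            },
            "n_skipped": len(self.skipped),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _evaluate_plans(plans, method: InferenceMethod, net, meta, seed, keep_scores):
    records = []
    skipped = []
    pooled: dict[str, list] = {}
    for plan in plans:
        fitted = method.fit_fold(
            net,
            plan.train,
            plan.ts_rows if plan.ts_rows.size else None,
            plan.ts_cols if plan.ts_cols.size else None,
            child_seed(seed, "fit", plan.run, plan.fold),
        )
        for family, test in plan.tests.items():
            if len(test) == 0:
                continue
            scores = fitted.predict(family, test.row_idx, test.col_idx)
            labels = test.labels
            if keep_scores:
                pooled.setdefault(family, []).append((scores, labels))
            try:
                rec_aupr = aupr(scores, labels)
                rec_auroc = auroc(scores, labels)
            except UndefinedMetricError:
                skipped.append((plan.run, plan.fold, family))
                warnings.warn(
                    f"run {plan.run} fold {plan.fold} family {family}: "
                    "single-class test labels, fold skipped"
                )
                continue
            records.append(
                {
                    "family": family,
                    "run": plan.run,
                    "fold": plan.fold,
                    "aupr": rec_aupr,
                    "auroc": rec_auroc,
                    "n_pairs": len(test),
                    "prevalence": test.prevalence,
                }
            )
    report = EvalReport(pd.DataFrame(records), meta, skipped)
    if keep_scores:
        report.pooled = {
            fam: (
                np.concatenate([s for s, _ in chunks]),
                np.concatenate([l for _, l in chunks]),
            )
            for fam, chunks in pooled.items()
        }
    return report


def cv_on_pairs(
    net: Network,
    method: InferenceMethod,
    folds: int = 10,
    runs: int = 10,
    seed: int = 0,
    pairs: PairSample | None = None,
    keep_scores: bool = False,
) -> EvalReport:
    """Evaluate LSxLS generalization by cross-validation on pairs."""
    from .network import known_pairs

    if pairs is None:
        pairs = known_pairs(net)
    meta = {
        "method": method.name, "cv": "pairs", "folds": folds, "runs": runs,
        "seed": seed,
    }
    plans = pair_fold_plans(net, pairs, folds, runs, seed)
    return _evaluate_plans(plans, method, net, meta, seed, keep_scores)


def cv_on_nodes(
    net: Network,
    method: InferenceMethod,
    folds: int = 10,
    runs: int = 10,
    seed: int = 0,
    pairs: PairSample | None = None,
    keep_scores: bool = False,
) -> EvalReport:
    """Evaluate LSxTS / TSxLS / TSxTS generalization by CV on nodes."""
    from .network import known_pairs

    if pairs is None:
        pairs = known_pairs(net)
    meta = {
        "method": method.name, "cv": "nodes", "folds": folds, "runs": runs,
        "seed": seed,
    }
    plans = node_fold_plans(net, pairs, folds, runs, seed)
    return _evaluate_plans(plans, method, net, meta, seed, keep_scores)
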