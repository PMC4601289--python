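"""Metrics, fold plans, CV protocols and baselines."""

import itertools

import numpy as np
import pytest

from treepairs.evaluation import (
    DegreeBaseline,
    GlobalMethod,
    UndefinedMetricError,
    aupr,
    auroc,
    cv_on_nodes,
    cv_on_pairs,
    degree_baseline,
    degree_baseline_scores,
    get_method,
    node_fold_plans,
    pair_fold_plans,
)
from treepairs.learners import LearnerParams
from treepairs.network import Network, known_pairs
from treepairs.synthetic import SynthConfig, generate_network


def auroc_oracle(scores, labels):
    """Exhaustive pairwise comparison: P(s_pos > s_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def aupr_oracle(scores, labels):
    """Step-wise average precision from a hand-built PR table."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for v in sorted(set(scores), reverse=True):
        predicted = scores >= v
        tp = int(labels[predicted].sum())
        precision = tp / predicted.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestAuroc:
    def test_perfect_and_derived_examples(self):
        assert auroc([0.9, 0.1], [1, 0]) == 1.0
        # brute force over the 2 pos x 1 neg comparisons: (0.8>0.6)=1,
        # (0.4>0.6)=0 -> 0.5
        assert auroc([0.8, 0.6, 0.4], [1, 0, 1]) == 0.5

    def test_constant_scores_exactly_half(self):
        assert auroc([0.3] * 7, [1, 0, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_oracle_exhaustively(self):
        grids = {1: (0.25, 0.5, 0.75), 2: (0.25, 0.5, 0.75), 3: (0.25, 0.5, 0.75),
                 4: (0.25, 0.5, 0.75), 5: (0.3, 0.7), 6: (0.3, 0.7)}
        for n, grid in grids.items():
            for labels in itertools.product((0, 1), repeat=n):
                if len(set(labels)) < 2:
                    continue
                for scores in itertools.product(grid, repeat=n):
                    assert auroc(scores, labels) == pytest.approx(
                        auroc_oracle(scores, labels), abs=1e-12
                    )


class TestAupr:
    def test_perfect_and_derived_examples(self):
        assert aupr([0.9, 0.2, 0.8], [1, 0, 1]) == 1.0
        # precisions at the two positives: 1 and 2/3
        assert aupr([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(5 / 6)

    def test_constant_scores_equal_prevalence(self):
        labels = [1, 0, 0, 0, 1]
        assert aupr([0.4] * 5, labels) == pytest.approx(2 / 5, abs=1e-15)

    def test_no_positives_undefined(self):
        with pytest.raises(UndefinedMetricError):
            aupr([0.1, 0.2], [0, 0])

    def test_matches_pr_table_oracle_exhaustively(self):
        grids = {3: (0.25, 0.5, 0.75), 4: (0.25, 0.5, 0.75),
                 5: (0.3, 0.7), 6: (0.3, 0.7)}
        for n, grid in grids.items():
            for labels in itertools.product((0, 1), repeat=n):
                if sum(labels) == 0:
                    continue
                for scores in itertools.product(grid, repeat=n):
                    assert aupr(scores, labels) == pytest.approx(
                        aupr_oracle(scores, labels), abs=1e-12
                    )


class TestFoldPlans:
    def test_every_pair_tested_once_per_run(self, small_bipartite_net):
        pairs = known_pairs(small_bipartite_net)
        for run in range(2):
            seen = np.zeros(len(pairs), dtype=int)
            for plan in pair_fold_plans(small_bipartite_net, pairs, 5, 2, seed=3):
                if plan.run != run:
                    continue
                test = plan.tests["LSxLS"]
                assert len(test) + len(plan.train) == len(pairs)
                for r, c in zip(test.row_idx, test.col_idx):
                    k = np.flatnonzero((pairs.row_idx == r) & (pairs.col_idx == c))
                    seen[k] += 1
            assert np.all(seen == 1)

    def test_partition_arithmetic(self, small_bipartite_net):
        pairs = known_pairs(small_bipartite_net)
        plans = list(pair_fold_plans(small_bipartite_net, pairs, 2, 1, seed=0))
        assert len(plans) == 2
        sizes = sorted(len(p.tests["LSxLS"]) for p in plans)
        assert abs(sizes[0] - sizes[1]) <= 1

    def test_node_fold_family_consistency(self, small_bipartite_net):
        pairs = known_pairs(small_bipartite_net)
        for plan in node_fold_plans(small_bipartite_net, pairs, 5, 1, seed=1):
            ts_r, ts_c = set(plan.ts_rows), set(plan.ts_cols)
            for r, c in zip(plan.train.row_idx, plan.train.col_idx):
                assert r not in ts_r and c not in ts_c
            for r, c in zip(*[plan.tests["LSxTS"].row_idx, plan.tests["LSxTS"].col_idx]):
                assert r not in ts_r and c in ts_c
            for r, c in zip(*[plan.tests["TSxLS"].row_idx, plan.tests["TSxLS"].col_idx]):
                assert r in ts_r and c not in ts_c
            for r, c in zip(*[plan.tests["TSxTS"].row_idx, plan.tests["TSxTS"].col_idx]):
                assert r in ts_r and c in ts_c

    def test_node_fold_block_arithmetic(self):
        net = generate_network(
            SynthConfig(n_rows=20, n_cols=30, p_rows=5, p_cols=5,
                        k_row_groups=2, k_col_groups=2, block_density=0.3, seed=0)
        )
        pairs = known_pairs(net)
        plans = list(node_fold_plans(net, pairs, 10, 1, seed=0))
        for plan in plans:
            assert len(plan.ts_rows) == 2 and len(plan.ts_cols) == 3
            assert len(plan.tests["TSxTS"]) == 6

    def test_homogeneous_merges_families(self, small_homogeneous_net):
        pairs = known_pairs(small_homogeneous_net)
        plan = next(node_fold_plans(small_homogeneous_net, pairs, 5, 1, seed=2))
        assert set(plan.tests) == {"LSxTS", "TSxTS"}
        assert np.array_equal(plan.ts_rows, plan.ts_cols)


class _OracleMethod:
    """Scores equal to the hidden true labels."""

    name = "oracle"

    def fit_fold(self, net, train, ts_rows, ts_cols, seed):
        adj = net.adjacency

        class F:
            def predict(self, family, row_idx, col_idx):
                return adj[row_idx, col_idx].astype(float)

        return F()


class _ConstantMethod:
    name = "constant"

    def fit_fold(self, net, train, ts_rows, ts_cols, seed):
        class F:
            def predict(self, family, row_idx, col_idx):
                return np.full(len(np.asarray(row_idx)), 0.5)

        return F()


class TestCVProtocols:
    def test_oracle_scores_perfectly(self, small_bipartite_net):
        rep = cv_on_pairs(small_bipartite_net, _OracleMethod(), folds=3, runs=1, seed=0)
        assert (rep.records["auroc"] == 1.0).all()
        assert (rep.records["aupr"] == 1.0).all()

    def test_constant_method_is_random_baseline(self, small_bipartite_net):
        rep = cv_on_pairs(small_bipartite_net, _ConstantMethod(), folds=3, runs=1, seed=0)
        assert (rep.records["auroc"] == 0.5).all()
        assert np.allclose(rep.records["aupr"], rep.records["prevalence"])

    def test_nodes_cv_reports_three_families(self, small_bipartite_net):
        rep = cv_on_nodes(small_bipartite_net, _OracleMethod(), folds=5, runs=1, seed=0)
        assert set(rep.records["family"]) == {"LSxTS", "TSxLS", "TSxTS"}

    def test_homogeneous_nodes_cv_two_families(self, small_homogeneous_net):
        rep = cv_on_nodes(small_homogeneous_net, _OracleMethod(), folds=5, runs=1, seed=0)
        assert set(rep.records["family"]) == {"LSxTS", "TSxTS"}

    def test_heldout_label_cannot_influence_its_score(self, small_bipartite_net):
        """Train/test hygiene: flipping a held-out adjacency entry leaves
        every test score unchanged (only training labels enter the fit)."""
        method = GlobalMethod(LearnerParams(n_trees=5, seed=1))
        plan = next(
            pair_fold_plans(small_bipartite_net, known_pairs(small_bipartite_net),
                            5, 1, seed=4)
        )
        test = plan.tests["LSxLS"]
        fitted = method.fit_fold(small_bipartite_net, plan.train, None, None, seed=7)
        s1 = fitted.predict("LSxLS", test.row_idx, test.col_idx)

        adj = small_bipartite_net.adjacency.copy()
        r0, c0 = test.row_idx[0], test.col_idx[0]
        adj[r0, c0] = 1.0 - adj[r0, c0]
        net2 = Network(small_bipartite_net.rows, small_bipartite_net.cols, adj)
        train2 = net2  # rebuild the same train pairs against the mutated net
        from treepairs.network import PairSample

        train2 = PairSample(
            plan.train.row_idx, plan.train.col_idx,
            adj[plan.train.row_idx, plan.train.col_idx], net2,
        )
        fitted2 = method.fit_fold(net2, train2, None, None, seed=7)
        s2 = fitted2.predict("LSxLS", test.row_idx, test.col_idx)
        assert np.array_equal(s1, s2)

    def test_single_class_fold_skipped_with_warning(self):
        net = generate_network(
            SynthConfig(n_rows=12, n_cols=12, p_rows=4, p_cols=4,
                        k_row_groups=2, k_col_groups=2, block_density=0.02, seed=5)
        )
        with pytest.warns(UserWarning, match="single-class"):
            rep = cv_on_pairs(net, _ConstantMethod(), folds=10, runs=1, seed=0)
        assert len(rep.skipped) > 0


class TestDegreeBaseline:
    def test_family_score_definitions(self):
        row_deg = np.array([3.0, 0.0])
        col_deg = np.array([5.0, 4.0])
        assert degree_baseline_scores(
            "LSxLS", row_deg, col_deg, [0], [0], False
        )[0] == 8.0
        assert degree_baseline_scores(
            "LSxTS", row_deg, col_deg, [0], [1], False
        )[0] == 3.0
        assert degree_baseline_scores(
            "TSxLS", row_deg, col_deg, [1], [1], False
        )[0] == 4.0
        assert np.all(
            degree_baseline_scores("TSxTS", row_deg, col_deg, [0, 1], [0, 1], False)
            == 0.0
        )

    def test_skewed_fixture_beats_chance_on_lsls(self):
        """Hub-dominated network with no feature signal: degrees predict
        seen-seen pairs well above chance, two-unseen pairs stay at 0.5."""
        cfg = SynthConfig(
            n_rows=80, n_cols=60, p_rows=10, p_cols=10,
            k_row_groups=2, k_col_groups=2, block_density=0.05,
            degree_skew=1.0, seed=9,
        )
        net = generate_network(cfg)
        rep_pairs = cv_on_pairs(net, DegreeBaseline(), folds=5, runs=2, seed=1)
        assert rep_pairs.summary().set_index("family").loc["LSxLS", "auroc"] > 0.6
        rep_nodes = cv_on_nodes(net, DegreeBaseline(), folds=5, runs=2, seed=1)
        tsts = rep_nodes.records.query("family == 'TSxTS'")
        assert np.allclose(tsts["auroc"], 0.5)

    def test_degree_baseline_helper_matches_scores(self, small_bipartite_net):
        pairs = known_pairs(small_bipartite_net)
        plan = next(node_fold_plans(small_bipartite_net, pairs, 5, 1, seed=0))
        scores = degree_baseline(plan)
        assert set(scores) == {"LSxTS", "TSxLS", "TSxTS"}


def test_get_method_registry():
    assert get_method("global").name == "global"
    assert get_method("local-so").name == "local-so"
    assert get_method("baseline").trains_ensembles is False
    with pytest.raises(ValueError):
        get_method("svm")


def test_report_summary_and_serialization(tmp_path, small_bipartite_net):
    rep = cv_on_pairs(small_bipartite_net, _OracleMethod(), folds=3, runs=1, seed=0)
    s = rep.summary()
    assert list(s.columns) == ["family", "aupr", "auroc"]
    rep.to_tsv(tmp_path / "r.tsv")
    rep.to_json(tmp_path / "r.json")
    import json

    payload = json.loads((tmp_path / "r.json").read_text())
    assert payload["summary"]["LSxLS"]["auroc"] == 1.0
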