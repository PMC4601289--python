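"""Reference experiments on the seeded synthetic fixtures.

These bundle the study designs used throughout the documentation and the
reproduction script: the qualitative-ordering benchmark (all methods and
the degree baseline under both CV schemes on the default bipartite
fixture) and the noiseless-recovery experiment (exact reconstruction of a
deterministic network by the two-step local procedure).

Problem sizes are chosen so a full benchmark runs on a single CPU in
minutes: the 200x150 fixture at edge density 0.02 with 10 runs of 5-fold
CV, scored with 20-tree ensembles.
"""

from __future__ import annotations

import numpy as np

from ._seeds import child_seed
from .evaluation import EvalReport, auroc, cv_on_nodes, cv_on_pairs, get_method
from .learners import LearnerParams
from .local_model import LocalPairModel
from .network import known_pairs
from .synthetic import SynthConfig, balanced_holdout, generate_network

__all__ = ["ordering_benchmark", "noiseless_recovery"]

ORDERING_METHODS = ("global", "local-so", "local-mo", "baseline")


def ordering_benchmark(
    seed: int = 0,
    runs: int = 10,
    folds: int = 5,
    n_trees: int = 20,
    cfg: SynthConfig | None = None,
) -> dict[str, dict[str, EvalReport]]:
    """All methods under both CV schemes on the default bipartite fixture.

    Returns ``{method: {"pairs": report, "nodes": report}}``; the
    multi-output local variant has no "pairs" entry (it cannot score
    seen-seen pairs).  Expected qualitative picture: mean AUPR decreases
    from LSxLS over LSxTS/TSxLS to TSxTS for every method, and every
    method beats the degree baseline wherever it is defined.
    """
    if cfg is None:
        cfg = SynthConfig.default_bipartite(seed=child_seed(seed, "net"))
    net = generate_network(cfg)
    params = LearnerParams(n_trees=n_trees)
    out: dict[str, dict[str, EvalReport]] = {}
    for name in ORDERING_METHODS:
        method = get_method(name, params)
        reports: dict[str, EvalReport] = {}
        if name != "local-mo":
            reports["pairs"] = cv_on_pairs(
                net, method, folds=folds, runs=runs, seed=child_seed(seed, "cvp")
            )
        reports["nodes"] = cv_on_nodes(
            net, method, folds=folds, runs=runs, seed=child_seed(seed, "cvn")
        )
        out[name] = reports
    return out


def noiseless_recovery(
    seed: int = 0, n_trees: int = 50, variant: str = "so"
) -> dict[str, float | bool]:
    """Exact-recovery experiment for the two-step local procedure.

    A deterministic network (block probabilities in {0, 1}, exact group
    features, balanced groups) is generated; balanced row/column holdouts
    play the unseen nodes.  Returns the TSxTS AUROC of the two-step
    predictions and whether the binarized step-1 blocks equal the hidden
    true labels exactly.
    """
    cfg = SynthConfig.noiseless(seed=child_seed(seed, "net"))
    net = generate_network(cfg)
    pairs = known_pairs(net)
    ts_rows = balanced_holdout(net.row_groups, 5, seed=child_seed(seed, "tsr"))
    ts_cols = balanced_holdout(net.col_groups, 6, seed=child_seed(seed, "tsc"))
    train = pairs.subset(
        ~(np.isin(pairs.row_idx, ts_rows) | np.isin(pairs.col_idx, ts_cols))
    )
    params = LearnerParams(n_trees=n_trees, seed=child_seed(seed, "fit"))
    res = LocalPairModel(net, params, variant).fit(train)
    res.fit_two_step(ts_rows, ts_cols)
    two = res.two_step
    truth_rows = net.adjacency[np.ix_(ts_rows, res.fitted.ls_cols)].astype(int)
    truth_cols = net.adjacency[np.ix_(res.fitted.ls_rows, ts_cols)].astype(int)
    test = pairs.subset(
        np.isin(pairs.row_idx, ts_rows) & np.isin(pairs.col_idx, ts_cols)
    )
    scores = res.predict(test.row_idx, test.col_idx, "TSxTS")
    return {
        "tsts_auroc": auroc(scores, test.labels),
        "step1_rows_exact": bool(np.array_equal(two.step1_row_labels, truth_rows)),
        "step1_cols_exact": bool(np.array_equal(two.step1_col_labels, truth_cols)),
        "n_tsts_pairs": len(test),
    }
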