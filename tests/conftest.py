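"""Shared fixtures: tiny hand-built networks and seeded synthetic ones."""

import numpy as np
import pytest

from treepairs.learners import LearnerParams
from treepairs.network import Network, NodeSet, known_pairs
from treepairs.synthetic import SynthConfig, generate_network


def make_nodeset(n, p, prefix="n", seed=0):
    rng = np.random.default_rng(seed)
    return NodeSet(
        [f"{prefix}{i}" for i in range(n)],
        rng.normal(size=(n, p)),
        [f"{prefix}f{j}" for j in range(p)],
    )


@pytest.fixture
def tiny_bipartite():
    """3x4 bipartite network, fully known."""
    rows = make_nodeset(3, 2, "r", seed=1)
    cols = make_nodeset(4, 3, "c", seed=2)
    adj = np.array(
        [[1, 0, 0, 1], [0, 1, 0, 0], [0, 0, 0, 0]], dtype=float
    )
    return Network(rows, cols, adj)


@pytest.fixture
def tiny_homogeneous():
    """4-node symmetric network with one unknown entry pair."""
    nodes = make_nodeset(4, 3, "n", seed=3)
    adj = np.array(
        [
            [0, 1, 0, np.nan],
            [1, 0, 1, 0],
            [0, 1, 0, 1],
            [np.nan, 0, 1, 0],
        ],
        dtype=float,
    )
    return Network(nodes, nodes, adj, homogeneous=True)


@pytest.fixture(scope="session")
def small_bipartite_net():
    """Seeded 60x45 bipartite block network with informative features."""
    cfg = SynthConfig(
        n_rows=60, n_cols=45, p_rows=30, p_cols=30,
        k_row_groups=3, k_col_groups=3,
        block_density=np.array(
            [[0.6, 0.05, 0.05], [0.05, 0.6, 0.05], [0.05, 0.05, 0.6]]
        ),
        feature_noise_sd=0.1, seed=7,
    )
    return generate_network(cfg)


@pytest.fixture(scope="session")
def small_homogeneous_net():
    """Seeded 50-node homogeneous block network."""
    cfg = SynthConfig(
        n_rows=50, n_cols=50, p_rows=25, p_cols=25,
        k_row_groups=2, k_col_groups=2,
        block_density=np.array([[0.5, 0.05], [0.05, 0.5]]),
        feature_noise_sd=0.1, homogeneous=True, seed=11,
    )
    return generate_network(cfg)


@pytest.fixture(scope="session")
def fast_params():
    return LearnerParams(n_trees=15, seed=5)


@pytest.fixture(scope="session")
def noiseless_net():
    return generate_network(SynthConfig.noiseless(seed=13))


@pytest.fixture
def tsv_network(tmp_path):
    """Write a network to TSV files, return the three paths."""

    def _write(net):
        from treepairs.network import write_network

        a = tmp_path / "adjacency.tsv"
        r = tmp_path / "row_features.tsv"
        c = None if net.homogeneous else tmp_path / "col_features.tsv"
        write_network(net, a, r, c)
        return a, r, c

    return _write
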