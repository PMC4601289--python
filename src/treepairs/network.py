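"""Data model and I/O for partially observed interaction networks.

A network is a (possibly partially observed) 0/1 adjacency matrix over one
node set (homogeneous, e.g. protein-protein interactions) or two node sets
(bipartite, e.g. transcription factors x genes, drugs x proteins), together
with a numeric feature vector per node.  Unknown adjacency entries are
represented as NaN and are excluded from the learning sample of pairs.

File formats are plain TSV: the adjacency matrix carries column ids in its
header row and row ids in its first column, with cells in {0, 1, NA}; feature
tables carry feature names in the header row and node ids in the first
column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NodeSet",
    "Network",
    "PairSample",
    "NetworkFormatError",
    "UnknownNodeError",
    "load_network",
    "write_network",
    "known_pairs",
    "node_degrees",
    "edge_prevalence",
]


class NetworkFormatError(ValueError):
    """Malformed adjacency/feature input (bad cells, asymmetry, shape)."""


class UnknownNodeError(KeyError):
    """A node id referenced somewhere has no feature row or is missing."""


@dataclass
class NodeSet:
    """An ordered set of nodes with per-node numeric features.

    Parameters
    ----------
    ids : list of str
        Unique node identifiers, order defines matrix orientation.
    features : ndarray of shape (n_nodes, n_features)
    feature_names : list of str
    """

    ids: list[str]
    features: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if len(set(self.ids)) != len(self.ids):
            raise NetworkFormatError("node ids must be unique")
        if self.features.ndim != 2 or self.features.shape[0] != len(self.ids):
            raise NetworkFormatError(
                f"feature matrix has {self.features.shape[0]} rows "
                f"for {len(self.ids)} node ids"
            )
        if self.features.shape[1] != len(self.feature_names):
            raise NetworkFormatError("feature_names length mismatch")
        if self.features.shape[1] and np.isnan(self.features).all(axis=0).any():
            raise NetworkFormatError("feature column entirely NaN")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def index_of(self, node_id: str) -> int:
        try:
            return self.ids.index(node_id)
        except ValueError:
            raise UnknownNodeError(node_id) from None


@dataclass
class Network:
    """A partially observed network: adjacency over one or two node sets.

    ``adjacency`` is an (n_rows, n_cols) float array with entries 0.0, 1.0
    or NaN (unknown).  For homogeneous networks ``rows`` and ``cols`` are the
    same :class:`NodeSet` and the known part of the adjacency is symmetric;
    the diagonal (self-interaction) is ignored throughout.
    """

    rows: NodeSet
    cols: NodeSet
    adjacency: np.ndarray
    homogeneous: bool = False

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        if self.adjacency.shape != (len(self.rows), len(self.cols)):
            raise NetworkFormatError(
                f"adjacency shape {self.adjacency.shape} does not match "
                f"node sets ({len(self.rows)}, {len(self.cols)})"
            )
        known = ~np.isnan(self.adjacency)
        vals = self.adjacency[known]
        if not np.isin(vals, (0.0, 1.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0))][0]
            raise NetworkFormatError(f"adjacency cell {bad!r} not in {{0,1,NA}}")
        if self.homogeneous:
            if self.rows is not self.cols and self.rows.ids != self.cols.ids:
                raise NetworkFormatError("homogeneous network needs one node set")
            both = known & known.T
            a, at = self.adjacency, self.adjacency.T
            if not np.array_equal(a[both], at[both]):
                i, j = np.argwhere(both & (a != at))[0]
                raise NetworkFormatError(
                    f"asymmetric known entries at ({self.rows.ids[i]}, "
                    f"{self.cols.ids[j]})"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.adjacency.shape

    @property
    def known_mask(self) -> np.ndarray:
        return ~np.isnan(self.adjacency)


@dataclass
class PairSample:
    """A labeled sample of node pairs: the learning sample of known entries.

    Stored as parallel integer index arrays plus 0/1 labels; ``source`` is
    the network the indices refer to.  For homogeneous networks only
    unordered pairs (i < j) are present and the diagonal is excluded.
    """

    row_idx: np.ndarray
    col_idx: np.ndarray
    labels: np.ndarray
    source: Network = field(repr=False)

    def __post_init__(self) -> None:
        self.row_idx = np.asarray(self.row_idx, dtype=np.intp)
        self.col_idx = np.asarray(self.col_idx, dtype=np.intp)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        n_r, n_c = self.source.shape
        if len({self.row_idx.shape, self.col_idx.shape, self.labels.shape}) != 1:
            raise ValueError("pair arrays must have equal length")
        if len(self) and (
            self.row_idx.min() < 0
            or self.row_idx.max() >= n_r
            or self.col_idx.min() < 0
            or self.col_idx.max() >= n_c
        ):
            raise IndexError("pair index out of range")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        keys = set(zip(self.row_idx.tolist(), self.col_idx.tolist()))
        if len(keys) != len(self):
            raise ValueError("duplicate (row, col) pairs")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def prevalence(self) -> float:
        """Fraction of positive pairs, the edge density of the sample."""
        return self.n_positive / len(self) if len(self) else 0.0

    def subset(self, mask: np.ndarray) -> "PairSample":
        return PairSample(
            self.row_idx[mask], self.col_idx[mask], self.labels[mask], self.source
        )


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return df


def _parse_features(path) -> NodeSet:
    df = _read_table(path)
    try:
        feats = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise NetworkFormatError(f"non-numeric feature cell in {path}: {exc}") from exc
    return NodeSet(list(df.index), feats, list(df.columns))


_NA_TOKENS = {"na", "nan", ""}


def load_network(adjacency_path, row_features_path, col_features_path=None) -> Network:
    """Load a network from an adjacency TSV and one or two feature TSVs.

    If ``col_features_path`` is omitted the network is homogeneous: rows and
    columns share the single node set, and the known entries of the adjacency
    must be symmetric.  Node ids are matched exactly after whitespace trim;
    feature tables may list nodes in any order.
    """
    adj_df = _read_table(adjacency_path)
    row_ids = list(adj_df.index)
    col_ids = list(adj_df.columns)

    cells = adj_df.to_numpy(dtype=object)
    adjacency = np.empty(cells.shape, dtype=float)
    for (i, j), cell in np.ndenumerate(cells):
        token = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
        if token.lower() in _NA_TOKENS:
            adjacency[i, j] = np.nan
        elif token in ("0", "1"):
            adjacency[i, j] = float(token)
        else:
            raise NetworkFormatError(
                f"adjacency cell {cell!r} at ({row_ids[i]}, {col_ids[j]}) "
                "not in {0,1,NA}"
            )

    row_set = _parse_features(row_features_path)
    homogeneous = col_features_path is None
    col_set = row_set if homogeneous else _parse_features(col_features_path)

    def align(node_set: NodeSet, wanted: list[str], which: str) -> NodeSet:
        missing = set(wanted) - set(node_set.ids)
        if missing:
            raise UnknownNodeError(
                f"{which} ids in adjacency without features: {sorted(missing)[:5]}"
            )
        order = [node_set.ids.index(i) for i in wanted]
        return NodeSet(wanted, node_set.features[order], node_set.feature_names)

    rows = align(row_set, row_ids, "row")
    if homogeneous:
        if set(row_ids) != set(col_ids):
            raise UnknownNodeError("homogeneous adjacency row/column ids differ")
        # reorder columns to the row order so rows and cols share one NodeSet
        perm = [col_ids.index(i) for i in row_ids]
        adjacency = adjacency[:, perm]
        return Network(rows, rows, adjacency, homogeneous=True)
    cols = align(col_set, col_ids, "col")
    return Network(rows, cols, adjacency, homogeneous=False)


def write_network(net: Network, adjacency_path, row_features_path, col_features_path=None) -> None:
    """Write a network back to the TSV formats accepted by :func:`load_network`."""
    unknown = np.isnan(net.adjacency)
    vals = np.nan_to_num(net.adjacency).astype(int).astype(str)
    cells = np.where(unknown, "NA", vals)
    pd.DataFrame(cells, index=net.rows.ids, columns=net.cols.ids).to_csv(
        adjacency_path, sep="\t"
    )
    pd.DataFrame(
        net.rows.features, index=net.rows.ids, columns=net.rows.feature_names
    ).to_csv(row_features_path, sep="\t")
    if not net.homogeneous:
        if col_features_path is None:
            raise ValueError("bipartite network needs col_features_path")
        pd.DataFrame(
            net.cols.features, index=net.cols.ids, columns=net.cols.feature_names
        ).to_csv(col_features_path, sep="\t")


def known_pairs(net: Network) -> PairSample:
    """Enumerate the known adjacency entries as the learning sample of pairs.

    Homogeneous networks contribute each unordered pair (i < j) once and
    never the diagonal.  Enumeration is row-major so seeded downstream runs
    are reproducible.
    """
    known = net.known_mask
    if net.homogeneous:
        known = known & np.triu(np.ones(net.shape, dtype=bool), k=1)
    r, c = np.nonzero(known)
    return PairSample(r, c, net.adjacency[r, c], net)


def node_degrees(sample: PairSample) -> tuple[np.ndarray, np.ndarray]:
    """Training degrees: per-node counts of positive pairs in the sample.

    Returns ``(row_degrees, col_degrees)`` over the source network's node
    sets; nodes absent from the sample have degree 0.  For homogeneous
    networks both vectors are the same per-node degree (each edge counted
    once per endpoint).
    """
    if len(sample) == 0:
        raise ValueError("empty pair sample")
    n_r, n_c = sample.source.shape
    pos = sample.labels == 1
    row_deg = np.bincount(sample.row_idx[pos], minlength=n_r).astype(float)
    col_deg = np.bincount(sample.col_idx[pos], minlength=n_c).astype(float)
    if sample.source.homogeneous:
        deg = row_deg + col_deg
        return deg, deg
    return row_deg, col_deg


def edge_prevalence(n_nodes: int, n_edges: int, *, n_cols: int | None = None) -> float:
    """Edge proportion among all candidate pairs of a fully known network.

    For a homogeneous network of ``n_nodes`` nodes the candidate pairs are
    the C(n, 2) unordered pairs (no self-interactions); for a bipartite
    network pass ``n_cols`` and the candidate pairs are n_nodes * n_cols.
    """
    if n_cols is None:
        total = n_nodes * (n_nodes - 1) // 2
    else:
        total = n_nodes * n_cols
    return n_edges / total
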