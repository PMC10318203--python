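"""Atlas handling, RSFC matrix construction, edge vectorization, lesioning.

A brain atlas here is a flat table of nodes (name, MNI coordinates, one
large-scale network label per node).  Resting-state functional connectivity
(RSFC) between two nodes is the Fisher-z transformed Pearson correlation of
their BOLD time courses, giving one symmetric ``n x n`` matrix per subject.
All downstream modules work on the canonical *edge vector*: the strict upper
triangle of that matrix flattened row-major, so that selected-edge indices are
portable across cross-validation folds and lesion runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("trustcpm")

#: Canonical large-scale networks of the 142-node cortical parcellation,
#: in canonical order.
NETWORKS: tuple[str, ...] = ("DMN", "FPN", "CON", "SMN", "OccN")

#: Node counts per network in the default 142-node parcellation.
NETWORK_SIZES: dict[str, int] = {"DMN": 34, "FPN": 21, "CON": 32, "SMN": 33, "OccN": 22}

#: Label used for cerebellar nodes, which are accepted on input but normally
#: excluded from analysis.
CEREBELLUM = "cerebellum"

_VALID_LABELS = set(NETWORKS) | {CEREBELLUM}

#: Clipping bound applied to correlations before the Fisher z transform.
RSFC_CLIP = 1.0 - 1e-7


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atlas:
    """A node table: name, MNI coordinates (mm), network label.

    Node order is canonical; ``node_index`` is the 0-based position in
    ``table``.  Coordinates are metadata only (used for reporting), never for
    computation.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"name", "x", "y", "z", "network"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        if self.table["name"].duplicated().any():
            dup = self.table.loc[self.table["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate node name: {dup!r}")
        bad = set(self.table["network"]) - _VALID_LABELS
        if bad:
            raise ValueError(f"unknown network label(s): {sorted(bad)}")
        object.__setattr__(self, "table", self.table.reset_index(drop=True))

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    @property
    def networks(self) -> tuple[str, ...]:
        """Networks present, in canonical order."""
        present = set(self.table["network"])
        return tuple(nw for nw in NETWORKS if nw in present) + tuple(
            sorted(present - set(NETWORKS))
        )

    @property
    def node_networks(self) -> np.ndarray:
        """Array of network labels, one per node in canonical order."""
        return self.table["network"].to_numpy()

    def network_size(self, network: str) -> int:
        self._check_network(network)
        return int((self.table["network"] == network).sum())

    def network_nodes(self, network: str) -> np.ndarray:
        """Indices of the nodes belonging to ``network``."""
        self._check_network(network)
        return np.flatnonzero(self.table["network"].to_numpy() == network)

    def _check_network(self, network: str) -> None:
        if network not in set(self.table["network"]):
            raise ValueError(f"network {network!r} not present in atlas")


def load_atlas(
    source: str | Path | pd.DataFrame,
    *,
    exclude_networks: Sequence[str] = (CEREBELLUM,),
    sep: str | None = None,
) -> Atlas:
    """Load an atlas from a delimited text table (or a DataFrame).

    The table must have a header with columns ``name,x,y,z,network``.
    Networks listed in ``exclude_networks`` (the cerebellum by default) are
    dropped before the atlas is constructed; pass ``exclude_networks=()`` to
    keep every row.
    """
    if isinstance(source, pd.DataFrame):
        table = source.copy()
    else:
        table = pd.read_csv(source, sep=sep, engine="python")
    bad = set(table["network"]) - _VALID_LABELS
    if bad:
        raise ValueError(f"unknown network label(s): {sorted(bad)}")
    if exclude_networks:
        dropped = table["network"].isin(set(exclude_networks))
        if dropped.any():
            logger.info("load_atlas: excluding %d node(s) in %s",
                        int(dropped.sum()), sorted(set(exclude_networks)))
        table = table.loc[~dropped]
    return Atlas(table.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Subject connectomes
# ---------------------------------------------------------------------------

@dataclass
class SubjectConnectome:
    """One subject's symmetric Fisher-z RSFC matrix (diagonal fixed at 0)."""

    subject_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectome matrix must be square")
        if not np.isfinite(m[~np.eye(len(m), dtype=bool)]).all():
            raise ValueError(f"non-finite connectivity values for {self.subject_id!r}")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError(f"connectome for {self.subject_id!r} is not symmetric")
        np.fill_diagonal(m, 0.0)
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def compute_rsfc(time_series: np.ndarray, subject_id: str = "") -> SubjectConnectome:
    """Build a Fisher-z RSFC matrix from per-node time courses.

    Parameters
    ----------
    time_series
        ``T x n`` array, one column per atlas node, T >= 3 time points.

    The pairwise Pearson correlations are clipped to ``+/-(1 - 1e-7)`` before
    ``atanh`` so that perfectly (anti)correlated series stay finite; the
    diagonal is set to 0 (self-connectivity is excluded by convention).
    """
    ts = np.asarray(time_series, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time_series must be a T x n array")
    T, n = ts.shape
    if T < 3:
        raise ValueError(f"need at least 3 time points, got {T}")
    spread = np.ptp(ts, axis=0)
    if np.any(spread == 0):
        node = int(np.flatnonzero(spread == 0)[0])
        raise ValueError(f"constant time series for node {node}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -RSFC_CLIP, RSFC_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # enforce exact symmetry against fp asymmetry
    return SubjectConnectome(subject_id=subject_id, matrix=z)


# ---------------------------------------------------------------------------
# Canonical edge vectorization
# ---------------------------------------------------------------------------

def edge_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Node index pairs (i, j), i < j, in canonical row-major order."""
    return np.triu_indices(n_nodes, k=1)


def n_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def edge_index_to_pair(edge_index: int, n_nodes: int) -> tuple[int, int]:
    """Map a canonical edge index back to its node pair (i, j), i < j."""
    m = n_edges(n_nodes)
    if not 0 <= edge_index < m:
        raise IndexError(f"edge index {edge_index} out of range for {n_nodes} nodes")
    rows, cols = edge_pairs(n_nodes)
    return int(rows[edge_index]), int(cols[edge_index])


def vectorize_edges(conn: SubjectConnectome | np.ndarray, *, atol: float = 1e-8) -> np.ndarray:
    """Flatten a symmetric matrix into the canonical edge vector.

    ``devectorize_edges(vectorize_edges(m), n)`` reconstructs ``m`` exactly
    (with a zero diagonal).
    """
    m = conn.matrix if isinstance(conn, SubjectConnectome) else np.asarray(conn, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(m, m.T, atol=atol):
        raise ValueError("matrix is asymmetric beyond tolerance")
    i, j = edge_pairs(m.shape[0])
    return m[i, j].copy()


def devectorize_edges(values: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`; diagonal is set to 0."""
    values = np.asarray(values, dtype=float)
    if values.shape != (n_edges(n_nodes),):
        raise ValueError(
            f"edge vector has length {values.size}, expected {n_edges(n_nodes)}"
        )
    out = np.zeros((n_nodes, n_nodes))
    i, j = edge_pairs(n_nodes)
    out[i, j] = values
    out[j, i] = values
    return out


def stack_edges(conns: Iterable[SubjectConnectome]) -> tuple[np.ndarray, list[str]]:
    """Stack subjects' edge vectors into an ``n_subjects x n_edges`` matrix."""
    vecs, ids = [], []
    for c in conns:
        vecs.append(vectorize_edges(c))
        ids.append(c.subject_id)
    return np.asarray(vecs), ids


# ---------------------------------------------------------------------------
# Network-pair labelling of edges
# ---------------------------------------------------------------------------

def pair_label(network_a: str, network_b: str) -> str:
    """Canonical unordered network-pair label, e.g. ``'DMN-CON'``.

    Ordering follows :data:`NETWORKS`, so the label is the same whichever way
    the two endpoint networks are given.  Within-network edges get labels like
    ``'DMN-DMN'``.
    """
    order = {nw: k for k, nw in enumerate(NETWORKS)}
    a, b = sorted((network_a, network_b), key=lambda nw: order.get(nw, len(order)))
    return f"{a}-{b}"


def network_pair_labels(networks: Sequence[str] = NETWORKS) -> list[str]:
    """All distinct unordered pair labels (within-network included)."""
    out = []
    for a in range(len(networks)):
        for b in range(a, len(networks)):
            out.append(pair_label(networks[a], networks[b]))
    return out


def edge_network_pair(edge_index: int, atlas: Atlas) -> str:
    """Unordered network-pair label of one canonical edge."""
    i, j = edge_index_to_pair(edge_index, atlas.n_nodes)
    nets = atlas.node_networks
    return pair_label(nets[i], nets[j])


def edge_pair_labels(atlas: Atlas) -> np.ndarray:
    """Network-pair label of every canonical edge (vectorized)."""
    i, j = edge_pairs(atlas.n_nodes)
    nets = atlas.node_networks
    return np.array([pair_label(a, b) for a, b in zip(nets[i], nets[j])])


# ---------------------------------------------------------------------------
# Computational lesioning
# ---------------------------------------------------------------------------

def apply_lesion(
    atlas: Atlas,
    conns: Sequence[SubjectConnectome],
    network: str,
) -> tuple[Atlas, list[SubjectConnectome]]:
    """Remove one network's nodes (and all incident edges) from the data.

    Returns a reduced atlas plus reduced connectomes with the remaining node
    order preserved.  The originals are left untouched, so lesioning with an
    empty removal set reproduces whole-brain results exactly.
    """
    atlas._check_network(network)
    keep = np.flatnonzero(atlas.node_networks != network)
    reduced_atlas = Atlas(atlas.table.iloc[keep].reset_index(drop=True))
    reduced = [
        SubjectConnectome(c.subject_id, c.matrix[np.ix_(keep, keep)]) for c in conns
    ]
    return reduced_atlas, reduced


def lesion_edge_mask(atlas: Atlas, network: str) -> np.ndarray:
    """Boolean mask over canonical edges that survive lesioning ``network``.

    Operating on edge vectors directly (rather than rebuilding matrices) gives
    the same reduced dataset: masking then re-indexing edges of the kept nodes
    equals vectorizing the reduced matrices, because removal preserves node
    order and hence canonical edge order.
    """
    atlas._check_network(network)
    gone = atlas.node_networks == network
    i, j = edge_pairs(atlas.n_nodes)
    return ~(gone[i] | gone[j])
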