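"""Common-edge identification and network/pair/node profiling.

Common edges are the edges selected in *every* LOOCV iteration; they
summarize the stable core of the predictive network.  Profiling counts them
per large-scale network, per unordered network pair, and per node.  A
between-network common edge counts toward both of its endpoint networks, so
per-network counts are proportions of all *possible* edges incident to the
network (within-network plus between-network pairs); a within-network-only
denominator is available as an option.
"""

from __future__ import annotations

from functools import reduce

import numpy as np
import pandas as pd

from .atlas_connectome import Atlas, edge_pairs, network_pair_labels, pair_label


def common_edges(result, tail: str = "positive") -> np.ndarray:
    """Canonical indices of edges selected in every LOOCV fold.

    Defined for LOOCV results only (each subject held out once); repeated
    k-fold results are refused because their folds are not a fixed, complete
    set of iterations.
    """
    if result.cv_scheme != "loocv":
        raise ValueError("common edges are defined for LOOCV results only")
    if not result.folds:
        raise ValueError("result contains no folds")
    if tail == "positive":
        sets = [f.positive_edges for f in result.folds]
    elif tail == "negative":
        sets = [f.negative_edges for f in result.folds]
    else:
        raise ValueError("tail must be 'positive' or 'negative'")
    return reduce(np.intersect1d, sets)


def _edge_endpoints(common: np.ndarray, atlas: Atlas) -> tuple[np.ndarray, np.ndarray]:
    common = np.asarray(common, dtype=int)
    if common.size and (common.min() < 0 or common.max() >= atlas.n_edges):
        raise IndexError("common edge index out of range for this atlas")
    i, j = edge_pairs(atlas.n_nodes)
    return i[common], j[common]


def network_denominator(atlas: Atlas, network: str, mode: str = "incident") -> int:
    """Number of possible edges counted toward ``network``.

    ``"incident"``: all node pairs with at least one endpoint in the network,
    i.e. C(s, 2) + s (n - s) for network size s.  ``"within"``: C(s, 2).
    """
    s = atlas.network_size(network)
    n = atlas.n_nodes
    if mode == "incident":
        return s * (s - 1) // 2 + s * (n - s)
    if mode == "within":
        return s * (s - 1) // 2
    raise ValueError("mode must be 'incident' or 'within'")


def network_proportions(
    common: np.ndarray, atlas: Atlas, mode: str = "incident"
) -> pd.DataFrame:
    """Common-edge count and proportion per large-scale network.

    With ``mode="incident"`` (default) a between-network edge counts toward
    both endpoint networks and the denominator is every possible edge
    touching the network; ``mode="within"`` counts and normalizes
    within-network edges only.
    """
    ei, ej = _edge_endpoints(common, atlas)
    nets = atlas.node_networks
    rows = []
    for nw in atlas.networks:
        in_i = nets[ei] == nw
        in_j = nets[ej] == nw
        count = int((in_i & in_j).sum()) if mode == "within" else int((in_i | in_j).sum())
        denom = network_denominator(atlas, nw, mode)
        rows.append({"network": nw, "count": count, "possible": denom,
                     "proportion": count / denom if denom else 0.0})
    return pd.DataFrame(rows)


def pair_proportions(common: np.ndarray, atlas: Atlas) -> pd.DataFrame:
    """Common-edge count and proportion per unordered network pair.

    The pair labels partition the edge set, so the counts sum to
    ``len(common)``; the denominator of pair (A, B) is ``s_A s_B`` for
    distinct networks and ``C(s_A, 2)`` within a network.
    """
    ei, ej = _edge_endpoints(common, atlas)
    nets = atlas.node_networks
    labels = [pair_label(a, b) for a, b in zip(nets[ei], nets[ej])]
    counts = pd.Series(labels).value_counts() if labels else pd.Series(dtype=int)
    rows = []
    for lab in network_pair_labels(atlas.networks):
        a, b = lab.split("-")
        sa, sb = atlas.network_size(a), atlas.network_size(b)
        possible = sa * (sa - 1) // 2 if a == b else sa * sb
        count = int(counts.get(lab, 0))
        rows.append({"pair": lab, "count": count, "possible": possible,
                     "proportion": count / possible if possible else 0.0})
    return pd.DataFrame(rows)


def node_degrees(common: np.ndarray, atlas: Atlas, top_k: int = 10) -> pd.DataFrame:
    """The ``top_k`` nodes with the most incident common edges.

    Degrees over all nodes sum to twice the number of common edges.  Ties
    are broken by canonical node index for determinism.  Returns name, MNI
    coordinates, network and degree, sorted by descending degree.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ei, ej = _edge_endpoints(common, atlas)
    deg = np.bincount(np.concatenate([ei, ej]), minlength=atlas.n_nodes)
    out = atlas.table[["name", "x", "y", "z", "network"]].copy()
    out["degree"] = deg
    out = out.sort_values(["degree"], ascending=False, kind="stable")
    return out.head(top_k).reset_index(drop=True)


def common_edge_table(common: np.ndarray, atlas: Atlas) -> pd.DataFrame:
    """Edge list (node names, networks, pair label) for external plotting."""
    ei, ej = _edge_endpoints(common, atlas)
    names = atlas.table["name"].to_numpy()
    nets = atlas.node_networks
    return pd.DataFrame({
        "edge_index": np.asarray(common, dtype=int),
        "node1": names[ei], "node2": names[ej],
        "network1": nets[ei], "network2": nets[ej],
        "pair": [pair_label(a, b) for a, b in zip(nets[ei], nets[ej])],
    })
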