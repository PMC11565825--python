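"""Protein module detection from embedding features and inter-module structure.

Mirrors the single-cell-style clustering recipe applied to network features:
z-scored features -> Euclidean k-nearest-neighbor graph (k = 25) ->
Louvain community detection (resolution = 1).  Module centroids are mean
feature vectors; modules are related to each other by centroid correlation
and Euclidean distance, and summarized as a complete "closeness" graph
weighted by reciprocal centroid distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import Embedding, WeightedNetwork, warn

__all__ = [
    "knn_graph",
    "louvain_cluster",
    "centroids",
    "centroid_relations",
    "closeness_network",
    "ClusterAssignment",
]

DEFAULT_K = 25
DEFAULT_RESOLUTION = 1.0


@dataclass
class ClusterAssignment:
    """Cluster label per node, labels contiguous from 1 by descending size."""

    labels: pd.Series  # index = node id, values = int cluster id
    k_used: int | None = None
    resolution_used: float | None = None
    seed_used: int | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    def members(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])

    def anchor_modules(self, anchors: list[str]) -> dict[str, int]:
        """Which module each anchor protein landed in (for reporting)."""
        return {a: int(self.labels[a]) for a in anchors if a in self.labels.index}


def knn_graph(embedding: Embedding, k: int = DEFAULT_K) -> nx.Graph:
    """Union-rule k-nearest-neighbor graph on Euclidean feature distance.

    An undirected, unweighted edge (i, j) exists iff j is among i's k
    nearest neighbors or vice versa.  Distance ties are broken by node-name
    order, so the graph is deterministic.

    Features are used as given: z-score learned features with arbitrary
    per-dimension scales first (:func:`~abtau_modnet.embed.zscore`); spectral
    fusion features already encode component importance in their scale and
    should be passed raw.
    """
    names = embedding.node_ids
    n = len(names)
    if k >= n:
        raise ValueError(f"k={k} must be < number of nodes ({n})")
    X = embedding.matrix()
    # squared Euclidean distances, computed blockwise-free (n is desk scale)
    sq = (X * X).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(D, np.inf)
    name_rank = np.argsort(np.argsort(names, kind="stable"), kind="stable")

    G = nx.Graph()
    G.add_nodes_from(names)
    for i in range(n):
        order = np.lexsort((name_rank, D[i]))[:k]
        for j in order:
            G.add_edge(names[i], names[int(j)])
    return G


def louvain_cluster(
    graph: nx.Graph, resolution: float = DEFAULT_RESOLUTION, seed: int = 0
) -> ClusterAssignment:
    """Louvain modularity clustering; labels 1..K by descending size."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = nx.community.louvain_communities(graph, resolution=resolution, seed=seed)
    # order clusters by (size desc, smallest member name) for stable labels
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = {}
    for cid, members in enumerate(comms, start=1):
        for m in members:
            labels[m] = cid
    ser = pd.Series({n: labels[n] for n in graph.nodes}, name="cluster")
    return ClusterAssignment(labels=ser, resolution_used=resolution, seed_used=seed)


def centroids(embedding: Embedding, clusters: ClusterAssignment) -> pd.DataFrame:
    """Mean feature vector per cluster; index = cluster id, plus a size column stored in attrs."""
    missing = set(embedding.node_ids) - set(clusters.labels.index)
    if missing:
        raise ValueError(f"assignment missing nodes: {sorted(missing)[:5]}")
    lab = clusters.labels.loc[embedding.node_ids]
    cent = embedding.features.groupby(lab).mean()
    cent.index.name = "cluster"
    cent.attrs["sizes"] = lab.value_counts().sort_index().to_dict()
    return cent


def centroid_relations(cents: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and Euclidean distance for every unordered cluster pair."""
    ids = list(cents.index)
    if len(ids) < 2:
        raise ValueError("need >= 2 clusters")
    X = cents.to_numpy(dtype=float)
    recs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = X[i], X[j]
            dist = float(np.linalg.norm(a - b))
            if a.std() == 0 or b.std() == 0:
                r = np.nan  # correlation undefined for a constant centroid
            else:
                r = float(np.corrcoef(a, b)[0, 1])
            recs.append({"cluster_a": ids[i], "cluster_b": ids[j], "pearson_r": r, "distance": dist})
    return pd.DataFrame(recs)


def closeness_network(cents: pd.DataFrame, epsilon: float = 1e-9) -> WeightedNetwork:
    """Complete cluster graph weighted by reciprocal centroid distance.

    Near-coincident centroids (distance < ``epsilon``) get the capped
    weight 1/epsilon with a warning instead of an infinite edge.
    """
    rel = centroid_relations(cents)
    w = np.empty(len(rel))
    for i, dist in enumerate(rel["distance"]):
        if dist < epsilon:
            warn(f"degenerate centroid distance {dist:.3g}; capping weight at 1/epsilon")
            w[i] = 1.0 / epsilon
        else:
            w[i] = 1.0 / dist
    edges = pd.DataFrame(
        {
            "node_a": rel["cluster_a"].astype(str),
            "node_b": rel["cluster_b"].astype(str),
            "weight": w,
        }
    )
    return WeightedNetwork(nodes=[str(c) for c in cents.index], edges=edges)
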