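"""Similarity network, anchored subnetworks, and community detection.

From the node embedding: build a similarity network keeping the top 5% of
all pairwise inner products, extract the subnetwork anchored on query
proteins (per-anchor top-5% Euclidean neighborhoods, union + anchors),
and partition it with Newman's leading-eigenvector modularity method.
:func:`query_neighborhood` composes the three steps into the interactive
"show me the neighborhood of these genes" query.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import Embedding, WeightedNetwork
from .embed import zscore

__all__ = [
    "similarity_network",
    "anchored_subnetwork",
    "leading_eigenvector_communities",
    "query_neighborhood",
    "CommunityPartition",
]

DEFAULT_Q = 0.05


@dataclass
class CommunityPartition:
    """Community label per node; labels contiguous from 1 by descending size."""

    labels: pd.Series
    method_tag: str = "leading_eigenvector"

    @property
    def n_communities(self) -> int:
        return int(self.labels.max())

    def members(self, community_id: int) -> list[str]:
        return list(self.labels.index[self.labels == community_id])


def _features(embedding: Embedding, use_zscored: bool = False) -> pd.DataFrame:
    # features are used as given by default (spectral fusion features carry
    # meaning in their scale); use_zscored standardizes first, for external
    # embeddings with arbitrary per-dimension scales
    if use_zscored and not embedding.zscored:
        embedding = zscore(embedding)
    return embedding.features


def similarity_network(
    embedding: Embedding, q: float = DEFAULT_Q, use_zscored: bool = False
) -> WeightedNetwork:
    """Keep the top ceil(q * n_pairs) node pairs by feature inner product.

    Ties at the cutoff are broken by lexicographic pair order, so the edge
    count is exactly ceil(q * n(n-1)/2) and the result is deterministic.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    X = _features(embedding, use_zscored)
    names = np.asarray(X.index)
    n = len(names)
    if n < 2:
        raise ValueError("need >= 2 nodes")
    S = X.to_numpy() @ X.to_numpy().T
    iu, ju = np.triu_indices(n, k=1)
    vals = S[iu, ju]
    m = int(np.ceil(q * len(vals)))
    # sort by (value desc, pair lex asc); names[] are compared as strings
    a = np.minimum(names[iu], names[ju])
    b = np.maximum(names[iu], names[ju])
    order = np.lexsort((b, a, -vals))[:m]
    edges = pd.DataFrame({"node_a": a[order], "node_b": b[order], "weight": vals[order]})
    return WeightedNetwork(nodes=list(names), edges=edges)


def anchored_subnetwork(
    network: WeightedNetwork,
    embedding: Embedding,
    anchors: list[str],
    q: float = DEFAULT_Q,
    use_zscored: bool = False,
    intersect: bool = False,
) -> WeightedNetwork:
    """Induced subgraph on the anchors plus their top-q neighborhoods.

    Per anchor, the ceil(q*(n-1)) nearest nodes by Euclidean feature
    distance are collected; by default neighborhoods are unioned (pass
    ``intersect=True`` for the common-neighborhood reading).
    """
    X = _features(embedding, use_zscored)
    names = np.asarray(X.index)
    for a in anchors:
        if a not in X.index:
            raise KeyError(f"anchor {a!r} not in embedding")
    m = int(np.ceil(q * (len(names) - 1)))
    sets = []
    for a in anchors:
        v = X.loc[a].to_numpy()
        others = names[names != a]
        d = np.linalg.norm(X.loc[others].to_numpy() - v, axis=1)
        order = np.lexsort((others, d))[:m]
        sets.append(set(others[order]))
    keep = set.intersection(*sets) if intersect else set.union(*sets)
    keep |= set(anchors)
    return network.subgraph(keep)


def leading_eigenvector_communities(graph: WeightedNetwork) -> CommunityPartition:
    """Newman leading-eigenvector modularity partition (weighted).

    Recursive spectral bisection on the modularity matrix, stopping when no
    split improves modularity; labels assigned by descending community size.
    The ARPACK starting vector is seeded deterministically (with a bounded
    ladder of fallback seeds, since ARPACK can fail to converge from an
    unlucky start), so repeated calls give identical partitions.
    """
    import random

    import igraph as ig

    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    g = graph.to_igraph()
    opts = ig.ARPACKOptions()
    opts.maxiter = 500_000
    clustering = None
    err: Exception | None = None
    try:
        for attempt in range(10):
            ig.set_random_number_generator(random.Random(attempt))
            try:
                clustering = g.community_leading_eigenvector(
                    weights="weight" if graph.n_edges else None, arpack_options=opts
                )
                break
            except ig.InternalError as exc:  # ARPACK non-convergence
                err = exc
    finally:
        ig.set_random_number_generator(None)
    if clustering is None:
        raise RuntimeError(f"leading-eigenvector detection failed to converge: {err}")
    comms = [set(g.vs[idx]["name"] for idx in c) for c in clustering]
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = {}
    for cid, members in enumerate(comms, start=1):
        for mname in members:
            labels[mname] = cid
    order = sorted(graph.nodes)
    return CommunityPartition(labels=pd.Series({n: labels[n] for n in order}, name="community"))


def query_neighborhood(
    embedding: Embedding,
    genes: list[str],
    pct: float = 5.0,
    q_sim: float = DEFAULT_Q,
) -> tuple[WeightedNetwork, CommunityPartition, pd.Series]:
    """AlzPPMap-style query: neighborhood subnetwork + communities.

    ``pct`` is the percentage of neighboring genes to include per query
    gene.  Returns the anchored subnetwork of the top-``q_sim`` similarity
    network, its leading-eigenvector partition, and each retained node's
    Euclidean distance to its nearest query gene.
    """
    X = _features(embedding)
    known = set(X.index)
    unknown = [g for g in genes if g not in known]
    if unknown:
        hints = {g: [k for k in sorted(known) if k.startswith(g[:3])][:3] for g in unknown}
        raise KeyError(f"unknown gene(s) {unknown}; near matches: {hints}")
    sim = similarity_network(embedding, q=q_sim)
    sub = anchored_subnetwork(sim, embedding, genes, q=pct / 100.0)
    part = leading_eigenvector_communities(sub)
    anchor_feats = X.loc[genes].to_numpy()
    dist = pd.Series(
        {
            n: float(np.min(np.linalg.norm(anchor_feats - X.loc[n].to_numpy(), axis=1)))
            for n in sub.nodes
        },
        name="distance_to_nearest_anchor",
    )
    return sub, part, dist
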