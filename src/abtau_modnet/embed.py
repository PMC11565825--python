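"""Per-node feature vectors from the fused networks.

The study pipeline assumes "some" node embedding of the integrated
functional + physical network (originally a trained graph-attention fusion
model producing 512-dimensional features).  Here the contract is simply an
:class:`~abtau_modnet.containers.Embedding`; it can be loaded from a TSV
produced by any external embedder, or computed by :func:`fuse_embed`, a
deterministic spectral fusion embedder: degree-normalize each network's
adjacency, average the normalized matrices, and take the top-d eigenvectors
scaled by sqrt(|eigenvalue|), with a fixed sign convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import Embedding, WeightedNetwork, warn

__all__ = ["load_embedding", "fuse_embed", "zscore"]

DEFAULT_DIM = 512


def load_embedding(path) -> Embedding:
    """Read a node x feature TSV (first column = node id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate node ids: {dups}")
    bad = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise ValueError(f"non-numeric feature columns: {list(bad)}")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in rows: {rows[:5]}")
    return Embedding(features=df.astype(float), zscored=False)


def _norm_adjacency(net: WeightedNetwork, order: list[str]) -> np.ndarray:
    A = net.adjacency(order)
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    return dinv[:, None] * A * dinv[None, :]


def fuse_embed(networks: list[WeightedNetwork], d: int | None = None) -> Embedding:
    """Deterministic spectral fusion of networks sharing one node set.

    Each network's adjacency is symmetrically degree-normalized
    (D^-1/2 A D^-1/2), the normalized matrices are averaged, and the
    eigenvectors of the fused matrix belonging to the ``d`` largest
    eigenvalues are taken, each scaled by sqrt(|eigenvalue|), and the
    resulting rows are normalized to unit length (the standard final step
    of spectral embedding, which makes Euclidean proximity reflect
    similarity of connectivity profiles rather than hub magnitude).  The
    sign of each eigenvector is fixed by making its largest-magnitude
    entry positive, so the output is identical across runs and platforms.
    """
    if not networks:
        raise ValueError("need at least one network")
    node_sets = {frozenset(n.nodes) for n in networks}
    if len(node_sets) != 1:
        raise ValueError("networks must share an identical node set (run intersect_nodes)")
    order = sorted(networks[0].nodes)
    n = len(order)
    if d is None:
        d = min(DEFAULT_DIM, n - 1)
    if d > n - 1:
        raise ValueError(f"d={d} too large for {n} nodes (max {n - 1})")
    if all(net.n_edges == 0 for net in networks):
        raise ValueError("all networks are edgeless; nothing to embed")

    M = np.mean([_norm_adjacency(net, order) for net in networks], axis=0)
    evals, evecs = np.linalg.eigh(M)  # ascending
    top = np.argsort(evals, kind="stable")[::-1][:d]
    V = evecs[:, top] * np.sqrt(np.abs(evals[top]))[None, :]
    # fixed sign convention: largest-|entry| of each column is positive
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    V = V / np.where(norms > 0, norms, 1.0)
    feats = pd.DataFrame(V, index=order, columns=[f"f{j + 1}" for j in range(d)])
    return Embedding(features=feats, zscored=False)


def zscore(embedding: Embedding) -> Embedding:
    """Standardize each feature column (population sd).

    Constant columns become all zeros with a warning rather than NaN.
    """
    X = embedding.matrix()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population (n) denominator
    const = sd == 0
    if const.any():
        warn(f"{int(const.sum())} constant feature column(s) set to zero")
    sd_safe = np.where(const, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, const] = 0.0
    feats = pd.DataFrame(Z, index=embedding.features.index, columns=embedding.features.columns)
    return Embedding(features=feats, zscored=True)
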