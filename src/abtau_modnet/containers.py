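"""Core in-memory containers shared across the pipeline stages.

All containers wrap :class:`pandas.DataFrame` objects so that TSV round-trips
are trivial and downstream code can use ordinary pandas idioms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Abundance",
    "WeightedNetwork",
    "Embedding",
    "CellData",
]


@dataclass
class Abundance:
    """Sample x protein abundance matrix with per-sample clinical metadata.

    Attributes
    ----------
    values : DataFrame
        Rows indexed by sample id, columns named by protein (gene symbol).
    meta : DataFrame
        Indexed by sample id, with at least ``diagnosis`` (one of
        ``NCI, MCI, AD-dementia, other``) and ``mmse`` (0-30).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            self.meta = self.meta.loc[self.values.index]

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        out = pd.concat([self.meta, self.values], axis=1)
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, meta_cols=("diagnosis", "mmse")) -> "Abundance":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        df.index.name = None
        meta = df[list(meta_cols)]
        values = df.drop(columns=list(meta_cols))
        return cls(values=values, meta=meta)


@dataclass
class WeightedNetwork:
    """Undirected weighted network stored as an edge table over named nodes.

    ``edges`` has columns ``node_a``, ``node_b``, ``weight``; each unordered
    pair appears at most once (``node_a < node_b`` lexicographically) and
    there are no self-loops.  ``nodes`` may contain isolated nodes not
    present in any edge.
    """

    nodes: list[str]
    edges: pd.DataFrame

    def __post_init__(self) -> None:
        e = self.edges
        if len(e):
            a = np.minimum(e["node_a"], e["node_b"])
            b = np.maximum(e["node_a"], e["node_b"])
            e = e.assign(node_a=a, node_b=b)
            if (e["node_a"] == e["node_b"]).any():
                raise ValueError("self-loops are not allowed")
            e = e.drop_duplicates(subset=["node_a", "node_b"])
            e = e.sort_values(["node_a", "node_b"], kind="stable").reset_index(drop=True)
        self.edges = e

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self, node_order: list[str] | None = None) -> np.ndarray:
        """Dense symmetric adjacency matrix in the given node order."""
        order = list(node_order) if node_order is not None else sorted(self.nodes)
        idx = {n: i for i, n in enumerate(order)}
        n = len(order)
        A = np.zeros((n, n))
        for a, b, w in self.edges.itertuples(index=False):
            i, j = idx[a], idx[b]
            A[i, j] = A[j, i] = w
        return A

    def subgraph(self, keep: set[str]) -> "WeightedNetwork":
        keep = set(keep)
        mask = self.edges["node_a"].isin(keep) & self.edges["node_b"].isin(keep)
        return WeightedNetwork(
            nodes=[n for n in self.nodes if n in keep],
            edges=self.edges.loc[mask].reset_index(drop=True),
        )

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "WeightedNetwork":
        edges = pd.read_csv(path, sep="\t")
        edges.columns = ["node_a", "node_b", "weight"]
        nodes = sorted(set(edges["node_a"]) | set(edges["node_b"]))
        return cls(nodes=nodes, edges=edges)

    def to_igraph(self):
        import igraph as ig

        order = sorted(self.nodes)
        idx = {n: i for i, n in enumerate(order)}
        pairs = [(idx[a], idx[b]) for a, b in zip(self.edges["node_a"], self.edges["node_b"])]
        g = ig.Graph(n=len(order), edges=pairs)
        g.vs["name"] = order
        g.es["weight"] = list(self.edges["weight"])
        return g


@dataclass
class Embedding:
    """Node x feature matrix (fused network representation).

    ``features`` is indexed by node id with columns ``f1..fd``.
    """

    features: pd.DataFrame
    zscored: bool = False

    def __post_init__(self) -> None:
        if self.features.index.has_duplicates:
            raise ValueError("duplicate node ids in embedding")
        if self.features.isna().any().any():
            raise ValueError("embedding contains NaN")

    @property
    def node_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def matrix(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        out = self.features.copy()
        out.index.name = "node"
        out.to_csv(path, sep="\t")


@dataclass
class CellData:
    """Cell x gene expression with per-cell subtype/condition/donor labels."""

    values: pd.DataFrame  # cells x genes, nonnegative
    labels: pd.DataFrame  # index = cell id; columns subtype, condition, donor

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            self.labels = self.labels.loc[self.values.index]
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, values_path, labels_path) -> None:
        v = self.values.copy()
        v.index.name = "cell_id"
        v.to_csv(values_path, sep="\t")
        lab = self.labels.copy()
        lab.index.name = "cell_id"
        lab.to_csv(labels_path, sep="\t")


def warn(msg: str) -> None:
    warnings.warn(msg, UserWarning, stacklevel=2)
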