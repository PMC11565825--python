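"""Construction of the functional (co-expression) and physical (PPI) networks.

The functional network scores every protein pair by Pearson correlation
across samples, keeps pairs significant after Benjamini-Hochberg correction,
and min-max normalizes the retained correlations to [0, 1] edge weights.
The physical network is a confidence-filtered interaction list, likewise
normalized.  Both are finally restricted to their common node set before
embedding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Abundance, WeightedNetwork, warn

__all__ = [
    "select_cohort",
    "aggregate_by_symbol",
    "bh_adjust",
    "correlation_network",
    "filter_ppi",
    "intersect_nodes",
    "CohortError",
]


class CohortError(ValueError):
    """No samples survive the cohort-selection rule."""


def select_cohort(matrix: Abundance, mmse_min: int = 21) -> Abundance:
    """Keep MCI samples plus early-dementia samples (MMSE >= ``mmse_min``).

    Mirrors a cohort restricted to mild cognitive impairment and early
    Alzheimer's dementia, where "early" is operationalized by a Mini-Mental
    State Examination score of at least 21.  Sample order is preserved.
    """
    diag = matrix.meta["diagnosis"]
    mmse = matrix.meta["mmse"]
    keep = (diag == "MCI") | ((diag == "AD-dementia") & (mmse >= mmse_min))
    if not keep.any():
        counts = diag.value_counts().to_dict()
        raise CohortError(f"no samples retained; diagnosis counts: {counts}")
    return Abundance(values=matrix.values.loc[keep], meta=matrix.meta.loc[keep])


def aggregate_by_symbol(matrix: Abundance) -> Abundance:
    """Sum abundance columns sharing a gene symbol; keeps first-occurrence order."""
    cols = matrix.values.columns
    if cols.is_unique:
        return matrix
    order = list(dict.fromkeys(cols))
    summed = matrix.values.T.groupby(level=0, sort=False).sum().T
    return Abundance(values=summed[order], meta=matrix.meta)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, multiply by n/rank, then take the cumulative minimum
    from the largest rank down; results are capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        # degenerate: keep edges rather than silently zeroing them out
        return np.ones_like(x)
    return (x - lo) / (hi - lo)


def correlation_network(
    matrix: Abundance, alpha: float = 0.05, use_absolute_r: bool = False
) -> WeightedNetwork:
    """Pearson co-expression network with BH-filtered edges.

    All protein pairs are scored by Pearson r with a two-sided p-value from
    the t transform ``t = r*sqrt((n-2)/(1-r^2))``; BH is applied across all
    tested pairs and pairs with adjusted p < ``alpha`` are kept.  Retained
    correlations (signed by default) are min-max normalized to [0, 1].
    Zero-variance proteins are dropped with a warning.
    """
    X = matrix.values.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 samples for correlation, got {n}")
    sd = X.std(axis=0)
    if (sd == 0).any():
        dropped = [c for c, s in zip(matrix.values.columns, sd) if s == 0]
        warn(f"dropping {len(dropped)} zero-variance proteins: {dropped[:5]}...")
        keepcols = sd > 0
        X = X[:, keepcols]
    names = [c for c, s in zip(matrix.values.columns, sd) if s > 0]

    R = np.corrcoef(X, rowvar=False)
    iu, ju = np.triu_indices(len(names), k=1)
    r = np.clip(R[iu, ju], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    padj = bh_adjust(p)
    keep = padj < alpha
    scores = np.abs(r[keep]) if use_absolute_r else r[keep]
    nm = np.asarray(names)
    edges = pd.DataFrame(
        {"node_a": nm[iu[keep]], "node_b": nm[ju[keep]], "weight": _minmax(scores) if keep.any() else []}
    )
    return WeightedNetwork(nodes=names, edges=edges)


def filter_ppi(edges: pd.DataFrame, threshold: float = 0.7) -> WeightedNetwork:
    """Confidence-filter a physical interaction edge list.

    Scores may be on a 0-1 scale or STRING's 0-1000 integer scale; any
    score > 1 triggers division by 1000.  Edges with score strictly above
    ``threshold`` are kept, duplicate A-B/B-A rows collapse to the max
    score, and retained scores are min-max normalized to [0, 1].
    """
    e = edges.copy()
    e.columns = ["node_a", "node_b", "weight"][: len(e.columns)]
    s = e["weight"].to_numpy(dtype=float)
    if np.any(s < 0):
        raise ValueError("negative confidence scores")
    if np.any(s > 1.0):
        if np.any(s > 1000.0):
            raise ValueError("scores exceed 1000; unknown scale")
        s = s / 1000.0
    e["weight"] = s
    a = np.minimum(e["node_a"], e["node_b"])
    b = np.maximum(e["node_a"], e["node_b"])
    e = e.assign(node_a=a, node_b=b)
    e = e[e["node_a"] != e["node_b"]]
    e = e.groupby(["node_a", "node_b"], as_index=False)["weight"].max()
    e = e[e["weight"] > threshold].reset_index(drop=True)
    if len(e):
        e["weight"] = _minmax(e["weight"].to_numpy())
    nodes = sorted(set(e["node_a"]) | set(e["node_b"]))
    return WeightedNetwork(nodes=nodes, edges=e)


def intersect_nodes(
    a: WeightedNetwork, b: WeightedNetwork
) -> tuple[WeightedNetwork, WeightedNetwork]:
    """Restrict both networks to their common nodes (sorted name order)."""
    common = set(a.nodes) & set(b.nodes)
    if not common:
        raise ValueError("node intersection is empty")
    order = sorted(common)
    ra, rb = a.subgraph(common), b.subgraph(common)
    ra.nodes = order
    rb.nodes = order
    return ra, rb
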