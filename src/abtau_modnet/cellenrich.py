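"""Scoring protein communities against labeled single-cell expression.

Three instruments:

* a control-matched signature score per cell (average expression of a gene
  set minus the average of expression-matched control genes), the standard
  single-cell "module score";
* a per-subtype combined score = mean signature score x proportion of
  signature-positive cells, optionally min-max normalized across subtypes;
* a generic hypergeometric over-representation test against named gene-set
  collections (GMT), BH-corrected;

plus a subtype-composition test (per-donor frequencies, one-way ANOVA
across conditions, Tukey HSD when the ANOVA is significant).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CellData, warn
from .netbuild import bh_adjust

__all__ = [
    "module_score",
    "combined_score",
    "hypergeom_ora",
    "composition_test",
    "read_gmt",
]

DEFAULT_CTRL_BINS = 24
DEFAULT_CTRL_PER_GENE = 100


def module_score(
    cells: CellData,
    gene_set: list[str],
    n_ctrl_bins: int = DEFAULT_CTRL_BINS,
    n_ctrl_per_gene: int = DEFAULT_CTRL_PER_GENE,
    seed: int = 0,
) -> pd.Series:
    """Control-subtracted signature score per cell.

    Genes are ranked by dataset-wide mean expression and cut into
    ``n_ctrl_bins`` equal-size bins; for each set gene, ``n_ctrl_per_gene``
    control genes are drawn (seeded) from its bin.  The score is the mean
    expression of the set genes minus the mean expression of the pooled
    control draw, per cell.  Set members absent from the data are dropped
    with a warning.
    """
    present = [g for g in gene_set if g in cells.values.columns]
    missing = [g for g in gene_set if g not in cells.values.columns]
    if missing:
        warn(f"{len(missing)} gene-set member(s) absent from expression data: {missing[:5]}")
    if not present:
        raise ValueError("no gene-set member present in expression data")

    means = cells.values.mean(axis=0)
    order = means.sort_values(kind="stable").index
    n_bins = min(n_ctrl_bins, len(order))
    bin_of = {}
    for b, chunk in enumerate(np.array_split(np.asarray(order), n_bins)):
        for g in chunk:
            bin_of[g] = b
    bins = [list(chunk) for chunk in np.array_split(np.asarray(order), n_bins)]

    rng = np.random.default_rng(seed)
    controls: list[str] = []
    for g in present:
        pool = bins[bin_of[g]]
        take = rng.choice(len(pool), size=n_ctrl_per_gene, replace=len(pool) < n_ctrl_per_gene)
        controls.extend(pool[i] for i in take)

    set_mean = cells.values[present].mean(axis=1)
    ctrl_mean = cells.values[controls].mean(axis=1)
    return (set_mean - ctrl_mean).rename("module_score")


def combined_score(
    cells: CellData, score: pd.Series, normalize: bool = True
) -> pd.DataFrame:
    """Per-subtype combined score table.

    combined = (mean per-cell score) x (proportion of cells with score > 0),
    per subtype; when ``normalize`` is set and >= 2 distinct values exist,
    the combined column is min-max scaled so the top subtype reads 1.
    """
    df = pd.DataFrame({"score": score, "subtype": cells.labels["subtype"]})
    grp = df.groupby("subtype")["score"]
    out = pd.DataFrame(
        {
            "mean_score": grp.mean(),
            "positive_proportion": grp.apply(lambda s: float((s > 0).mean())),
        }
    )
    out["combined"] = out["mean_score"] * out["positive_proportion"]
    if normalize:
        lo, hi = out["combined"].min(), out["combined"].max()
        out["combined_normalized"] = (
            (out["combined"] - lo) / (hi - lo) if hi > lo else 1.0
        )
    return out.sort_index()


def hypergeom_ora(
    query: set[str],
    universe: set[str],
    collections: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each collection set.

    For overlap k with a set of size K in a universe of size N and a query
    of size n, p = P[X >= k], X ~ Hypergeometric(N, K, n).  BH correction is
    applied across collections; rows with adjusted p < ``alpha`` are flagged.
    Collection sets are intersected with the universe first.
    """
    query = set(query)
    universe = set(universe)
    if not universe or not query:
        raise ValueError("query and universe must be nonempty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    recs = []
    for name in sorted(collections):
        members = collections[name] & universe
        k = len(query & members)
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        recs.append({"set": name, "set_size": K, "overlap": k, "p_value": p})
    df = pd.DataFrame(recs)
    df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    df["significant"] = df["p_adjusted"] < alpha
    return df.sort_values(["p_value", "set"], kind="stable").reset_index(drop=True)


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (name, description, genes...)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = set(g for g in parts[2:] if g)
    return out


def composition_test(cells: CellData, subtype: str) -> dict:
    """Does the frequency of ``subtype`` differ across conditions?

    Per-donor frequencies of the subtype are compared across conditions by
    one-way ANOVA; when p < 0.05 a Tukey HSD table of pairwise condition
    contrasts is appended.  Returns a dict with keys ``frequencies``
    (per-donor table), ``anova`` (F, p), and ``tukey`` (DataFrame or None).
    """
    lab = cells.labels
    freq = (
        lab.assign(is_sub=lab["subtype"] == subtype)
        .groupby(["condition", "donor"], observed=True)["is_sub"]
        .mean()
        .reset_index()
        .rename(columns={"is_sub": "frequency"})
    )
    counts = freq.groupby("condition")["donor"].count()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError(f"need >= 2 donors per condition and >= 2 conditions; got {counts.to_dict()}")
    groups = [g["frequency"].to_numpy() for _, g in freq.groupby("condition")]
    if np.ptp(freq["frequency"].to_numpy()) == 0:
        F, p = 0.0, 1.0  # all frequencies identical: no variance to explain
    else:
        F, p = stats.f_oneway(*groups)
    tukey = None
    if p < 0.05:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(freq["frequency"].to_numpy(), freq["condition"].to_numpy())
        tukey = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return {"frequencies": freq, "anova": {"F": float(F), "p": float(p)}, "tukey": tukey}
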