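"""Moderator inference for the anchor-pair (APP-MAPT) dependence.

A two-group variant of the MINDy (Modulator Inference by Network Dynamics)
idea: a candidate moderator M of the dependence between anchors X and Y is
scored by

    dMI(M) = | MI(X, Y | M in top 35%) - MI(X, Y | M in bottom 35%) |

where MI is mutual information in bits estimated from equal-frequency
discretized abundances, and the strata are the samples in the top and
bottom 35% of M's abundance.  Significance comes from a resampling null in
which stratum membership is randomized (the anchors' joint distribution is
preserved), with an add-one permutation p-value; candidates are the
proteins embedded near both anchors (intersection of the top-5%
neighborhoods), and BH correction is applied across candidates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import Abundance, Embedding, warn
from .netbuild import bh_adjust

__all__ = [
    "StratifiedSamples",
    "candidate_moderators",
    "stratify",
    "mutual_information",
    "delta_mi",
    "resample_pvalue",
    "score_moderators",
    "run_mindy",
    "default_bins",
]

DEFAULT_FRACTION = 0.35
DEFAULT_Q = 0.05
DEFAULT_B = 1000


@dataclass
class StratifiedSamples:
    """Top/bottom expression strata for one candidate moderator."""

    modulator_id: str
    top_ids: list[str]
    bottom_ids: list[str]
    fraction: float = DEFAULT_FRACTION


def default_bins(n_stratum: int) -> int:
    """Plug-in bin count for the MI estimator: floor(sqrt(n/5)), clamped to [2, 8]."""
    return int(np.clip(np.sqrt(n_stratum / 5.0), 2, 8))


def candidate_moderators(
    embedding: Embedding, anchors: tuple[str, str], q: float = DEFAULT_Q
) -> list[str]:
    """Proteins in the top-q Euclidean neighborhood of *both* anchors.

    For each anchor, the ceil(q*(n-1)) nearest non-anchor nodes are taken
    (features as given — z-score external embeddings first); the
    intersection is returned sorted by summed distance to the two anchors,
    ascending.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    for a in anchors:
        if a not in embedding.features.index:
            raise KeyError(f"anchor {a!r} not present in embedding")
    X = embedding.features
    names = np.asarray(X.index)
    others = names[~np.isin(names, list(anchors))]
    m = int(np.ceil(q * (len(names) - 1)))
    neigh_sets = []
    dists = {}
    for a in anchors:
        v = X.loc[a].to_numpy()
        d = np.linalg.norm(X.loc[others].to_numpy() - v, axis=1)
        dists[a] = dict(zip(others, d))
        order = np.lexsort((others, d))[:m]
        neigh_sets.append(set(others[order]))
    common = neigh_sets[0] & neigh_sets[1]
    return sorted(common, key=lambda g: (dists[anchors[0]][g] + dists[anchors[1]][g], g))


def stratify(
    matrix: Abundance, modulator: str, fraction: float = DEFAULT_FRACTION
) -> StratifiedSamples:
    """Split samples into the top and bottom ``fraction`` by moderator abundance.

    Each stratum has floor(fraction * n) samples.  Samples are ordered by
    (abundance, sample name); the bottom stratum is the first block of that
    ordering and the top stratum the last, so ties resolve
    deterministically.  An all-tied moderator still yields a valid,
    name-ordered split (with a warning).
    """
    if modulator not in matrix.values.columns:
        raise KeyError(f"modulator {modulator!r} not in abundance matrix")
    vals = matrix.values[modulator]
    n = len(vals)
    m = int(np.floor(fraction * n))
    if 2 * m > n:
        raise ValueError(f"strata of size {m} would overlap at n={n}")
    if m == 0:
        raise ValueError("fraction too small: empty strata")
    order = vals.reset_index()
    order.columns = ["sample", "value"]
    order = order.sort_values(["value", "sample"], kind="stable")
    if vals.nunique() == 1:
        warn(f"modulator {modulator!r} is constant; split falls back to sample-name order")
    bottom = list(order["sample"].iloc[:m])
    top = list(order["sample"].iloc[n - m :])
    return StratifiedSamples(modulator_id=modulator, top_ids=top, bottom_ids=bottom, fraction=fraction)


def _ef_bins(v: np.ndarray, k: int) -> np.ndarray:
    """Equal-frequency bin labels via ranks (stable ties -> deterministic,
    invariant under strictly monotone transforms)."""
    n = v.shape[0]
    order = np.argsort(v, kind="stable")
    b = np.empty(n, dtype=np.int64)
    b[order] = (np.arange(n) * k) // n
    return b


def _mi_bits(bx: np.ndarray, by: np.ndarray, k: int) -> float:
    """MI in bits from two integer bin-label vectors (0..k-1)."""
    n = bx.shape[0]
    joint = np.bincount(bx * k + by, minlength=k * k).astype(float) / n
    px = joint.reshape(k, k).sum(axis=1)
    py = joint.reshape(k, k).sum(axis=0)
    denom = np.outer(px, py).ravel()
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / denom[nz])))


def mutual_information(x, y, n_bins: int | None = None) -> float:
    """Mutual information MI(X, Y) in bits after equal-frequency binning.

    MI = sum_xy p(x,y) log2( p(x,y) / (p(x) p(y)) ), with 0 log 0 = 0.
    ``n_bins`` defaults to :func:`default_bins`(len(x)).  A constant input
    carries no information: MI = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = x.shape[0]
    if n_bins is None:
        n_bins = default_bins(n)
    if n < 2 * n_bins:
        warn(f"n={n} < 2*n_bins={2 * n_bins}; MI estimate will be coarse")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warn("constant input vector; MI set to 0")
        return 0.0
    return _mi_bits(_ef_bins(x, n_bins), _ef_bins(y, n_bins), n_bins)


def mi_from_joint(joint) -> float:
    """MI in bits computed directly from a joint count (or probability) table."""
    J = np.asarray(joint, dtype=float)
    J = J / J.sum()
    px = J.sum(axis=1, keepdims=True)
    py = J.sum(axis=0, keepdims=True)
    nz = J > 0
    return float(np.sum(J[nz] * np.log2(J[nz] / (px @ py)[nz])))


def delta_mi(
    matrix: Abundance,
    anchors: tuple[str, str],
    strata: StratifiedSamples,
    n_bins: int | None = None,
) -> tuple[float, float, float]:
    """(mi_top, mi_bottom, |difference|) of anchor MI across the two strata."""
    for a in anchors:
        if a not in matrix.values.columns:
            raise KeyError(f"anchor {a!r} not in abundance matrix")
    x = matrix.values[anchors[0]]
    y = matrix.values[anchors[1]]
    k = n_bins if n_bins is not None else default_bins(len(strata.top_ids))
    for ids in (strata.top_ids, strata.bottom_ids):
        if len(ids) < k:
            raise ValueError(f"stratum of size {len(ids)} smaller than n_bins={k}")
    mi_top = mutual_information(x.loc[strata.top_ids], y.loc[strata.top_ids], k)
    mi_bot = mutual_information(x.loc[strata.bottom_ids], y.loc[strata.bottom_ids], k)
    return mi_top, mi_bot, abs(mi_top - mi_bot)


def _mi_bits_rows(xs: np.ndarray, ys: np.ndarray, k: int) -> np.ndarray:
    """Row-wise MI in bits for (B, m) value arrays (equal-frequency bins)."""
    Bn, m = xs.shape
    ranks = np.broadcast_to((np.arange(m) * k) // m, (Bn, m))
    bx = np.empty((Bn, m), dtype=np.int64)
    by = np.empty((Bn, m), dtype=np.int64)
    np.put_along_axis(bx, np.argsort(xs, axis=1, kind="stable"), ranks, axis=1)
    np.put_along_axis(by, np.argsort(ys, axis=1, kind="stable"), ranks, axis=1)
    code = bx * k + by + np.arange(Bn)[:, None] * (k * k)
    joint = np.bincount(code.ravel(), minlength=Bn * k * k).reshape(Bn, k, k) / m
    px = joint.sum(axis=2)
    py = joint.sum(axis=1)
    denom = px[:, :, None] * py[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(joint > 0, joint * np.log2(joint / denom), 0.0)
    return terms.sum(axis=(1, 2))


def _null_deltas(
    x: np.ndarray, y: np.ndarray, m: int, k: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Null dMI distribution: random disjoint pseudo-strata of size m,
    vectorized across resamples."""
    n = x.shape[0]
    perm = np.argsort(rng.random((B, n)), axis=1)
    it, ib = perm[:, :m], perm[:, m : 2 * m]
    return np.abs(_mi_bits_rows(x[it], y[it], k) - _mi_bits_rows(x[ib], y[ib], k))


def resample_pvalue(
    matrix: Abundance,
    anchors: tuple[str, str],
    modulator: str,
    B: int = DEFAULT_B,
    fraction: float = DEFAULT_FRACTION,
    n_bins: int | None = None,
    seed: int = 0,
) -> float:
    """Permutation p-value for one candidate's observed dMI.

    The null randomizes sample-to-stratum assignment (disjoint random
    pseudo-top / pseudo-bottom sets of the observed sizes), which preserves
    the anchors' joint distribution and tests exactly "stratum membership
    carries no information about the anchor dependence".
    p = (1 + #{null >= observed}) / (B + 1).
    """
    strata = stratify(matrix, modulator, fraction)
    k = n_bins if n_bins is not None else default_bins(len(strata.top_ids))
    _, _, obs = delta_mi(matrix, anchors, strata, k)
    x = matrix.values[anchors[0]].to_numpy(dtype=float)
    y = matrix.values[anchors[1]].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    null = _null_deltas(x, y, len(strata.top_ids), k, B, rng)
    return float((1 + np.sum(null >= obs)) / (B + 1))


def score_moderators(
    matrix: Abundance,
    candidates: list[str],
    anchors: tuple[str, str],
    fraction: float = DEFAULT_FRACTION,
    B: int = DEFAULT_B,
    n_bins: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """dMI + resampling p-value for an explicit candidate list.

    Returns a table with columns modulator, mi_top, mi_bottom, delta_mi,
    p_value, p_adjusted (BH across candidates), rank — sorted by p-value
    then delta descending.  One child seed per candidate keeps the result
    independent of candidate order.
    """
    if not candidates:
        warn("no candidate moderators; returning empty table")
        return pd.DataFrame(
            columns=["modulator", "mi_top", "mi_bottom", "delta_mi", "p_value", "p_adjusted", "rank"]
        )
    x = matrix.values[anchors[0]].to_numpy(dtype=float)
    y = matrix.values[anchors[1]].to_numpy(dtype=float)
    recs = []
    for cand in candidates:
        strata = stratify(matrix, cand, fraction)
        k = n_bins if n_bins is not None else default_bins(len(strata.top_ids))
        mi_t, mi_b, obs = delta_mi(matrix, anchors, strata, k)
        # candidate-specific stream: stable under reordering of candidates
        rng = np.random.default_rng([seed, zlib.crc32(cand.encode()) % (2**31)])
        null = _null_deltas(x, y, len(strata.top_ids), k, B, rng)
        p = float((1 + np.sum(null >= obs)) / (B + 1))
        recs.append(
            {"modulator": cand, "mi_top": mi_t, "mi_bottom": mi_b, "delta_mi": obs, "p_value": p}
        )
    df = pd.DataFrame(recs)
    df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    df = df.sort_values(
        ["p_value", "delta_mi", "modulator"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def run_mindy(
    matrix: Abundance,
    embedding: Embedding,
    anchors: tuple[str, str],
    q: float = DEFAULT_Q,
    fraction: float = DEFAULT_FRACTION,
    B: int = DEFAULT_B,
    n_bins: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full moderator screen: embedding-proximity candidates -> dMI scoring."""
    cands = candidate_moderators(embedding, anchors, q)
    return score_moderators(matrix, cands, anchors, fraction=fraction, B=B, n_bins=n_bins, seed=seed)
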