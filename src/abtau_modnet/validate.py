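"""Interaction-term regression on histopathology tables and severity cross-tabs.

The moderation hypothesis is validated on independent tissue data by
fitting, within each (region, dementia-status) stratum, the ordinary least
squares model

    outcome ~ b0 + b1*x1 + b2*x2 + b3*(x1*x2)

(e.g., Tau2 %area ~ Abeta %area x GFAP %area) and testing b3 with a
two-sided t-test on n-4 degrees of freedom.  Severity cross-tabulation
splits donors into top/bottom expression strata (e.g., by GPNMB) and
tabulates CERAD x Braak score frequencies per stratum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import warn

__all__ = ["fit_interaction", "severity_crosstab"]

CERAD_LEVELS = (1, 2, 3, 4)
BRAAK_LEVELS = (0, 1, 2, 3, 4, 5, 6)


def _ols_fit(y: np.ndarray, X: np.ndarray) -> dict | None:
    """Closed-form OLS with classical standard errors; None if rank-deficient."""
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        return None
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    return {"beta": beta, "se": se, "t": t, "p": p, "n": n, "df": df, "resid": resid}


def fit_interaction(
    table: pd.DataFrame,
    outcome: str,
    x1: str,
    x2: str,
    stratify_by: list[str] = ("region", "dementia"),
) -> pd.DataFrame:
    """Per-stratum OLS of ``outcome ~ x1 + x2 + x1:x2``.

    Rows with missing values in the model columns are dropped (listwise,
    counts logged); strata with fewer than 5 complete rows are skipped with
    a warning and rank-deficient strata are flagged with ``ok = False``.
    Returns a tidy table with one row per stratum and term.
    """
    stratify_by = list(stratify_by)
    cols = [outcome, x1, x2]
    recs = []
    for key, grp in table.groupby(stratify_by, observed=True, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        sub = grp[cols].dropna()
        n_dropped = len(grp) - len(sub)
        if n_dropped:
            warn(f"stratum {key}: dropped {n_dropped} incomplete rows")
        if len(sub) < 5:
            warn(f"stratum {key}: only {len(sub)} complete rows; skipped")
            continue
        y = sub[outcome].to_numpy(dtype=float)
        X = np.column_stack(
            [
                np.ones(len(sub)),
                sub[x1].to_numpy(dtype=float),
                sub[x2].to_numpy(dtype=float),
                sub[x1].to_numpy(dtype=float) * sub[x2].to_numpy(dtype=float),
            ]
        )
        fit = _ols_fit(y, X)
        base = dict(zip(stratify_by, key))
        if fit is None:
            recs.append({**base, "term": "rank_deficient", "ok": False, "n_used": len(sub)})
            continue
        for i, term in enumerate(["intercept", x1, x2, f"{x1}:{x2}"]):
            recs.append(
                {
                    **base,
                    "term": term,
                    "beta": float(fit["beta"][i]),
                    "se": float(fit["se"][i]),
                    "t": float(fit["t"][i]),
                    "p": float(fit["p"][i]),
                    "n_used": fit["n"],
                    "ok": True,
                }
            )
    return pd.DataFrame(recs)


def severity_crosstab(
    expr: pd.Series, cerad: pd.Series, braak: pd.Series, fraction: float = 0.35
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CERAD x Braak frequency tables for top/bottom expression strata.

    Donors are split into the top and bottom floor(fraction * n) by
    ``expr`` (ties resolved by donor name, as in moderator stratification);
    each stratum yields a count table over the full CERAD (1-4) x Braak
    (0-6) grid, zeros included.  Returns (top_table, bottom_table).
    """
    df = pd.DataFrame({"expr": expr, "cerad": cerad, "braak": braak}).dropna()
    n = len(df)
    m = int(np.floor(fraction * n))
    if m == 0 or 2 * m > n:
        raise ValueError(f"invalid stratum size {m} for n={n}")
    order = df.reset_index(names="donor").sort_values(["expr", "donor"], kind="stable")
    bottom = order.iloc[:m]
    top = order.iloc[n - m :]

    def tab(sub: pd.DataFrame) -> pd.DataFrame:
        ct = pd.crosstab(sub["cerad"], sub["braak"])
        ct = ct.reindex(index=CERAD_LEVELS, columns=BRAAK_LEVELS, fill_value=0)
        ct.index.name = "cerad"
        ct.columns.name = "braak"
        return ct

    return tab(top), tab(bottom)
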