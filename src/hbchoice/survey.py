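"""Cost-sensitivity and treatment-attitude analyses.

Willingness-to-pay curves summarize the 5-point likelihood scores given at
each monthly out-of-pocket price as the top-2-box proportion (scores 4-5,
"quite likely"/"definitely"), by group and overall, with linear
interpolation across the unmeasured $300-$450 price points flagged as
extrapolated.  A linear model of score on price yields the reported cost
beta.  Attitude statements (1-5 agreement) are compared between groups with
two-tailed Welch t-tests at the 0.05 level, alongside top-2-box agreement
proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CostBeta",
    "MaxPriceSummary",
    "willingness_curve",
    "cost_beta",
    "max_price_summary",
    "implied_max_prices",
    "compare_attitudes",
]

TOP2_CUTOFF = 4
EXTRAPOLATED_PRICES: tuple[int, ...] = (300, 350, 400, 450)


def willingness_curve(
    prices: pd.DataFrame,
    cutoff: int = TOP2_CUTOFF,
    extrapolate_at: tuple[int, ...] = EXTRAPOLATED_PRICES,
) -> pd.DataFrame:
    """Top-2-box willingness proportion per price, by group and overall.

    ``prices`` needs columns respondent_id, group, price_usd, score.
    Respondents missing any measured price point are excluded with a
    warning.  Unmeasured prices inside the grid's span are filled by linear
    interpolation between the surrounding measured points and flagged with
    ``extrapolated=True``.  Returns a tidy frame: group ("All" plus each
    observed group), price_usd, pct_willing, extrapolated.
    """
    grid = np.sort(prices["price_usd"].unique())
    counts = prices.groupby("respondent_id")["price_usd"].nunique()
    complete = counts[counts == len(grid)].index
    dropped = counts.index.difference(complete)
    if len(dropped):
        warnings.warn(
            f"excluding {len(dropped)} respondent(s) without full price coverage"
        )
    data = prices[prices["respondent_id"].isin(complete)].copy()
    data["willing"] = data["score"] >= cutoff

    rows = []
    group_frames = [("All", data)] + [
        (g, data[data["group"] == g]) for g in sorted(data["group"].unique())
    ]
    for gname, gdata in group_frames:
        pct = gdata.groupby("price_usd")["willing"].mean() * 100.0
        for p in grid:
            rows.append(
                {
                    "group": gname,
                    "price_usd": int(p),
                    "pct_willing": float(pct.loc[p]),
                    "extrapolated": False,
                }
            )
        for p in extrapolate_at:
            if grid.min() < p < grid.max() and p not in grid:
                rows.append(
                    {
                        "group": gname,
                        "price_usd": int(p),
                        "pct_willing": float(np.interp(p, grid, pct.loc[grid])),
                        "extrapolated": True,
                    }
                )
    return (
        pd.DataFrame(rows)
        .sort_values(["group", "price_usd"])
        .reset_index(drop=True)
    )


@dataclass
class CostBeta:
    """OLS fit of likelihood score on monthly price (USD)."""

    group: str
    slope_per_usd: float
    intercept: float
    stderr: float
    price_window: tuple[float, float]
    n_obs: int


def cost_beta(
    prices: pd.DataFrame,
    group: str | None = None,
    price_window: tuple[float, float] | None = None,
) -> CostBeta:
    """Linear-model beta of the 1-5 likelihood score against price.

    Ordinary least squares on respondent-price observations, optionally
    restricted to one group and a price window (inclusive); the window must
    contain at least two distinct prices.
    """
    data = prices if group is None else prices[prices["group"] == group]
    lo = float(data["price_usd"].min() if price_window is None else price_window[0])
    hi = float(data["price_usd"].max() if price_window is None else price_window[1])
    data = data[(data["price_usd"] >= lo) & (data["price_usd"] <= hi)]
    if data["price_usd"].nunique() < 2:
        raise ValueError("price window must contain at least two distinct prices")
    x = sm.add_constant(data["price_usd"].to_numpy(dtype=float))
    res = sm.OLS(data["score"].to_numpy(dtype=float), x).fit()
    return CostBeta(
        group=group or "All",
        slope_per_usd=float(res.params[1]),
        intercept=float(res.params[0]),
        stderr=float(res.bse[1]),
        price_window=(lo, hi),
        n_obs=int(res.nobs),
    )


@dataclass
class MaxPriceSummary:
    mean: float
    median: float
    n: int


def max_price_summary(max_prices) -> MaxPriceSummary:
    """Mean and median of stated maximum acceptable monthly costs."""
    arr = np.asarray(list(max_prices), dtype=float)
    if arr.size == 0:
        raise ValueError("no maximum-price statements")
    if (arr < 0).any():
        raise ValueError("maximum prices must be non-negative")
    return MaxPriceSummary(float(arr.mean()), float(np.median(arr)), int(arr.size))


def implied_max_prices(prices: pd.DataFrame, cutoff: int = TOP2_CUTOFF) -> pd.Series:
    """Highest measured price each respondent still rates at or above the cutoff.

    A stand-in for the survey's stated maximum-acceptable-cost question when
    only the price-grid scores are available; respondents never willing at
    any price get 0.
    """
    willing = prices[prices["score"] >= cutoff]
    out = willing.groupby("respondent_id")["price_usd"].max()
    return out.reindex(prices["respondent_id"].unique(), fill_value=0.0).astype(float)


def compare_attitudes(
    attitudes: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-statement Welch two-sample two-tailed t-tests between groups.

    ``attitudes`` needs columns respondent_id, group, statement_id, score.
    Reports group means, top-2-box agreement percentages (scores 4-5),
    the t statistic, two-sided p-value, and a significance flag at
    ``alpha`` (optionally Bonferroni-adjusted across statements).  When
    both groups have zero variance the test is degenerate: p is 1 for
    equal means and 0 otherwise, reported explicitly.
    """
    statements = list(pd.unique(attitudes["statement_id"]))
    level = alpha / len(statements) if bonferroni else alpha
    rows = []
    for sid in statements:
        sub = attitudes[attitudes["statement_id"] == sid]
        a = sub.loc[sub["group"] == group_a, "score"].to_numpy(dtype=float)
        b = sub.loc[sub["group"] == group_b, "score"].to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"statement {sid!r}: both groups must be non-empty")
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            equal = a.mean() == b.mean()
            t, p = (0.0, 1.0) if equal else (np.inf * np.sign(a.mean() - b.mean()), 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "statement_id": sid,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "top2_pct_a": float((a >= TOP2_CUTOFF).mean() * 100.0),
                "top2_pct_b": float((b >= TOP2_CUTOFF).mean() * 100.0),
                "t": float(t),
                "p_value": float(p),
                "significant": bool(p < level),
            }
        )
    return pd.DataFrame(rows)
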