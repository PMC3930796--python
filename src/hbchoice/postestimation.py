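"""Post-estimation for conjoint part-worths: importance, shares, sensitivity.

Three standard summaries of a fitted choice model:

* **Relative importance (range method):** per respondent, an attribute's
  importance is its part-worth range (best minus worst level) divided by
  the sum of ranges, times 100; the aggregate is the mean of the
  per-respondent percentages, so every importance vector sums to 100.
* **Share of preference:** within a fixed competitive set of products, each
  respondent's logit choice probabilities (or first-choice indicator) are
  averaged across respondents into aggregate percentage shares.
* **Sensitivity:** starting from a base-case pair of products, one attribute
  of one product is flexed through all its levels while everything else
  stays at base case, tracing how that product's share responds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import softmax

from .schema import AttributeSchema, Product, encode_products, level_partworths

__all__ = [
    "ImportanceResult",
    "ShareResult",
    "SensitivityResult",
    "attribute_ranges",
    "relative_importance",
    "preference_shares",
    "sensitivity_analysis",
]


def attribute_ranges(beta, schema: AttributeSchema) -> np.ndarray:
    """Part-worth range (max level utility minus min) per attribute."""
    return np.array([pw.max() - pw.min() for pw in level_partworths(schema, beta)])


@dataclass
class ImportanceResult:
    """Range-method importances, per respondent and aggregated."""

    per_respondent: pd.DataFrame   # respondent_id + one percent column per attribute
    aggregate: pd.Series           # percent per attribute, sums to 100
    excluded: list[str]            # respondents with all-zero ranges


def relative_importance(
    betas: np.ndarray,
    schema: AttributeSchema,
    respondent_ids: list[str] | None = None,
    aggregation: str = "respondent_mean",
) -> ImportanceResult:
    """Range-method relative importance of each attribute.

    ``aggregation='respondent_mean'`` (default) normalizes each respondent's
    ranges to percentages first and averages those; ``'pooled_ranges'``
    averages the raw ranges and normalizes once.  Respondents whose ranges
    are all zero carry no preference information and are excluded with a
    warning.  Both per-respondent and aggregate vectors are renormalized to
    sum to exactly 100.
    """
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    n = betas.shape[0]
    if n == 0:
        raise ValueError("need at least one respondent")
    if respondent_ids is None:
        respondent_ids = [f"R{i + 1:04d}" for i in range(n)]

    ranges = np.array([attribute_ranges(b, schema) for b in betas])  # (N, A)
    totals = ranges.sum(axis=1)
    keep = totals > 0
    excluded = [r for r, k in zip(respondent_ids, keep) if not k]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} respondent(s) with all-zero part-worth ranges"
        )
    if not keep.any():
        raise ValueError("all respondents have zero part-worth ranges")

    imp = 100.0 * ranges[keep] / totals[keep, None]
    if aggregation == "respondent_mean":
        agg = imp.mean(axis=0)
    elif aggregation == "pooled_ranges":
        mean_ranges = ranges[keep].mean(axis=0)
        agg = 100.0 * mean_ranges / mean_ranges.sum()
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    agg = 100.0 * agg / agg.sum()  # guard against numerical drift

    per = pd.DataFrame(imp, columns=schema.names)
    per.insert(0, "respondent_id", [r for r, k in zip(respondent_ids, keep) if k])
    return ImportanceResult(
        per_respondent=per,
        aggregate=pd.Series(agg, index=schema.names, name="importance_pct"),
        excluded=excluded,
    )


@dataclass
class ShareResult:
    """Preference shares over a product set."""

    products: list[Product]
    per_respondent: np.ndarray   # (N, K) probabilities
    aggregate: pd.Series         # percent per product, sums to 100


def _share_matrix(
    betas: np.ndarray, coded: np.ndarray, rule: str
) -> np.ndarray:
    util = betas @ coded.T                      # (N, K)
    if rule == "logit":
        return softmax(util, axis=1)
    if rule == "first_choice":
        # ties split evenly among the argmax set
        best = util == util.max(axis=1, keepdims=True)
        return best / best.sum(axis=1, keepdims=True)
    raise ValueError(f"unknown share rule {rule!r}")


def preference_shares(
    betas: np.ndarray,
    products: list[Product],
    schema: AttributeSchema,
    rule: str = "logit",
) -> ShareResult:
    """Individual-level shares over a product set, averaged into aggregate shares.

    Default rule is the logit (probabilistic) share
    ``exp(x_k' beta_i) / sum_j exp(x_j' beta_i)``; ``rule='first_choice'``
    assigns each respondent's share to their highest-utility product.
    Duplicate product configurations in the set are rejected.
    """
    if len(products) < 2:
        raise ValueError("need at least two products")
    keys = [p.levels for p in products]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate products in the competitive set")
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    coded = encode_products(schema, products)
    shares = _share_matrix(betas, coded, rule)
    agg = 100.0 * shares.mean(axis=0)
    labels = [f"P{k + 1}" for k in range(len(products))]
    return ShareResult(
        products=list(products),
        per_respondent=shares,
        aggregate=pd.Series(agg, index=labels, name="share_pct"),
    )


@dataclass
class SensitivityResult:
    """Share response of one product to flexing one attribute."""

    flexed_product: str           # "A" or "B"
    attribute: str
    base_a: Product
    base_b: Product
    table: pd.DataFrame           # level_index, level, share_pct, is_base
    base_share_pct: float


def sensitivity_analysis(
    betas: np.ndarray,
    base_a: Product,
    base_b: Product,
    schema: AttributeSchema,
    rule: str = "logit",
) -> list[SensitivityResult]:
    """One-attribute-at-a-time share sensitivity from a base-case pair.

    For each attribute and each of its levels, product A (and separately B)
    is rebuilt with that attribute set to the level while every other
    attribute stays at base case, and the flexed product's aggregate share
    against the unchanged competitor is recorded.  The base level reproduces
    the base-case share exactly.
    """
    base_a.validate(schema)
    base_b.validate(schema)
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    results: list[SensitivityResult] = []
    for which, base, other in (("A", base_a, base_b), ("B", base_b, base_a)):
        for j, attr in enumerate(schema):
            rows = []
            base_share = None
            for lvl in range(attr.n_levels):
                levels = list(base.levels)
                levels[j] = lvl
                flexed = Product(tuple(levels))
                coded = encode_products(schema, [flexed, other])
                share = float(
                    100.0 * _share_matrix(betas, coded, rule)[:, 0].mean()
                )
                is_base = lvl == base.levels[j]
                if is_base:
                    base_share = share
                rows.append(
                    {
                        "level_index": lvl,
                        "level": attr.levels[lvl],
                        "share_pct": share,
                        "is_base": is_base,
                    }
                )
            results.append(
                SensitivityResult(
                    flexed_product=which,
                    attribute=attr.name,
                    base_a=base_a,
                    base_b=base_b,
                    table=pd.DataFrame(rows),
                    base_share_pct=float(base_share),
                )
            )
    return results


def sensitivity_frame(results: list[SensitivityResult]) -> pd.DataFrame:
    """Flatten sensitivity results into one tidy table."""
    frames = []
    for r in results:
        t = r.table.copy()
        t.insert(0, "attribute", r.attribute)
        t.insert(0, "product", r.flexed_product)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
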