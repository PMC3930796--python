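"""Blocked, level-balanced paired-choice experimental designs.

The survey instrument shows each respondent one block of paired product
comparisons.  The default plan mirrors the published instrument's shape:
64 distinct scenarios arranged as 8 blocks of 8 pairs, so each block exposes
16 product "slots".  Within every block each attribute's levels are spread
as evenly as possible across those slots (counts differ by at most one), no
product is repeated, and no two scenarios coincide as unordered pairs.

Construction is a seeded greedy search: per block, draw level-balanced
columns, pair consecutive slots into scenarios, repair any duplicate
products by count-preserving swaps, and keep the candidate whose pairwise
attribute-level cross-tabulation is closest to uniform (an orthogonality
proxy).  The search is deterministic given the seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import AttributeSchema, Product, build_default_schema

__all__ = [
    "Scenario",
    "DesignPlan",
    "BalanceReport",
    "generate_design",
    "balance_report",
    "assign_blocks",
]


@dataclass(frozen=True)
class Scenario:
    """One paired comparison: two distinct product configurations A and B."""

    scenario_id: str
    product_a: Product
    product_b: Product

    def __post_init__(self) -> None:
        if self.product_a.levels == self.product_b.levels:
            raise ValueError(
                f"scenario {self.scenario_id}: products A and B are identical"
            )

    @property
    def pair_key(self) -> frozenset:
        """Content identity: the unordered pair of product configurations."""
        return frozenset((self.product_a.levels, self.product_b.levels))


@dataclass
class DesignPlan:
    """A blocked paired-choice design over a schema."""

    schema: AttributeSchema
    blocks: list[list[Scenario]]
    seed: int

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def scenarios(self) -> list[Scenario]:
        return [s for block in self.blocks for s in block]

    def block_of(self, scenario_id: str) -> int:
        for b, block in enumerate(self.blocks):
            if any(s.scenario_id == scenario_id for s in block):
                return b
        raise KeyError(scenario_id)

    def scenario(self, scenario_id: str) -> Scenario:
        for s in self.scenarios:
            if s.scenario_id == scenario_id:
                return s
        raise KeyError(scenario_id)

    # ---- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "schema": self.schema.to_dict(),
            "blocks": [
                [
                    {
                        "scenario_id": s.scenario_id,
                        "product_a": list(s.product_a.levels),
                        "product_b": list(s.product_b.levels),
                    }
                    for s in block
                ]
                for block in self.blocks
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "DesignPlan":
        schema = AttributeSchema.from_dict(d["schema"])
        blocks = [
            [
                Scenario(s["scenario_id"], Product(tuple(s["product_a"])),
                         Product(tuple(s["product_b"])))
                for s in block
            ]
            for block in d["blocks"]
        ]
        return cls(schema=schema, blocks=blocks, seed=int(d["seed"]))

    @classmethod
    def from_json(cls, path: str | Path) -> "DesignPlan":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per (scenario, alternative) with level labels."""
        rows = []
        for b, block in enumerate(self.blocks):
            for s in block:
                for alt, prod in (("A", s.product_a), ("B", s.product_b)):
                    row = {"block_id": b, "scenario_id": s.scenario_id,
                           "alternative": alt}
                    row.update(prod.labels(self.schema))
                    rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class BalanceReport:
    """Level-balance and orthogonality diagnostics for a design plan."""

    level_counts: pd.DataFrame      # block_id, attribute, level, count
    imbalance: pd.DataFrame         # block_id, attribute, imbalance (max-min)
    duplicate_scenarios: int        # unordered-pair collisions across the plan
    duplicate_products: int         # product configurations reused anywhere
    crosstab_deviation: pd.DataFrame  # attribute pair, max |count - expected|

    @property
    def max_imbalance(self) -> int:
        return int(self.imbalance["imbalance"].max())


def _balanced_column(n_slots: int, n_levels: int, offset: int) -> np.ndarray:
    """Level multiset of size n_slots with counts as equal as possible.

    The ``offset`` rotates which levels receive the remainder so that extras
    are spread across blocks rather than always favouring level 0.
    """
    base, extra = divmod(n_slots, n_levels)
    counts = np.full(n_levels, base)
    for k in range(extra):
        counts[(offset + k) % n_levels] += 1
    return np.repeat(np.arange(n_levels), counts)


def _crosstab_score(prods: np.ndarray, schema: AttributeSchema) -> float:
    """Sum over attribute pairs of squared deviation of level cross-tabs from uniform."""
    score = 0.0
    n = prods.shape[0]
    for j, k in itertools.combinations(range(len(schema)), 2):
        lj = schema.attributes[j].n_levels
        lk = schema.attributes[k].n_levels
        counts = np.zeros((lj, lk))
        np.add.at(counts, (prods[:, j], prods[:, k]), 1)
        score += float(((counts - n / (lj * lk)) ** 2).sum())
    return score


def generate_design(
    schema: AttributeSchema | None = None,
    n_blocks: int = 8,
    scenarios_per_block: int = 8,
    seed: int = 0,
    n_candidates: int = 20,
) -> DesignPlan:
    """Construct a blocked, level-balanced paired-choice design.

    Per block, each attribute's levels occupy the 2*scenarios_per_block
    product slots with counts differing by at most one.  Products are unique
    across the whole plan whenever the product space is large enough (hence
    scenarios are too); otherwise only scenario uniqueness is enforced.

    Deterministic given ``seed``.  Raises ``ValueError`` when a block is too
    small to show every level of some attribute.
    """
    if schema is None:
        schema = build_default_schema()
    if n_blocks < 1 or scenarios_per_block < 1:
        raise ValueError("n_blocks and scenarios_per_block must be >= 1")
    n_slots = 2 * scenarios_per_block
    for a in schema:
        if n_slots < a.n_levels:
            raise ValueError(
                f"block of {n_slots} product slots cannot show all "
                f"{a.n_levels} levels of attribute {a.name!r}"
            )
    unique_products = n_blocks * n_slots <= schema.n_products

    rng = np.random.default_rng(seed)
    seen_products: set[tuple[int, ...]] = set()
    seen_pairs: set[frozenset] = set()
    blocks: list[list[Scenario]] = []

    for b in range(n_blocks):
        best: np.ndarray | None = None
        best_score = np.inf
        for _ in range(n_candidates):
            cols = []
            for j, a in enumerate(schema):
                col = _balanced_column(n_slots, a.n_levels, offset=b + j)
                rng.shuffle(col)
                cols.append(col)
            prods = np.stack(cols, axis=1)
            if not _repair_block(prods, schema, seen_products, seen_pairs,
                                 unique_products, rng):
                continue
            score = _crosstab_score(prods, schema)
            if score < best_score:
                best_score = score
                best = prods.copy()
        if best is None:
            raise ValueError(
                f"could not build a valid block {b} after {n_candidates} attempts; "
                "the requested design may be infeasible"
            )
        block = []
        for i in range(scenarios_per_block):
            pa = Product(tuple(best[2 * i]))
            pb = Product(tuple(best[2 * i + 1]))
            block.append(Scenario(f"B{b + 1}S{i + 1}", pa, pb))
        for s in block:
            seen_pairs.add(s.pair_key)
            seen_products.add(s.product_a.levels)
            seen_products.add(s.product_b.levels)
        blocks.append(block)

    return DesignPlan(schema=schema, blocks=blocks, seed=seed)


def _repair_block(
    prods: np.ndarray,
    schema: AttributeSchema,
    seen_products: set[tuple[int, ...]],
    seen_pairs: set[frozenset],
    unique_products: bool,
    rng: np.random.Generator,
    max_tries: int = 400,
) -> bool:
    """Swap-repair a block's slot matrix in place until it is conflict-free.

    Swapping one attribute's value between two slots preserves the per-block
    level counts, so balance survives every repair.  Returns False when the
    conflict set cannot be cleared within the try budget.
    """
    n_slots = prods.shape[0]

    def conflicts() -> list[int]:
        bad: set[int] = set()
        local: dict[tuple[int, ...], int] = {}
        local_pairs: dict[frozenset, int] = {}
        for i in range(0, n_slots, 2):
            a, bv = tuple(prods[i]), tuple(prods[i + 1])
            if a == bv:
                bad.update((i, i + 1))
                continue
            key = frozenset((a, bv))
            if key in seen_pairs or key in local_pairs:
                bad.update((i, i + 1))
            else:
                local_pairs[key] = i
        if unique_products:
            for i in range(n_slots):
                t = tuple(prods[i])
                if t in seen_products:
                    bad.add(i)
                elif t in local:
                    bad.add(i)
                else:
                    local[t] = i
        return sorted(bad)

    for _ in range(max_tries):
        bad = conflicts()
        if not bad:
            return True
        slot = int(rng.choice(bad))
        attr = int(rng.integers(len(schema)))
        others = [i for i in range(n_slots)
                  if i != slot and prods[i, attr] != prods[slot, attr]]
        if not others:
            continue
        other = int(rng.choice(others))
        prods[[slot, other], attr] = prods[[other, slot], attr]
    return not conflicts()


def balance_report(plan: DesignPlan) -> BalanceReport:
    """Per-block level counts and imbalance, duplicate counts, cross-tab deviation."""
    schema = plan.schema
    count_rows, imb_rows = [], []
    all_prods = []
    for b, block in enumerate(plan.blocks):
        slots = np.array(
            [p.levels for s in block for p in (s.product_a, s.product_b)]
        )
        all_prods.append(slots)
        for j, a in enumerate(schema):
            counts = np.bincount(slots[:, j], minlength=a.n_levels)
            for lvl, c in zip(a.levels, counts):
                count_rows.append(
                    {"block_id": b, "attribute": a.name, "level": lvl,
                     "count": int(c)}
                )
            imb_rows.append(
                {"block_id": b, "attribute": a.name,
                 "imbalance": int(counts.max() - counts.min())}
            )
    prods = np.concatenate(all_prods, axis=0)

    pair_keys = [s.pair_key for s in plan.scenarios]
    dup_scen = len(pair_keys) - len(set(pair_keys))
    prod_keys = [tuple(r) for r in prods]
    dup_prod = len(prod_keys) - len(set(prod_keys))

    xtab_rows = []
    n = prods.shape[0]
    for j, k in itertools.combinations(range(len(schema)), 2):
        lj = schema.attributes[j].n_levels
        lk = schema.attributes[k].n_levels
        counts = np.zeros((lj, lk))
        np.add.at(counts, (prods[:, j], prods[:, k]), 1)
        expected = n / (lj * lk)
        xtab_rows.append(
            {
                "attribute_a": schema.attributes[j].name,
                "attribute_b": schema.attributes[k].name,
                "max_abs_deviation": float(np.abs(counts - expected).max()),
            }
        )

    return BalanceReport(
        level_counts=pd.DataFrame(count_rows),
        imbalance=pd.DataFrame(imb_rows),
        duplicate_scenarios=dup_scen,
        duplicate_products=dup_prod,
        crosstab_deviation=pd.DataFrame(xtab_rows),
    )


def assign_blocks(
    plan: DesignPlan,
    respondents: pd.DataFrame,
    seed: int = 0,
) -> pd.Series:
    """Assign each respondent one block, balanced within each group.

    ``respondents`` needs columns ``respondent_id`` and ``group``.  Within a
    group the (seed-shuffled) members are dealt round-robin over blocks, so
    per-group block counts differ by at most one; with equal group sizes
    divisible by the block count, every block sees the same number of each
    group.  Returns a Series mapping respondent_id -> block_id.
    """
    if len(respondents) == 0:
        raise ValueError("respondent list is empty")
    if not {"respondent_id", "group"} <= set(respondents.columns):
        raise ValueError("respondents must have 'respondent_id' and 'group' columns")
    rng = np.random.default_rng(seed)
    n_blocks = plan.n_blocks
    assignment: dict = {}
    for group in sorted(respondents["group"].unique()):
        ids = respondents.loc[respondents["group"] == group, "respondent_id"].tolist()
        order = rng.permutation(len(ids))
        start = int(rng.integers(n_blocks))
        for pos, idx in enumerate(order):
            assignment[ids[idx]] = (start + pos) % n_blocks
    out = pd.Series(assignment, name="block_id")
    out.index.name = "respondent_id"
    return out.loc[respondents["respondent_id"]]
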