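"""Synthetic respondents, choices, price-response and attitude data.

The generators mirror the assumptions of the hierarchical Bayesian choice
model: individual part-worth vectors are multivariate-normal around a
population mean, and paired choices follow a binary logit on the coded
utility difference.  The default population is calibrated so that the
range-method relative importances of the mean part-worth vector equal the
published aggregate importance profile (kidney risk 37.9 %, cost 23.4 %,
bone risk 18.0 %, efficacy 9.0 %, market time 6.8 %, level of use 4.9 %),
with 252 respondents split 111 Treated / 141 Treatment-naive.

Price-response and attitude generators use latent-variable models of the
survey instruments (5-point Likert scales); their defaults are qualitative
emulations, documented in the methods note, not reproductions of the
observed survey marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import DesignPlan
from .schema import AttributeSchema, build_default_schema, encode_product

__all__ = [
    "PopulationSpec",
    "RespondentProfiles",
    "PUBLISHED_IMPORTANCE_PCT",
    "published_importance_calibration",
    "simulate_respondents",
    "simulate_choices",
    "simulate_price_responses",
    "simulate_attitudes",
    "PriceModel",
    "DEFAULT_PRICE_GRID",
    "DEFAULT_ATTITUDE_STATEMENTS",
]

GROUP_TREATED = "Treated"
GROUP_NAIVE = "Treatment-naive"

#: Published aggregate relative importances (percent, total column).
PUBLISHED_IMPORTANCE_PCT: dict[str, float] = {
    "kidney_risk": 37.9,
    "cost": 23.4,
    "bone_risk": 18.0,
    "efficacy": 9.0,
    "years_on_market": 6.8,
    "patients_worldwide": 4.9,
}

#: +1 if utility increases along the schema's level order, -1 if it decreases.
_LEVEL_ORIENTATION: dict[str, int] = {
    "efficacy": +1,            # 71 % -> 92 %: higher efficacy preferred
    "bone_risk": -1,           # < 1 % -> 14 %: lower risk preferred
    "kidney_risk": -1,
    "patients_worldwide": +1,  # more patients treated preferred
    "years_on_market": +1,
    "cost": -1,                # $0 -> $150: cheaper preferred
}

#: Monthly out-of-pocket cost points shown in the price-sensitivity exercise.
DEFAULT_PRICE_GRID: tuple[int, ...] = (0, 50, 100, 150, 200, 250, 500)


@dataclass
class PopulationSpec:
    """Population distribution of part-worths: beta_i ~ MVN(mu, sigma)."""

    mu: np.ndarray
    sigma: np.ndarray
    group_mix: dict[str, float] = field(
        default_factory=lambda: {GROUP_TREATED: 111 / 252, GROUP_NAIVE: 141 / 252}
    )
    n_respondents: int = 252

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        p = self.mu.shape[0]
        if self.sigma.shape != (p, p):
            raise ValueError("sigma must be square and match mu's length")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma must be symmetric")
        eig = np.linalg.eigvalsh(self.sigma)
        if eig.min() < -1e-10 * max(1.0, eig.max()):
            raise ValueError("sigma must be positive semi-definite")
        total = sum(self.group_mix.values())
        if not np.isclose(total, 1.0) or any(v < 0 for v in self.group_mix.values()):
            raise ValueError("group_mix proportions must be non-negative and sum to 1")


@dataclass
class RespondentProfiles:
    """Simulated panel: ids, group/ethnicity labels, and part-worth vectors."""

    respondent_ids: list[str]
    groups: np.ndarray          # (N,) str
    ethnicities: np.ndarray     # (N,) str
    betas: np.ndarray           # (N, p)

    @property
    def n(self) -> int:
        return len(self.respondent_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "respondent_id": self.respondent_ids,
                "group": self.groups,
                "ethnicity": self.ethnicities,
            }
        )


def published_importance_calibration(
    schema: AttributeSchema | None = None,
    n_respondents: int = 252,
    sigma_scale: float = 0.25,
) -> PopulationSpec:
    """Population spec whose mean part-worths reproduce the published importances.

    Each attribute's level part-worths are symmetric about zero and equally
    spaced best-to-worst, with ranges proportional to the published relative
    importances and scaled to sum to 8.0 (so e.g. kidney risk gets range
    8 * 0.379 = 3.032).  Heterogeneity defaults to 0.25 * I (sd 0.5 per coded
    coefficient).  Only the default six-attribute schema is accepted.
    """
    default = build_default_schema()
    if schema is None:
        schema = default
    if schema.to_dict() != default.to_dict():
        raise ValueError("published_importance_calibration requires the default attribute schema")

    total_range = 8.0
    mu_parts = []
    for a in schema:
        rng_a = total_range * PUBLISHED_IMPORTANCE_PCT[a.name] / 100.0
        orient = _LEVEL_ORIENTATION[a.name]
        # part-worths along the level order; symmetric, sum to zero
        pw = orient * np.linspace(-rng_a / 2.0, rng_a / 2.0, a.n_levels)
        mu_parts.append(pw[:-1])  # effect-coded coordinates
    mu = np.concatenate(mu_parts)
    sigma = sigma_scale * np.eye(schema.n_coefficients)
    return PopulationSpec(mu=mu, sigma=sigma, n_respondents=n_respondents)


def _label_counts(n: int, mix: dict[str, float]) -> list[str]:
    """Deterministic label multiset with counts proportional to the mix."""
    labels = sorted(mix)
    counts = {k: int(np.floor(mix[k] * n)) for k in labels}
    # distribute remainder by largest fractional part, ties by label order
    rem = n - sum(counts.values())
    fracs = sorted(labels, key=lambda k: (-(mix[k] * n - counts[k]), k))
    for k in fracs[:rem]:
        counts[k] += 1
    out: list[str] = []
    for k in labels:
        out.extend([k] * counts[k])
    return out


_ETHNICITY_MIX = {"Chinese": 90 / 252, "Vietnamese": 85 / 252, "Korean": 77 / 252}


def simulate_respondents(spec: PopulationSpec, seed: int = 0) -> RespondentProfiles:
    """Draw a panel of respondents with beta_i ~ MVN(mu, sigma).

    Group and ethnicity labels are dealt in fixed proportions and shuffled by
    the seed; with ``sigma = 0`` every beta equals ``mu`` exactly.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_respondents
    p = spec.mu.shape[0]
    if np.allclose(spec.sigma, 0.0):
        betas = np.tile(spec.mu, (n, 1))
    else:
        betas = rng.multivariate_normal(spec.mu, spec.sigma, size=n, method="eigh")
    groups = np.array(_label_counts(n, spec.group_mix))
    rng.shuffle(groups)
    eth = np.array(_label_counts(n, _ETHNICITY_MIX))
    rng.shuffle(eth)
    ids = [f"R{i + 1:04d}" for i in range(n)]
    return RespondentProfiles(ids, groups, eth, betas.reshape(n, p))


def simulate_choices(
    profiles: RespondentProfiles,
    plan: DesignPlan,
    assignment: pd.Series,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate paired choices by the logit rule for each respondent's block.

    For every scenario in the respondent's assigned block, product A is
    chosen with probability logistic((x_A - x_B)' beta_i).  Returns a tidy
    frame with columns respondent_id, group, block_id, scenario_id, choice.
    """
    missing = [r for r in profiles.respondent_ids if r not in assignment.index]
    if missing:
        raise ValueError(f"respondents lack a block assignment: {missing[:5]}")
    rng = np.random.default_rng(seed)
    schema = plan.schema

    # Precompute per-block difference matrices (scenarios x p).
    block_diffs = []
    block_ids = []
    for block in plan.blocks:
        d = np.array(
            [
                encode_product(schema, s.product_a) - encode_product(schema, s.product_b)
                for s in block
            ]
        )
        block_diffs.append(d)
        block_ids.append([s.scenario_id for s in block])

    rows = []
    idx_of = {r: i for i, r in enumerate(profiles.respondent_ids)}
    for b in range(plan.n_blocks):
        members = [r for r in profiles.respondent_ids if assignment[r] == b]
        if not members:
            continue
        betas = profiles.betas[[idx_of[r] for r in members]]
        probs = expit(betas @ block_diffs[b].T)          # (n_members, n_scen)
        draws = rng.random(probs.shape)
        chose_a = draws < probs
        for i, r in enumerate(members):
            g = profiles.groups[idx_of[r]]
            for j, sid in enumerate(block_ids[b]):
                rows.append(
                    {
                        "respondent_id": r,
                        "group": g,
                        "block_id": b,
                        "scenario_id": sid,
                        "choice": "A" if chose_a[i, j] else "B",
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class PriceModel:
    """Latent-threshold model for 5-point willingness scores over price.

    score = clip(round(a_i + b_i * price + noise), 1, 5), with respondent
    intercepts a_i and (negative) slopes b_i drawn around group means.  The
    Treated group's steeper default slope reflects its greater observed
    price sensitivity.
    """

    a_mean: dict[str, float] = field(
        default_factory=lambda: {GROUP_TREATED: 5.0, GROUP_NAIVE: 5.2}
    )
    a_sd: float = 0.6
    b_mean: dict[str, float] = field(
        default_factory=lambda: {GROUP_TREATED: -0.009, GROUP_NAIVE: -0.0065}
    )
    b_sd: float = 0.002
    noise_sd: float = 0.5


def simulate_price_responses(
    profiles: RespondentProfiles,
    price_grid: tuple[int, ...] = DEFAULT_PRICE_GRID,
    seed: int = 0,
    model: PriceModel | None = None,
) -> pd.DataFrame:
    """Every respondent scores every price point on the 1-5 likelihood scale.

    Columns: respondent_id, group, price_usd, score.  Mean score decreases
    in price under the default model (b_i <= 0 is enforced by truncation).
    """
    if len(price_grid) == 0:
        raise ValueError("price grid is empty")
    model = model or PriceModel()
    rng = np.random.default_rng(seed)
    n = profiles.n
    prices = np.asarray(price_grid, dtype=float)

    a_mu = np.array([model.a_mean[g] for g in profiles.groups])
    b_mu = np.array([model.b_mean[g] for g in profiles.groups])
    a_i = a_mu + model.a_sd * rng.standard_normal(n)
    b_i = np.minimum(b_mu + model.b_sd * rng.standard_normal(n), 0.0)
    latent = a_i[:, None] + b_i[:, None] * prices[None, :]
    latent = latent + model.noise_sd * rng.standard_normal((n, len(prices)))
    scores = np.clip(np.rint(latent), 1, 5).astype(int)

    return pd.DataFrame(
        {
            "respondent_id": np.repeat(profiles.respondent_ids, len(prices)),
            "group": np.repeat(profiles.groups, len(prices)),
            "price_usd": np.tile(prices.astype(int), n),
            "score": scores.ravel(),
        }
    )


#: Default attitude battery: statement id -> (baseline latent mean,
#: {group: shift}).  Positive shift raises agreement for that group.
DEFAULT_ATTITUDE_STATEMENTS: dict[str, tuple[float, dict[str, float]]] = {
    "untreated_chb_serious_liver_damage": (4.4, {}),
    "effective_medications_exist": (3.9, {}),
    "reluctant_long_term_side_effects": (2.9, {GROUP_NAIVE: 0.35}),
    "lifestyle_diet_sufficient": (2.8, {GROUP_NAIVE: 0.35}),
    "doctor_decides_treatment": (3.5, {}),
}


def simulate_attitudes(
    profiles: RespondentProfiles,
    statements: dict[str, tuple[float, dict[str, float]]] | None = None,
    group_effects: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Simulate 1-5 agreement scores for a battery of attitude statements.

    Each score is a discretized latent normal whose mean is the statement
    baseline plus the respondent group's shift.  ``group_effects`` overrides
    the per-statement shifts (statement id -> {group: shift}).  Columns:
    respondent_id, group, statement_id, score.
    """
    statements = statements if statements is not None else DEFAULT_ATTITUDE_STATEMENTS
    if not statements:
        raise ValueError("statement battery is empty")
    rng = np.random.default_rng(seed)
    n = profiles.n
    frames = []
    for sid, (base, shifts) in statements.items():
        shifts = (group_effects or {}).get(sid, shifts)
        mean = base + np.array([shifts.get(g, 0.0) for g in profiles.groups])
        latent = mean + noise_sd * rng.standard_normal(n)
        scores = np.clip(np.rint(latent), 1, 5).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "respondent_id": profiles.respondent_ids,
                    "group": profiles.groups,
                    "statement_id": sid,
                    "score": scores,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_dataset(
    out_dir: str | Path,
    choices: pd.DataFrame,
    prices: pd.DataFrame,
    attitudes: pd.DataFrame,
) -> dict[str, Path]:
    """Write the three survey tables as CSV; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "choices": out / "choices.csv",
        "prices": out / "prices.csv",
        "attitudes": out / "attitudes.csv",
    }
    choices.to_csv(paths["choices"], index=False)
    prices.to_csv(paths["prices"], index=False)
    attitudes.to_csv(paths["attitudes"], index=False)
    return paths
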