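"""End-to-end replication pipeline and input validation.

``replicate`` chains every stage — design construction, synthetic panel,
choice/price/attitude simulation, hierarchical Bayesian fit, and all
post-estimation summaries — into one reproducible run driven by a single
master seed.  Stage seeds are derived as stable hashes of (master seed,
stage name), so any stage can be re-run in isolation and still agree with
the full pipeline.  All artifacts are plain text (CSV/JSON/markdown) and a
re-run with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import postestimation, survey
from .design import DesignPlan, assign_blocks, balance_report, generate_design
from .diagnostics import diagnostics
from .hb import ChoiceDataset, HBConfig, posterior_point_estimates, run_mcmc
from .schema import AttributeSchema, Product, build_default_schema, load_schema
from .simulate import (
    simulate_attitudes,
    simulate_choices,
    simulate_price_responses,
    simulate_respondents,
    published_importance_calibration,
    write_dataset,
    GROUP_NAIVE,
    GROUP_TREATED,
)

__all__ = ["RunConfig", "stage_seed", "replicate", "validate_inputs"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    return zlib.crc32(f"{stage}:{master_seed}".encode()) % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full replication run."""

    schema_path: str | None = None       # None -> packaged default schema
    n_blocks: int = 8
    scenarios_per_block: int = 8
    calibration: str = "published"
    n_respondents: int = 252
    sigma_scale: float = 0.25
    n_chains: int = 2
    n_iterations: int = 20_000
    n_burnin: int = 10_000
    thin: int = 10
    master_seed: int = 0
    out_dir: str = "hbchoice_run"
    # base-case products for sensitivity, as {attribute: level label};
    # None -> middle levels for A, B shifted on efficacy and cost.
    base_a: dict[str, str] | None = None
    base_b: dict[str, str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)


def default_base_products(schema: AttributeSchema) -> tuple[Product, Product]:
    """Package default base case: A at every middle level ($50 cost); B the
    same but with top efficacy (92 %) and $100 cost, so the pair differs on
    two attributes and no single flex can collapse them into one product."""
    mid_a = Product(tuple(a.n_levels // 2 for a in schema))
    levels_b = list(mid_a.levels)
    names = schema.names
    levels_b[names.index("efficacy")] = 2
    levels_b[names.index("cost")] = 2
    return mid_a, Product(tuple(levels_b))


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def replicate(config: RunConfig) -> dict:
    """Run the full pipeline and write a report bundle under ``config.out_dir``.

    Returns the report dictionary (also written as ``report.json`` /
    ``report.md``).  Stages: design -> panel -> block assignment -> choices,
    price responses, attitudes -> HB fit -> importance (total and by group),
    shares, sensitivity, cost curve/beta, attitude comparisons.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    stage = "init"
    try:
        stage = "design"
        schema = (
            load_schema(config.schema_path) if config.schema_path else build_default_schema()
        )
        plan = generate_design(
            schema,
            config.n_blocks,
            config.scenarios_per_block,
            seed=stage_seed(config.master_seed, "design"),
        )
        plan.to_json(out / "design.json")
        plan.to_frame().to_csv(out / "design.csv", index=False)
        manifest += ["design.json", "design.csv"]
        bal = balance_report(plan)

        stage = "simulate"
        if config.calibration != "published":
            raise ValueError(f"unknown calibration {config.calibration!r}")
        pop = published_importance_calibration(
            schema, n_respondents=config.n_respondents, sigma_scale=config.sigma_scale
        )
        profiles = simulate_respondents(pop, seed=stage_seed(config.master_seed, "panel"))
        assignment = assign_blocks(
            plan, profiles.to_frame(), seed=stage_seed(config.master_seed, "assign")
        )
        choices = simulate_choices(
            profiles, plan, assignment, seed=stage_seed(config.master_seed, "choices")
        )
        prices = simulate_price_responses(
            profiles, seed=stage_seed(config.master_seed, "prices")
        )
        attitudes = simulate_attitudes(
            profiles, seed=stage_seed(config.master_seed, "attitudes")
        )
        write_dataset(out, choices, prices, attitudes)
        manifest += ["choices.csv", "prices.csv", "attitudes.csv"]

        stage = "fit"
        dataset = ChoiceDataset.from_frame(choices, plan, schema)
        hb_config = HBConfig(
            n_chains=config.n_chains,
            n_iterations=config.n_iterations,
            n_burnin=config.n_burnin,
            thin=config.thin,
            seed=stage_seed(config.master_seed, "fit"),
        )
        draws = run_mcmc(dataset, hb_config)
        est = posterior_point_estimates(draws)
        est.betas_frame().to_csv(out / "betas.csv", index=False)
        manifest.append("betas.csv")
        diag = diagnostics(draws)
        diag.to_csv(out / "diagnostics.csv", index=False)
        manifest.append("diagnostics.csv")

        stage = "postestimation"
        groups = dict(zip(profiles.respondent_ids, profiles.groups))
        imp_total = postestimation.relative_importance(
            est.beta, schema, respondent_ids=est.respondent_ids
        )
        imp_table = {"Total": imp_total.aggregate.to_dict()}
        for gname in (GROUP_TREATED, GROUP_NAIVE):
            mask = np.array([groups[r] == gname for r in est.respondent_ids])
            if mask.any():
                sub = postestimation.relative_importance(
                    est.beta[mask],
                    schema,
                    respondent_ids=[r for r, m in zip(est.respondent_ids, mask) if m],
                )
                imp_table[gname] = sub.aggregate.to_dict()
        imp_total.per_respondent.to_csv(out / "importance.csv", index=False)
        manifest.append("importance.csv")

        base_a, base_b = default_base_products(schema)
        if config.base_a:
            base_a = Product.from_labels(schema, config.base_a)
        if config.base_b:
            base_b = Product.from_labels(schema, config.base_b)
        shares = postestimation.preference_shares(est.beta, [base_a, base_b], schema)
        sens = postestimation.sensitivity_analysis(est.beta, base_a, base_b, schema)
        sens_table = postestimation.sensitivity_frame(sens)
        sens_table.to_csv(out / "sensitivity.csv", index=False)
        manifest.append("sensitivity.csv")

        stage = "survey_stats"
        curve = survey.willingness_curve(prices)
        curve.to_csv(out / "cost_curve.csv", index=False)
        manifest.append("cost_curve.csv")
        betas_cost = {
            g: asdict(survey.cost_beta(prices, group=None if g == "All" else g))
            for g in ("All", GROUP_TREATED, GROUP_NAIVE)
        }
        maxp = survey.max_price_summary(survey.implied_max_prices(prices))
        att = survey.compare_attitudes(attitudes, GROUP_TREATED, GROUP_NAIVE)
        att.to_csv(out / "attitudes_summary.csv", index=False)
        manifest.append("attitudes_summary.csv")

        stage = "report"
        report = {
            "master_seed": config.master_seed,
            "n_respondents": config.n_respondents,
            "design": {
                "n_blocks": plan.n_blocks,
                "scenarios_per_block": config.scenarios_per_block,
                "n_scenarios": len(plan.scenarios),
                "duplicate_scenarios": bal.duplicate_scenarios,
                "duplicate_products": bal.duplicate_products,
                "max_level_imbalance": bal.max_imbalance,
            },
            "fit": {
                "n_chains": hb_config.n_chains,
                "n_iterations": hb_config.n_iterations,
                "n_burnin": hb_config.n_burnin,
                "thin": hb_config.thin,
                "mean_accept_rate": float(draws.accept_rate.mean()),
                "max_rhat_mu": float(
                    diag.loc[diag["parameter"].str.startswith("mu["), "rhat"].max()
                ),
                "n_flagged_parameters": int(diag["flagged"].sum()),
            },
            "importance_pct": imp_table,
            "shares_pct": {
                "base_case_a": base_a.labels(schema),
                "base_case_b": base_b.labels(schema),
                "share_a": float(shares.aggregate.iloc[0]),
                "share_b": float(shares.aggregate.iloc[1]),
            },
            "cost": {
                "beta": betas_cost,
                "max_price_mean": maxp.mean,
                "max_price_median": maxp.median,
                "top2_pct_at_100": float(
                    curve.query("group == 'All' and price_usd == 100")[
                        "pct_willing"
                    ].iloc[0]
                ),
            },
            "attitudes": att.to_dict(orient="records"),
            "manifest": sorted(manifest + ["report.json", "report.md"]),
        }
        report = _round_floats(report)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        (out / "report.md").write_text(_render_markdown(report, schema))
        return report
    except Exception as exc:
        (out / "manifest_partial.json").write_text(
            json.dumps({"failed_stage": stage, "artifacts": sorted(manifest)}, indent=2)
        )
        raise RuntimeError(f"replicate failed during stage {stage!r}: {exc}") from exc


def _render_markdown(report: dict, schema: AttributeSchema) -> str:
    lines = ["# Replication report", ""]
    d = report["design"]
    lines += [
        f"- Design: {d['n_scenarios']} scenarios in {d['n_blocks']} blocks "
        f"({d['duplicate_scenarios']} duplicate scenarios, "
        f"max level imbalance {d['max_level_imbalance']})",
        f"- Fit: {report['fit']['n_chains']} chains x "
        f"{report['fit']['n_iterations']} iterations, "
        f"max mu R-hat {report['fit']['max_rhat_mu']:.3f}",
        "",
        "## Relative importance (%)",
        "",
    ]
    cols = list(report["importance_pct"].keys())
    lines.append("| Attribute | " + " | ".join(cols) + " |")
    lines.append("|---" * (len(cols) + 1) + "|")
    for name in schema.names:
        vals = " | ".join(f"{report['importance_pct'][c][name]:.1f}" for c in cols)
        lines.append(f"| {name} | {vals} |")
    lines += [
        "",
        "## Shares and cost",
        "",
        f"- Base-case shares: A {report['shares_pct']['share_a']:.1f} % vs "
        f"B {report['shares_pct']['share_b']:.1f} %",
        f"- Cost beta (All): "
        f"{report['cost']['beta']['All']['slope_per_usd']:.5f} per $",
        f"- Top-2-box willingness at $100: "
        f"{report['cost']['top2_pct_at_100']:.1f} %",
        f"- Implied max price: mean ${report['cost']['max_price_mean']:.0f}, "
        f"median ${report['cost']['max_price_median']:.0f}",
        "",
    ]
    return "\n".join(lines)


def validate_inputs(
    data_dir: str | Path,
    schema: AttributeSchema | None = None,
    plan: DesignPlan | None = None,
) -> list[str]:
    """Schema/referential checks on a data directory; returns violations.

    Violations are data, not exceptions: the list is empty for a well-formed
    bundle.  Checks CSV column sets, score ranges, level-label membership in
    the design plan, and choice records' referential integrity against the
    plan's scenarios and blocks.
    """
    data_dir = Path(data_dir)
    violations: list[str] = []
    if plan is None and (data_dir / "design.json").exists():
        plan = DesignPlan.from_json(data_dir / "design.json")
    if schema is None:
        schema = plan.schema if plan is not None else build_default_schema()

    expected_cols = {
        "choices.csv": {"respondent_id", "block_id", "scenario_id", "choice"},
        "prices.csv": {"respondent_id", "group", "price_usd", "score"},
        "attitudes.csv": {"respondent_id", "group", "statement_id", "score"},
    }
    frames: dict[str, pd.DataFrame] = {}
    for fname, cols in expected_cols.items():
        path = data_dir / fname
        if not path.exists():
            violations.append(f"{fname}: missing file")
            continue
        df = pd.read_csv(path)
        frames[fname] = df
        missing = cols - set(df.columns)
        if missing:
            violations.append(f"{fname}: missing columns {sorted(missing)}")

    if "choices.csv" in frames and plan is not None:
        df = frames["choices.csv"]
        known = {s.scenario_id for s in plan.scenarios}
        for sid in pd.unique(df["scenario_id"]):
            if sid not in known:
                violations.append(f"choices.csv: unknown scenario {sid!r}")
        if "block_id" in df.columns:
            for sid, bid in df[["scenario_id", "block_id"]].drop_duplicates().itertuples(
                index=False
            ):
                if sid in known and plan.block_of(sid) != bid:
                    violations.append(
                        f"choices.csv: scenario {sid!r} is not in block {bid}"
                    )
        bad_choice = set(pd.unique(df["choice"])) - {"A", "B"}
        if bad_choice:
            violations.append(f"choices.csv: invalid choice values {sorted(bad_choice)}")

    for fname in ("prices.csv", "attitudes.csv"):
        if fname in frames and "score" in frames[fname].columns:
            s = frames[fname]["score"]
            if ((s < 1) | (s > 5)).any():
                violations.append(f"{fname}: scores outside 1..5")

    if (data_dir / "design.csv").exists():
        df = pd.read_csv(data_dir / "design.csv")
        for a in schema:
            if a.name in df.columns:
                bad = set(df[a.name].astype(str)) - set(a.levels)
                for lbl in sorted(bad):
                    violations.append(
                        f"design.csv: unknown level {lbl!r} for attribute {a.name!r}"
                    )
    return violations
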