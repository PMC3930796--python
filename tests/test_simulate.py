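"""Synthetic-data generators: calibration, determinism, distributional checks."""

import numpy as np
import pandas as pd
import pytest

from hbchoice.postestimation import attribute_ranges, relative_importance
from hbchoice.simulate import (
    DEFAULT_PRICE_GRID,
    GROUP_NAIVE,
    GROUP_TREATED,
    PopulationSpec,
    PriceModel,
    simulate_attitudes,
    simulate_choices,
    simulate_price_responses,
    simulate_respondents,
    published_importance_calibration,
)


class TestCalibration:
    def test_ranges_match_published_importance_profile(self, schema, calibration):
        ranges = attribute_ranges(calibration.mu, schema)
        expected = {
            "kidney_risk": 3.032,
            "cost": 1.872,
            "bone_risk": 1.440,
            "efficacy": 0.720,
            "years_on_market": 0.544,
            "patients_worldwide": 0.392,
        }
        for name, r in zip(schema.names, ranges):
            assert r == pytest.approx(expected[name], abs=1e-12)
        assert ranges.sum() == pytest.approx(8.0, abs=1e-12)

    def test_importances_of_mu_equal_published_column(self, schema, calibration):
        imp = relative_importance(calibration.mu[None, :], schema).aggregate
        expected = {
            "kidney_risk": 37.9,
            "cost": 23.4,
            "bone_risk": 18.0,
            "efficacy": 9.0,
            "years_on_market": 6.8,
            "patients_worldwide": 4.9,
        }
        for name, want in expected.items():
            assert imp[name] == pytest.approx(want, abs=1e-9)

    def test_defaults_match_study_composition(self, calibration):
        assert calibration.n_respondents == 252
        np.testing.assert_allclose(
            np.diag(calibration.sigma), 0.25
        )

    def test_rejects_non_default_schema(self, schema):
        from hbchoice.schema import AttributeSchema, AttributeSpec

        other = AttributeSchema(
            (AttributeSpec("a", "", ("1", "2", "3")),) + schema.attributes[1:]
        )
        with pytest.raises(ValueError, match="default"):
            published_importance_calibration(other)


class TestSimulateRespondents:
    def test_zero_sigma_gives_mu_exactly(self, schema, calibration):
        spec = PopulationSpec(
            mu=calibration.mu, sigma=np.zeros((13, 13)), n_respondents=20
        )
        prof = simulate_respondents(spec, seed=0)
        assert np.array_equal(prof.betas, np.tile(calibration.mu, (20, 1)))

    def test_sample_mean_near_mu_at_large_n(self, calibration):
        spec = PopulationSpec(mu=calibration.mu, sigma=calibration.sigma,
                              n_respondents=10_000)
        prof = simulate_respondents(spec, seed=1)
        # CLT bound: 3 * 0.5 / sqrt(10000)
        assert np.abs(prof.betas.mean(axis=0) - calibration.mu).max() < 3 * 0.5 / 100

    def test_group_mix_counts(self, calibration):
        prof = simulate_respondents(calibration, seed=2)
        counts = pd.Series(prof.groups).value_counts()
        assert counts[GROUP_TREATED] == 111
        assert counts[GROUP_NAIVE] == 141

    def test_seed_determinism(self, calibration):
        a = simulate_respondents(calibration, seed=3)
        b = simulate_respondents(calibration, seed=3)
        assert np.array_equal(a.betas, b.betas)
        assert np.array_equal(a.groups, b.groups)

    def test_rejects_non_psd_sigma(self, calibration):
        bad = -np.eye(13)
        with pytest.raises(ValueError, match="positive semi-definite"):
            PopulationSpec(mu=calibration.mu, sigma=bad)


class TestSimulateChoices:
    def test_record_count_is_respondents_times_scenarios(self, panel):
        _, _, choices = panel
        assert len(choices) == 252 * 8

    def test_choices_reference_assigned_block(self, plan, panel):
        _, assignment, choices = panel
        for rid, block_id in choices[["respondent_id", "block_id"]].drop_duplicates().itertuples(index=False):
            assert assignment[rid] == block_id
        for sid, bid in choices[["scenario_id", "block_id"]].drop_duplicates().itertuples(index=False):
            assert plan.block_of(sid) == bid

    def test_indifferent_respondents_split_evenly(self, schema, plan, calibration):
        spec = PopulationSpec(mu=np.zeros(13), sigma=np.zeros((13, 13)),
                              n_respondents=500)
        prof = simulate_respondents(spec, seed=4)
        from hbchoice import assign_blocks

        assignment = assign_blocks(plan, prof.to_frame(), seed=4)
        choices = simulate_choices(prof, plan, assignment, seed=4)
        frac_a = (choices["choice"] == "A").mean()
        # 4000 Bernoulli(0.5) draws: 4 sigma ~ 0.032
        assert abs(frac_a - 0.5) < 0.032

    def test_dominant_utility_always_chooses_a(self, schema, plan, calibration):
        # beta large and aligned with the design: strong preferences make
        # choices near-deterministic given the sign of the utility diff
        spec = PopulationSpec(mu=10 * calibration.mu, sigma=np.zeros((13, 13)),
                              n_respondents=50)
        prof = simulate_respondents(spec, seed=5)
        from hbchoice import assign_blocks
        from hbchoice.schema import encode_product
        from scipy.special import expit

        assignment = assign_blocks(plan, prof.to_frame(), seed=5)
        choices = simulate_choices(prof, plan, assignment, seed=5)
        # compare against per-scenario sign of the utility difference
        mism = 0
        for rid, sid, ch in choices[["respondent_id", "scenario_id", "choice"]].itertuples(index=False):
            s = plan.scenario(sid)
            diff = encode_product(schema, s.product_a) - encode_product(schema, s.product_b)
            u = diff @ prof.betas[prof.respondent_ids.index(rid)]
            if abs(u) > 10:  # logistic(10) > 0.99995
                mism += (ch == "A") != (u > 0)
        assert mism == 0

    def test_missing_assignment_rejected(self, plan, calibration):
        prof = simulate_respondents(calibration, seed=6)
        partial = pd.Series({prof.respondent_ids[0]: 0})
        with pytest.raises(ValueError, match="assignment"):
            simulate_choices(prof, plan, partial, seed=0)


class TestSimulatePriceResponses:
    def test_seven_prices_per_respondent(self, panel):
        profiles, _, _ = panel
        prices = simulate_price_responses(profiles, seed=7)
        assert len(prices) == profiles.n * 7
        assert prices.groupby("respondent_id")["price_usd"].nunique().eq(7).all()
        assert sorted(prices["price_usd"].unique()) == list(DEFAULT_PRICE_GRID)

    def test_degenerate_model_pins_scores_at_five(self, panel):
        profiles, _, _ = panel
        model = PriceModel(
            a_mean={GROUP_TREATED: 5.0, GROUP_NAIVE: 5.0},
            a_sd=0.0,
            b_mean={GROUP_TREATED: 0.0, GROUP_NAIVE: 0.0},
            b_sd=0.0,
            noise_sd=0.0,
        )
        prices = simulate_price_responses(profiles, seed=8, model=model)
        assert (prices["score"] == 5).all()

    def test_mean_score_decreases_with_price(self, panel):
        profiles, _, _ = panel
        prices = simulate_price_responses(profiles, seed=9)
        means = prices.groupby("price_usd")["score"].mean()
        assert means.loc[0] >= means.loc[500]
        assert means.loc[0] > 4.0 and means.loc[500] < 3.5

    def test_scores_within_scale(self, panel):
        profiles, _, _ = panel
        prices = simulate_price_responses(profiles, seed=10)
        assert prices["score"].between(1, 5).all()


class TestSimulateAttitudes:
    def test_record_count(self, panel):
        profiles, _, _ = panel
        att = simulate_attitudes(profiles, seed=11)
        assert len(att) == profiles.n * 5

    def test_null_group_effect_gives_similar_means(self, calibration):
        spec = PopulationSpec(mu=calibration.mu, sigma=calibration.sigma,
                              n_respondents=20_000)
        prof = simulate_respondents(spec, seed=12)
        att = simulate_attitudes(
            prof, statements={"s1": (3.0, {})}, seed=12
        )
        means = att.groupby("group")["score"].mean()
        assert abs(means.iloc[0] - means.iloc[1]) < 0.1

    def test_degenerate_statement_scores_three(self, panel):
        profiles, _, _ = panel
        att = simulate_attitudes(
            profiles, statements={"s1": (3.0, {})}, seed=13, noise_sd=0.0
        )
        assert (att["score"] == 3).all()

    def test_group_effect_shifts_mean(self, panel):
        profiles, _, _ = panel
        att = simulate_attitudes(
            profiles,
            statements={"s1": (3.0, {})},
            group_effects={"s1": {GROUP_NAIVE: 1.0}},
            seed=14,
        )
        means = att.groupby("group")["score"].mean()
        assert means[GROUP_NAIVE] > means[GROUP_TREATED] + 0.5
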