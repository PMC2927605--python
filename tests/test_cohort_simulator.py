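"""Generator: marginal calibration, absorbing states, determinism."""

import numpy as np
import pandas as pd
import pytest

from cohortdrift.cohort_simulator import (
    ATTRITION_OUTCOMES,
    STATUSES,
    AttritionModelSpec,
    CohortTable,
    RiskFactorSpec,
    assign_final_status,
    assign_transition_surveys,
    assign_weights,
    calibrate_intercepts,
    enumerate_joint,
    expand_to_surveys,
    generate_baseline,
    impose_missingness,
    interval_rates_from_marginals,
)

TARGETS = {"respondent": 0.447, "dead": 0.284, "frail": 0.051, "withdrawn": 0.114, "lost": 0.104}


class TestGenerateBaseline:
    def test_marginals_match_configuration(self, spec_by_name):
        smoking = spec_by_name["smoking"]
        cohort = generate_baseline(100_000, [smoking], seed=42)
        share = (cohort.data["smoking"] == "Never smoker").mean()
        assert share == pytest.approx(0.629, abs=0.01)

    def test_single_record_and_determinism(self, specs):
        one = generate_baseline(1, specs, seed=5)
        assert len(one) == 1
        assert not one.data[[s.name for s in specs]].isna().any().any()
        a = generate_baseline(500, specs, seed=11).data
        b = generate_baseline(500, specs, seed=11).data
        pd.testing.assert_frame_equal(a, b)
        c = generate_baseline(500, specs, seed=12).data
        assert not a.equals(c)

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            RiskFactorSpec("x", ("a", "b"), (0.5, 0.6), reference="a")
        with pytest.raises(ValueError, match="n must be"):
            generate_baseline(0, [], seed=1)


class TestCalibrateIntercepts:
    def test_null_coefficients_have_closed_form(self, specs):
        """With no covariate effects the calibrated intercepts are the target
        log-ratios versus the respondent share."""
        grid, probs = enumerate_joint(specs)
        model = calibrate_intercepts(AttritionModelSpec.null(), grid, TARGETS, weights=probs)
        for outcome in ATTRITION_OUTCOMES:
            expected = np.log(TARGETS[outcome] / TARGETS["respondent"])
            assert model.intercepts[outcome] == pytest.approx(expected, abs=1e-5)

    def test_degenerate_target_rejected(self, specs):
        grid, probs = enumerate_joint(specs)
        corner = {"respondent": 1.0, "dead": 0.0, "frail": 0.0, "withdrawn": 0.0, "lost": 0.0}
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_intercepts(AttritionModelSpec.null(), grid, corner, weights=probs)

    def test_fixture_model_hits_targets_in_expectation(self, fixture_model, specs):
        """Exact expectation over the enumerated joint baseline distribution."""
        grid, probs = enumerate_joint(specs)
        p = fixture_model.outcome_probabilities(grid).to_numpy()
        achieved = p.T @ probs
        for k, status in enumerate(STATUSES):
            assert achieved[k] == pytest.approx(TARGETS[status], abs=1e-3)

    def test_unknown_category_coefficient_rejected(self, specs):
        bad = AttritionModelSpec(
            intercepts={o: 0.0 for o in ATTRITION_OUTCOMES},
            coefficients={("dead", "smoking", "Cigar aficionado"): 0.5},
        )
        with pytest.raises(ValueError, match="unknown category"):
            bad.validate_against(specs)


class TestAssignFinalStatus:
    def test_null_model_reproduces_target_marginals(self, specs, null_model):
        cohort = generate_baseline(100_000, specs, seed=21)
        cohort = assign_final_status(cohort, null_model, seed=21)
        shares = cohort.data["status_s5"].value_counts(normalize=True)
        for status, target in TARGETS.items():
            se = np.sqrt(target * (1 - target) / 100_000)
            assert shares[status] == pytest.approx(target, abs=4 * se)

    def test_all_respondent_limit(self, specs):
        # intercepts pushed to -inf proxy: everyone responds
        model = AttritionModelSpec(
            intercepts={o: -50.0 for o in ATTRITION_OUTCOMES}, coefficients={}
        )
        cohort = assign_final_status(generate_baseline(200, specs, seed=1), model, seed=1)
        assert (cohort.data["status_s5"] == "respondent").all()

    def test_missing_covariates_rejected(self, specs, fixture_model):
        cohort = generate_baseline(200, specs, seed=2)
        cohort = impose_missingness(cohort, {"smoking": 0.5}, seed=2)
        with pytest.raises(ValueError, match="missing values"):
            assign_final_status(cohort, fixture_model, seed=2)


class TestExpandToSurveys:
    def test_interval_rates_rows_sum_to_one(self, table1):
        rates = interval_rates_from_marginals(table1)
        np.testing.assert_allclose(rates.sum(axis=1), 1.0, atol=1e-12)
        assert (rates.to_numpy() >= 0).all()

    def test_zero_attrition_keeps_everyone(self, specs):
        rates = pd.DataFrame(
            {s: [1.0 if s == "respondent" else 0.0] * 4 for s in STATUSES},
            index=pd.Index(range(2, 6), name="survey"),
        )
        cohort = expand_to_surveys(generate_baseline(300, specs, seed=3), rates, seed=3)
        for col in cohort.status_columns:
            assert (cohort.data[col] == "respondent").all()

    def test_absorbing_states_and_monotone_cumulative_shares(self, specs, table1):
        rates = interval_rates_from_marginals(table1)
        cohort = expand_to_surveys(generate_baseline(20_000, specs, seed=4), rates, seed=4)
        cohort.validate()  # absorbing-state rules per individual
        for st in ("dead", "frail", "withdrawn", "lost"):
            shares = [(cohort.data[c] == st).mean() for c in cohort.status_columns]
            assert (np.diff(shares) >= 0).all()

    def test_bad_transition_rows_rejected(self, specs):
        rates = pd.DataFrame(
            {s: [0.5 if s == "respondent" else 0.0] * 4 for s in STATUSES},
            index=pd.Index(range(2, 6), name="survey"),
        )
        with pytest.raises(ValueError, match="sum to 1"):
            expand_to_surveys(generate_baseline(10, specs, seed=1), rates, seed=1)


class TestAssignTransitionSurveys:
    def test_backfill_preserves_final_status_and_absorption(self, specs, fixture_model, table1):
        cohort = generate_baseline(5_000, specs, seed=6)
        cohort = assign_final_status(cohort, fixture_model, seed=6)
        final = cohort.data["status_s5"].copy()
        filled = assign_transition_surveys(cohort, table1, seed=6)
        filled.validate()
        pd.testing.assert_series_equal(filled.data["status_s5"], final)

    def test_requires_final_status(self, specs, table1):
        with pytest.raises(ValueError, match="status_s5"):
            assign_transition_surveys(generate_baseline(10, specs, seed=1), table1, seed=1)


class TestImposeMissingness:
    def test_rates_and_complete_case_count(self, specs):
        rates = {"bmi_group": 0.110, "smoking": 0.074, "country_of_birth": 0.070}
        cohort = generate_baseline(100_000, specs, seed=8)
        blanked = impose_missingness(cohort, rates, seed=8)
        assert blanked.data["bmi_group"].isna().mean() == pytest.approx(0.110, abs=0.005)
        # independence across factors: complete-row count near n * prod(1-r)
        complete = (~blanked.data[list(rates)].isna().any(axis=1)).sum()
        expected = 100_000 * np.prod([1 - r for r in rates.values()])
        assert complete == pytest.approx(expected, rel=0.01)
        # statuses and untouched factors unaffected
        assert blanked.data["alcohol"].notna().all()

    def test_zero_rate_is_identity(self, specs):
        cohort = generate_baseline(500, specs, seed=9)
        same = impose_missingness(cohort, {"smoking": 0.0}, seed=9)
        pd.testing.assert_frame_equal(cohort.data, same.data)

    def test_invalid_rate_rejected(self, specs):
        cohort = generate_baseline(10, specs, seed=1)
        with pytest.raises(ValueError, match="rate"):
            impose_missingness(cohort, {"smoking": 1.0}, seed=1)
        with pytest.raises(ValueError, match="unknown factor"):
            impose_missingness(cohort, {"caffeine": 0.1}, seed=1)


class TestAssignWeights:
    SHARES = {"city": 0.70, "rural": 0.25, "remote": 0.05}

    def test_equal_fractions_give_unit_weights(self, specs):
        cohort = generate_baseline(1_000, specs, seed=10)
        w = assign_weights(cohort, {s: 1.0 for s in self.SHARES}, self.SHARES, seed=10)
        np.testing.assert_allclose(w.data["weight"], 1.0)

    def test_inverse_proportionality(self, specs):
        cohort = generate_baseline(5_000, specs, seed=11)
        w = assign_weights(cohort, {"city": 1.0, "rural": 2.0, "remote": 2.0}, self.SHARES, seed=11)
        city = w.data.loc[w.data["area_stratum"] == "city", "weight"].iloc[0]
        rural = w.data.loc[w.data["area_stratum"] == "rural", "weight"].iloc[0]
        assert rural / city == pytest.approx(0.5)

    def test_weighted_shares_recover_population_shares(self, specs):
        """Closed form: weighted share of stratum s is its population share,
        regardless of over-sampling."""
        cohort = generate_baseline(200_000, specs, seed=12)
        w = assign_weights(cohort, {"city": 1.0, "rural": 2.0, "remote": 2.0}, self.SHARES, seed=12)
        total = w.data["weight"].sum()
        for stratum, share in self.SHARES.items():
            got = w.data.loc[w.data["area_stratum"] == stratum, "weight"].sum() / total
            se = np.sqrt(share * (1 - share) / 200_000)
            assert got == pytest.approx(share, abs=5 * se)

    def test_bad_fractions_rejected(self, specs):
        cohort = generate_baseline(10, specs, seed=1)
        with pytest.raises(ValueError, match="positive"):
            assign_weights(cohort, {"city": 0.0, "rural": 1.0, "remote": 1.0}, self.SHARES, seed=1)


def test_cohort_table_absorbing_validation():
    df = pd.DataFrame(
        {
            "id": [1],
            "smoking": ["Never smoker"],
            "status_s2": ["dead"],
            "status_s3": ["respondent"],
            "status_s4": ["respondent"],
            "status_s5": ["respondent"],
        }
    )
    with pytest.raises(ValueError, match="absorbing"):
        CohortTable(df, ["smoking"]).validate()
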