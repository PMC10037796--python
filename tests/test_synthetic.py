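"""Generator: schema, determinism, marginals, closed-form truths, MAR masking."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy.special import expit

import gendermech as gm
from gendermech.preprocess import ALL_COLUMNS
from gendermech.synthetic import MarModel, OutcomeModel, joint_bernoulli_p11


def _with_outcomes(params, **kw):
    """Default params with every outcome model replaced by one simple model."""
    om = OutcomeModel(**{"a": 0.0, "b": 0.0, "c": 0.0, "d": 0.0,
                         "sigma_y": 1.0, "w": {}, **kw})
    return dataclasses.replace(
        params, outcome_models={bm: om for bm in gm.BIOMARKERS})


class TestGenerateCohort:
    def test_empty_cohort_keeps_full_schema(self, params):
        table = gm.generate_cohort(params, n=0, seed=1)
        assert len(table) == 0
        assert tuple(table.columns) == ALL_COLUMNS

    def test_same_inputs_give_byte_identical_tables(self, params):
        a = gm.generate_cohort(params, n=500, seed=42)
        b = gm.generate_cohort(params, n=500, seed=42)
        assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_negative_n_rejected(self, params):
        with pytest.raises(ValueError, match="non-negative"):
            gm.generate_cohort(params, n=-1, seed=0)

    def test_probability_out_of_range_rejected(self, params):
        with pytest.raises(ValueError, match="p_male"):
            dataclasses.replace(params, p_male=1.2)

    def test_marginals_match_generative_model(self, params):
        n = 100_000
        t = gm.generate_cohort(params, n=n, seed=5)
        se = math.sqrt(params.p_male * (1 - params.p_male) / n)
        assert abs(t["sex"].mean() - params.p_male) < 3 * se
        # mediator prevalence within each (S, E) cell follows its logit model
        for m in ("smoking_33", "no_laundry_33", "manual_class_33"):
            mm = params.mediator_models[m]
            for s in (0, 1):
                for e in (0, 1):
                    cell = t[(t.sex == s) & (t.deprived == e)][m]
                    p = mm.prevalence(s, e)
                    assert abs(cell.mean() - p) < 3 * math.sqrt(p * (1 - p) / len(cell))
        # environment marginals and deprivation probability
        assert abs(t["mother_short_education"].mean() - params.p_short_edu) < 3 * se
        p11 = params.p_deprived
        assert abs(t["deprived"].mean() - p11) < 3 * math.sqrt(p11 * (1 - p11) / n)

    def test_deprivation_is_conjunction(self, cohort):
        expected = cohort["mother_short_education"] * cohort["parent_manual_class"]
        assert (cohort["deprived"] == expected).all()

    def test_positivity_at_default_params(self, params):
        t = gm.generate_cohort(params, n=1000, seed=3)
        assert t.groupby(["sex", "deprived"]).size().shape[0] == 4

    def test_log_biomarkers_positive(self, cohort):
        for bm in ("triglycerides", "crp", "cortisol"):
            assert (cohort[bm] > 0).all()


class TestJointBernoulli:
    def test_odds_ratio_recovered(self):
        p11 = joint_bernoulli_p11(0.75, 0.73, 3.0)
        p10, p01 = 0.75 - p11, 0.73 - p11
        p00 = 1 - p11 - p10 - p01
        assert p11 * p00 / (p10 * p01) == pytest.approx(3.0)
        assert all(p > 0 for p in (p11, p10, p01, p00))

    def test_independence_case(self):
        assert joint_bernoulli_p11(0.3, 0.6, 1.0) == pytest.approx(0.18)


class TestComputeTruth:
    def test_no_mediation_no_interaction(self, params):
        p = _with_outcomes(params, b=1.5)
        truth = gm.compute_truth(p, with_cde_g=False)
        for bm in gm.BIOMARKERS:
            assert truth[bm].te == pytest.approx(1.5)
            assert truth[bm].ep_sigma == pytest.approx(0.0)

    def test_pure_interaction(self, params):
        p = _with_outcomes(params, d=0.7)
        truth = gm.compute_truth(p, with_cde_g=False)
        for bm in gm.BIOMARKERS:
            assert truth[bm].ie == pytest.approx(0.7)
            assert truth[bm].te0 == pytest.approx(0.0)

    def test_truth_identities_hold_exactly(self, truth):
        for bm in gm.BIOMARKERS:
            t = truth[bm]
            assert t.ie == pytest.approx(t.te1 - t.te0, abs=1e-12)
            assert t.ep_sigma == pytest.approx((t.te - t.cde_sigma) / t.te, abs=1e-12)
            assert t.ep_e == pytest.approx((t.te - t.te0) / t.te, abs=1e-12)
            om = truth.params.outcome_models[bm]
            assert t.cde_sigma == pytest.approx(
                om.b + om.d * truth.params.p_deprived, abs=1e-12)

    def test_te_matches_brute_force_potential_outcomes(self, params, truth):
        # independent draw of Y(S=1) and Y(S=0) straight from the structural
        # equations, bypassing generate_cohort
        n = 1_000_000
        rng = np.random.default_rng(99)
        e = rng.random(n) < params.p_deprived
        bm, om = "sbp", params.outcome_models["sbp"]
        ys = {}
        for s in (0, 1):
            y = om.a + om.b * s + om.c * e + om.d * s * e
            for m, w in om.w.items():
                mm = params.mediator_models[m]
                pj = expit(mm.alpha + mm.beta * s + mm.gamma * e)
                y = y + w * (rng.random(n) < pj)
            ys[s] = y + rng.normal(0, om.sigma_y, n)
        diff = ys[1] - ys[0]
        mc_se = diff.std(ddof=1) / math.sqrt(n)
        assert abs(diff.mean() - truth[bm].te) < 3 * mc_se

    def test_mc_n_floor_for_score_oracle(self, params):
        with pytest.raises(ValueError, match="100,000"):
            gm.compute_truth(params, mc_n=1000)


class TestInjectMissingness:
    def test_zero_missingness_when_intercepts_neg_inf(self, params, cohort):
        mar = {c: MarModel(-np.inf, {}) for c in params.mar_params}
        p = dataclasses.replace(params, mar_params=mar)
        masked = gm.inject_missingness(cohort, p, seed=1)
        assert_frame_equal(masked, cohort, check_dtype=False)

    def test_missing_fractions_match_model(self, params):
        n = 50_000
        t = gm.generate_cohort(params, n=n, seed=7)
        masked = gm.inject_missingness(t, params, seed=7)
        for col in ("sbp", "crp", "smoking_33"):
            mm = params.mar_params[col]
            eta = np.full(n, mm.intercept)
            for pred, coef in mm.coef.items():
                eta += coef * t[pred].to_numpy(float)
            rate = expit(eta).mean()
            frac = masked[col].isna().mean()
            assert abs(frac - rate) < 3 * math.sqrt(rate * (1 - rate) / n)

    def test_sex_and_environment_never_masked(self, masked_cohort):
        for col in ("sex", "mother_short_education", "parent_manual_class", "deprived"):
            assert masked_cohort[col].notna().all()

    def test_mar_model_on_maskable_column_rejected(self, params):
        mar = dict(params.mar_params)
        mar["sbp"] = MarModel(-1.0, {"crp": 0.5})
        with pytest.raises(ValueError, match="MAR"):
            dataclasses.replace(params, mar_params=mar)

    def test_incomplete_input_rejected(self, params, masked_cohort):
        with pytest.raises(ValueError, match="complete"):
            gm.inject_missingness(masked_cohort, params, seed=1)


def test_params_yaml_roundtrip(tmp_path, params):
    path = tmp_path / "scenario.yaml"
    gm.save_params(params, path)
    loaded = gm.load_params(path)
    assert loaded == params
    assert_frame_equal(gm.generate_cohort(loaded, 100, 5),
                       gm.generate_cohort(params, 100, 5))
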