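"""G-computation core: model fitting, counterfactual means, contrasts."""

import math

import numpy as np
import pandas as pd
import pytest

import gendermech as gm
from gendermech.estimands import GENDER_SCORE, ScenarioSpec

from conftest import toy_cell_table


def contrast_se(table, qbar):
    """OLS standard error of the sex contrast beta_S + beta_SE * mean(E)."""
    from gendermech.estimands import _design

    x = _design(table, qbar.terms, {})
    resid = table[qbar.outcome].to_numpy(float) - x @ qbar.coef
    if qbar.scale == "z":
        resid = resid / qbar.sigma
    s2 = resid @ resid / (len(table) - x.shape[1])
    c = np.zeros(x.shape[1])
    c[list(qbar.terms).index("sex")] = 1.0
    c[list(qbar.terms).index("sex:deprived")] = table["deprived"].mean()
    return math.sqrt(s2 * c @ np.linalg.inv(x.T @ x) @ c)


@pytest.fixture(scope="module")
def qbar_se(cohort_t):
    return gm.fit_qbar(cohort_t, "sbp", "S*E")


@pytest.fixture(scope="module")
def scored_cohort(cohort_t):
    model = gm.fit_gender_model(cohort_t, gm.COMPLETE_SET)
    return cohort_t.assign(**{GENDER_SCORE: gm.predict_gender_score(model, cohort_t)})


class TestFitQbar:
    def test_saturated_model_reproduces_cell_means(self, cohort_t, qbar_se):
        observed = cohort_t.groupby(["sex", "deprived"])["sbp"].mean()
        for (s, e), mu in observed.items():
            got = gm.gcomp_mean(qbar_se, cohort_t, ScenarioSpec(s=s, e=e))
            assert got == pytest.approx(mu, abs=1e-10)

    def test_z_scale_centers_outcome(self, cohort_t):
        q = gm.fit_qbar(cohort_t, "sbp", "S*E", scale="z")
        assert gm.gcomp_mean(q, cohort_t, ScenarioSpec()) == pytest.approx(0.0, abs=1e-10)

    def test_sigma_spec_has_no_sex_mediator_products(self, cohort_t):
        q = gm.fit_qbar(cohort_t, "sbp", "S*E+Sigma",
                        mediators=gm.SMALL_SET.mediators)
        assert "sex:deprived" in q.terms
        assert not any(":" in t and t != "sex:deprived" for t in q.terms)
        assert set(gm.SMALL_SET.mediators) <= set(q.terms)

    def test_empty_cell_rejected_with_cell_named(self, cohort_t):
        crippled = cohort_t[~((cohort_t.sex == 1) & (cohort_t.deprived == 1))]
        with pytest.raises(ValueError, match=r"\(S=1, E=1\)"):
            gm.fit_qbar(crippled, "sbp", "S*E")

    def test_incomplete_table_rejected(self, masked_cohort):
        with pytest.raises(ValueError, match="complete"):
            gm.fit_qbar(masked_cohort, "sbp", "S*E")

    def test_unknown_spec_rejected(self, cohort_t):
        with pytest.raises(ValueError, match="spec"):
            gm.fit_qbar(cohort_t, "sbp", "S+E")


class TestGcompMean:
    def test_empty_scenario_gives_sample_mean(self, cohort_t, qbar_se):
        got = gm.gcomp_mean(qbar_se, cohort_t, ScenarioSpec())
        assert got == pytest.approx(cohort_t["sbp"].mean(), abs=1e-10)

    def test_toy_fixture_matches_per_row_enumeration(self):
        cells = {(1, 0): 10.0, (1, 1): 14.0, (0, 0): 7.0, (0, 1): 9.0}
        t = toy_cell_table(cells)
        q = gm.fit_qbar(t, "y", "S*E")
        # hand enumeration: with S forced to 1, each row predicts the
        # (1, e_i) observed cell mean
        expected = np.mean([cells[(1, e)] for e in t["deprived"]])
        assert gm.gcomp_mean(q, t, ScenarioSpec(s=1)) == pytest.approx(expected, abs=1e-10)

    def test_scenario_with_score_needs_score_model(self, cohort_t, qbar_se):
        with pytest.raises(ValueError, match="no score term"):
            gm.gcomp_mean(qbar_se, cohort_t, ScenarioSpec(s=1, g=0.5))

    def test_scenario_cannot_set_score_and_mediators(self):
        with pytest.raises(ValueError, match="never both"):
            ScenarioSpec(g=0.5, sigma=gm.ReferenceProfile({"smoking_33": 1}))


class TestTotalEffect:
    def test_null_when_outcome_independent_of_sex(self):
        rng = np.random.default_rng(8)
        n = 20_000
        t = pd.DataFrame({"sex": rng.integers(0, 2, n),
                          "deprived": rng.integers(0, 2, n)})
        t["y"] = 2.0 + 0.5 * t["deprived"] + rng.normal(0, 1, n)
        q = gm.fit_qbar(t, "y", "S*E")
        mc_se = 2.0 / math.sqrt(n)
        assert abs(gm.total_effect(q, t).point) < 3 * mc_se

    def test_te_close_to_generative_truth(self, params, truth):
        n = 50_000
        t = gm.transform_outcomes(gm.generate_cohort(params, n=n, seed=17))
        for bm in ("sbp", "crp"):
            col = gm.outcome_column(bm)
            q = gm.fit_qbar(t, col, "S*E")
            mc_se = 2.0 * t[col].std() / math.sqrt(n)
            assert abs(gm.total_effect(q, t).point - truth[bm].te) < 3 * mc_se

    def test_te_decomposes_over_strata(self, cohort_t, qbar_se):
        te = gm.total_effect(qbar_se, cohort_t).point
        te0 = gm.stratum_total_effect(qbar_se, cohort_t, 0).point
        te1 = gm.stratum_total_effect(qbar_se, cohort_t, 1).point
        p1 = cohort_t["deprived"].mean()
        assert te == pytest.approx((1 - p1) * te0 + p1 * te1, abs=1e-10)


class TestControlledDirectEffects:
    def test_cde_g_invariant_to_g0(self, scored_cohort):
        q = gm.fit_qbar(scored_cohort, "sbp", "S*E+G")
        a = gm.controlled_direct_effect_score(q, scored_cohort, g0=0.5).point
        b = gm.controlled_direct_effect_score(q, scored_cohort, g0=0.9).point
        assert a == pytest.approx(b, abs=1e-10)

    def test_g0_outside_unit_interval_rejected(self, scored_cohort):
        q = gm.fit_qbar(scored_cohort, "sbp", "S*E+G")
        with pytest.raises(ValueError, match="g0"):
            gm.controlled_direct_effect_score(q, scored_cohort, g0=1.5)

    def test_cde_sigma_invariant_to_reference_profile(self, cohort_t):
        q = gm.fit_qbar(cohort_t, "sbp", "S*E+Sigma", mediators=gm.COMPLETE_SET.mediators)
        zeros = gm.ReferenceProfile({m: 0 for m in gm.COMPLETE_SET.mediators})
        modal = gm.modal_reference_profile(cohort_t, gm.COMPLETE_SET)
        a = gm.controlled_direct_effect_mediators(q, cohort_t, zeros).point
        b = gm.controlled_direct_effect_mediators(q, cohort_t, modal).point
        assert a == pytest.approx(b, abs=1e-10)

    def test_incomplete_reference_rejected(self, cohort_t):
        q = gm.fit_qbar(cohort_t, "sbp", "S*E+Sigma", mediators=gm.COMPLETE_SET.mediators)
        with pytest.raises(ValueError, match="does not cover"):
            gm.controlled_direct_effect_mediators(
                q, cohort_t, gm.ReferenceProfile({"smoking_33": 1}))

    def test_cde_sigma_near_b_when_no_interaction(self, params):
        # d = 0: the controlled direct effect reduces to the sex coefficient
        import dataclasses
        from gendermech.synthetic import OutcomeModel
        om = params.outcome_models["sbp"]
        p = dataclasses.replace(params, outcome_models={
            **params.outcome_models,
            "sbp": OutcomeModel(om.a, om.b, om.c, 0.0, om.sigma_y, om.w)})
        n = 50_000
        t = gm.transform_outcomes(gm.generate_cohort(p, n=n, seed=19))
        q = gm.fit_qbar(t, "sbp", "S*E+Sigma", mediators=gm.COMPLETE_SET.mediators)
        ref = gm.modal_reference_profile(t, gm.COMPLETE_SET)
        got = gm.controlled_direct_effect_mediators(q, t, ref).point
        assert abs(got - om.b) < 3 * contrast_se(t, q)

    def test_inert_mediators_give_cde_equal_te(self, params):
        # all w_j = 0: mediation is absent; both contrasts estimate b + d*P(E)
        import dataclasses
        from gendermech.synthetic import OutcomeModel
        new = {bm: OutcomeModel(om.a, om.b, om.c, om.d, om.sigma_y, {})
               for bm, om in params.outcome_models.items()}
        p = dataclasses.replace(params, outcome_models=new)
        t = gm.transform_outcomes(gm.generate_cohort(p, n=30_000, seed=23))
        q_se = gm.fit_qbar(t, "sbp", "S*E")
        q_sig = gm.fit_qbar(t, "sbp", "S*E+Sigma", mediators=gm.COMPLETE_SET.mediators)
        te = gm.total_effect(q_se, t).point
        cde = gm.controlled_direct_effect_mediators(
            q_sig, t, gm.modal_reference_profile(t, gm.COMPLETE_SET)).point
        # both estimate b + d*P(E); difference is sampling noise bounded by
        # the two contrasts' OLS standard errors
        tol = 3 * math.hypot(contrast_se(t, q_se), contrast_se(t, q_sig))
        assert cde == pytest.approx(te, abs=tol)

    def test_cde_g_close_to_monte_carlo_oracle(self, params, truth):
        n = 50_000
        t = gm.transform_outcomes(gm.generate_cohort(params, n=n, seed=29))
        model = gm.fit_gender_model(t, gm.COMPLETE_SET)
        scored = t.assign(**{GENDER_SCORE: gm.predict_gender_score(model, t)})
        bt = truth["sbp"]
        q = gm.fit_qbar(scored, "sbp", "S*E+G")
        got = gm.controlled_direct_effect_score(q, scored, 0.5).point
        # estimator noise at n plus oracle MC noise
        tol = 3 * math.sqrt(bt.cde_g_se**2 * (1 + 200_000 / n))
        assert abs(got - bt.cde_g) < tol


class TestInteractionContrasts:
    def test_ie_identities(self, cohort_t, qbar_se):
        ie = gm.additive_interaction(qbar_se, cohort_t).point
        te0 = gm.stratum_total_effect(qbar_se, cohort_t, 0).point
        te1 = gm.stratum_total_effect(qbar_se, cohort_t, 1).point
        dep1 = gm.deprivation_effect_by_sex(qbar_se, cohort_t, 1).point
        dep0 = gm.deprivation_effect_by_sex(qbar_se, cohort_t, 0).point
        assert ie == pytest.approx(te1 - te0, abs=1e-10)
        assert ie == pytest.approx(dep1 - dep0, abs=1e-10)

    def test_parallel_effects_give_zero_interaction(self):
        t = toy_cell_table({(0, 0): 1.0, (0, 1): 2.0, (1, 0): 3.0, (1, 1): 4.0})
        q = gm.fit_qbar(t, "y", "S*E")
        assert gm.additive_interaction(q, t).point == pytest.approx(0.0, abs=1e-10)

    def test_identical_cell_means_give_zero_stratum_effect(self):
        t = toy_cell_table({(0, 0): 5.0, (0, 1): 5.0, (1, 0): 5.0, (1, 1): 5.0})
        q = gm.fit_qbar(t, "y", "S*E")
        assert gm.stratum_total_effect(q, t, 0).point == pytest.approx(0.0, abs=1e-10)
        assert gm.deprivation_effect_by_sex(q, t, 1).point == pytest.approx(0.0, abs=1e-10)


class TestEliminatedProportion:
    @pytest.mark.parametrize(
        "te, remaining, expected",
        [(0.5, 0.5, 0.0),      # nothing eliminated
         (0.5, 0.0, 1.0),      # full elimination
         (0.5, 0.6, -0.2)],    # attenuation: gap widens, negative EP
    )
    def test_values(self, te, remaining, expected):
        assert gm.eliminated_proportion(te, remaining) == pytest.approx(expected)

    def test_zero_te_undefined_not_crashing(self):
        assert math.isnan(gm.eliminated_proportion(0.0, 0.3))


class TestAffineEquivariance:
    def test_z_scale_equals_original_over_sigma(self, cohort_t):
        for bm in ("sbp", "crp"):
            col = gm.outcome_column(bm)
            qo = gm.fit_qbar(cohort_t, col, "S*E", scale="original")
            qz = gm.fit_qbar(cohort_t, col, "S*E", scale="z")
            sigma = cohort_t[col].std(ddof=1)
            for op in (gm.total_effect, gm.additive_interaction):
                assert op(qz, cohort_t).point == pytest.approx(
                    op(qo, cohort_t).point / sigma, abs=1e-10)
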