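"""Treat/no-treat specialization: regret values, profiles, thresholds."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualthreshold import (
    BenefitHarmProfile,
    DualWeights,
    OutcomeQuadruple,
    Regime,
    critical_gamma,
    decide,
    dual_threshold,
    eut_threshold,
    profile_from_outcomes,
    regret_values,
    valuation_notreat,
    valuation_treat,
)
from dualthreshold.scenarios import numeric_indifference, random_scenarios


@st.composite
def standard_quads(draw):
    x3 = draw(st.floats(min_value=0.01, max_value=0.98))
    x1 = draw(st.floats(min_value=x3 + 0.01, max_value=1.0))
    x2 = draw(st.floats(min_value=0.01, max_value=0.98))
    x4 = draw(st.floats(min_value=x2 + 0.01, max_value=1.0))
    return OutcomeQuadruple(x1=x1, x2=x2, x3=x3, x4=x4)


@st.composite
def interior_weights(draw):
    # gamma of exactly 0 and well-scaled positives; subnormal gammas would
    # underflow the system I correction and are not meaningful inputs
    gamma = draw(st.one_of(st.just(0.0),
                           st.floats(min_value=1e-9, max_value=0.99)))
    return DualWeights(
        gamma=gamma,
        k=draw(st.sampled_from([0.5, 1.0, 2.0])),
        m_i=draw(st.floats(min_value=0.05, max_value=1.0)),
    )


class TestRegretValues:
    def test_right_in_retrospect_cells_carry_no_regret(self):
        quad = OutcomeQuadruple(x1=0.9, x2=0.7, x3=0.4, x4=0.95)
        table = regret_values(quad, DualWeights(gamma=0.5))
        assert table.rg_rx_dpos == 0.0
        assert table.rg_norx_dneg == 0.0

    def test_no_benefit_means_no_regret_of_omission(self):
        quad = OutcomeQuadruple(x1=0.5, x2=0.3, x3=0.5, x4=0.9,
                                non_standard=True)
        table = regret_values(quad, DualWeights(gamma=0.5))
        assert table.rg_norx_dpos == 0.0

    def test_no_harm_means_no_regret_of_commission(self):
        quad = OutcomeQuadruple(x1=0.9, x2=0.6, x3=0.4, x4=0.6,
                                non_standard=True)
        table = regret_values(quad, DualWeights(gamma=0.5))
        assert table.rg_rx_dneg == 0.0

    def test_omission_regret_is_power_value_difference(self):
        quad = OutcomeQuadruple(x1=0.9, x2=0.2, x3=0.4, x4=0.95)
        table = regret_values(quad, DualWeights(gamma=0.5, m_i=1.0))
        assert table.rg_norx_dpos == pytest.approx(-0.5, abs=1e-15)


class TestProfileDerivation:
    def test_linear_value_function_collapses_the_systems(self):
        quad = OutcomeQuadruple(x1=0.9, x2=0.7, x3=0.4, x4=0.95)
        prof = profile_from_outcomes(quad, DualWeights(gamma=0.5, m_i=1.0))
        assert prof.b2 == pytest.approx(0.5)
        assert prof.h2 == pytest.approx(0.25)
        assert prof.b1 == prof.b2
        assert prof.h1 == prof.h2

    def test_square_root_curvature_hand_values(self):
        quad = OutcomeQuadruple(x1=0.81, x2=0.49, x3=0.36, x4=1.0)
        prof = profile_from_outcomes(quad, DualWeights(gamma=0.5, m_i=0.5))
        assert prof.b1 == pytest.approx(0.3, abs=1e-12)
        assert prof.h1 == pytest.approx(0.3, abs=1e-12)

    def test_inverted_benefit_rejected_unless_flagged(self):
        with pytest.raises(ValueError, match="x1 > x3"):
            OutcomeQuadruple(x1=0.4, x2=0.7, x3=0.9, x4=0.95)
        quad = OutcomeQuadruple(x1=0.4, x2=0.7, x3=0.9, x4=0.95,
                                non_standard=True)
        with pytest.raises(ValueError, match="b2"):
            profile = profile_from_outcomes(quad, DualWeights(gamma=0.5))
            BenefitHarmProfile(b2=profile.b2, h2=profile.h2,
                               b1=profile.b1, h1=profile.h1)


class TestValuations:
    def test_gamma_zero_is_pure_expected_utility(self):
        quad = OutcomeQuadruple(x1=0.9, x2=0.7, x3=0.4, x4=0.95)
        w = DualWeights(gamma=0.0, k=1.0)
        p = 0.3
        assert valuation_treat(p, quad, w) == pytest.approx(
            p * quad.x1 + (1 - p) * quad.x2)
        assert valuation_notreat(p, quad, w) == pytest.approx(
            p * quad.x3 + (1 - p) * quad.x4)
        assert valuation_notreat(0.0, quad, w) == pytest.approx(quad.x4)

    def test_pure_system1_valuation_ignores_probability(self):
        quad = OutcomeQuadruple(x1=0.9, x2=0.7, x3=0.4, x4=0.95)
        w = DualWeights(gamma=1.0, m_i=0.7)
        values = {valuation_treat(p, quad, w) for p in (0.0, 0.3, 0.9, 1.0)}
        assert len(values) == 1

    @settings(max_examples=150, derandomize=True)
    @given(standard_quads(), interior_weights(),
           st.floats(min_value=0.0, max_value=1.0))
    def test_valuations_match_generic_dual_value(self, quad, w, p):
        """Eqs. for the two actions equal the generic model applied to each
        branch with regret as the system I value (2 outcomes, n = 2)."""
        table = regret_values(quad, w)
        # generic model: gamma * mean(V_I) + (1-gamma) * k * sum(p_i x_i);
        # the treat branch has system I values (0, rg_rx_dneg)
        treat_generic = (
            w.gamma * (table.rg_rx_dpos + table.rg_rx_dneg) / 2.0
            + (1 - w.gamma) * w.k * (p * quad.x1 + (1 - p) * quad.x2)
        )
        notreat_generic = (
            w.gamma * (table.rg_norx_dpos + table.rg_norx_dneg) / 2.0
            + (1 - w.gamma) * w.k * (p * quad.x3 + (1 - p) * quad.x4)
        )
        assert valuation_treat(p, quad, w) == pytest.approx(
            treat_generic, abs=1e-12)
        assert valuation_notreat(p, quad, w) == pytest.approx(
            notreat_generic, abs=1e-12)


class TestEutThreshold:
    @pytest.mark.parametrize(
        "b2, h2, expected",
        [
            (60.8, 1.0, 1.0 / 61.8),    # PE best case, prints as 1.6%
            (1.0, 1.0, 0.5),            # equal benefit and harm
            (0.12, 0.16, 0.16 / 0.28),  # AML transplant, prints as 57.1%
        ],
    )
    def test_published_thresholds(self, b2, h2, expected):
        prof = BenefitHarmProfile(b2=b2, h2=h2, b1=1.0, h1=1.0)
        assert eut_threshold(prof) == pytest.approx(expected, abs=1e-15)

    def test_rounds_to_printed_percentages(self):
        pe = BenefitHarmProfile(b2=60.8, h2=1.0, b1=1.0, h1=1.0)
        aml = BenefitHarmProfile(b2=0.12, h2=0.16, b1=1.0, h1=1.0)
        assert round(100 * eut_threshold(pe), 1) == 1.6
        assert round(100 * eut_threshold(aml), 1) == 57.1


class TestDualThreshold:
    def test_gamma_zero_reduces_to_eut_exactly(self, pe_worst_profile):
        res = dual_threshold(pe_worst_profile, DualWeights(gamma=0.0))
        assert res.p_dual_raw == res.p_eut

    def test_pe_worst_case_published_value(self, pe_worst_profile, pe_weights):
        res = dual_threshold(pe_worst_profile, pe_weights)
        assert res.p_dual_raw == pytest.approx(0.966, abs=5e-4)
        assert round(100 * res.p_dual_raw, 1) == 96.6
        assert res.regime is Regime.INTERIOR

    def test_pe_threshold_saturates_just_above(self, pe_worst_profile):
        res = dual_threshold(pe_worst_profile, DualWeights(gamma=0.78))
        assert res.p_dual_raw >= 1.0
        assert res.regime is Regime.NEVER_TREAT
        assert res.p_dual == 1.0

    def test_neutral_system1_gives_eut_for_all_gamma(self):
        prof = BenefitHarmProfile(b2=0.3, h2=0.1, b1=0.2, h1=0.2)
        for g in [i / 100 for i in range(100)]:
            res = dual_threshold(prof, DualWeights(gamma=g))
            assert res.p_dual_raw == res.p_eut

    def test_gamma_one_is_categorical_regime(self, pe_worst_profile):
        res = dual_threshold(pe_worst_profile, DualWeights(gamma=1.0))
        assert res.regime is Regime.SYSTEM1_ONLY
        assert res.p_dual_raw is None and res.p_dual is None

    @settings(max_examples=150, derandomize=True)
    @given(standard_quads(), interior_weights())
    def test_side_of_eut_follows_system1_balance(self, quad, w):
        prof = profile_from_outcomes(quad, w)
        res = dual_threshold(prof, w)
        delta = prof.b1 - prof.h1
        if w.gamma == 0.0 or delta == 0.0:
            assert res.p_dual_raw == pytest.approx(res.p_eut, abs=1e-15)
        elif delta > 0:
            assert res.p_dual_raw < res.p_eut
        else:
            assert res.p_dual_raw > res.p_eut

    @settings(max_examples=100, derandomize=True)
    @given(standard_quads(), interior_weights(),
           st.floats(min_value=0.01, max_value=0.98))
    def test_monotone_in_gamma_per_system1_sign(self, quad, w, g_lo):
        prof = profile_from_outcomes(quad, w)
        g_hi = g_lo + 0.01
        lo = dual_threshold(prof, DualWeights(gamma=g_lo, k=w.k)).p_dual_raw
        hi = dual_threshold(prof, DualWeights(gamma=g_hi, k=w.k)).p_dual_raw
        delta = prof.b1 - prof.h1
        if delta > 0:
            assert hi < lo
        elif delta < 0:
            assert hi > lo
        else:
            assert hi == lo

    @settings(max_examples=100, derandomize=True)
    @given(standard_quads(), interior_weights(),
           st.sampled_from([0.25, 0.5, 2.0, 4.0]))
    def test_k_never_flips_side_of_eut(self, quad, w, k_scale):
        prof = profile_from_outcomes(quad, w)
        res = dual_threshold(prof, w)
        res_k = dual_threshold(
            prof, DualWeights(gamma=w.gamma, k=w.k * k_scale, m_i=w.m_i))
        side = (res.p_dual_raw or res.p_eut) - res.p_eut
        side_k = (res_k.p_dual_raw or res_k.p_eut) - res_k.p_eut
        assert math.copysign(1, side) == math.copysign(1, side_k) or (
            side == 0 and side_k == 0)


class TestDecide:
    def test_below_threshold_withholds_treatment(self, aml_pessimistic):
        res = dual_threshold(aml_pessimistic, DualWeights(gamma=0.0))
        assert decide(0.5, res, aml_pessimistic) == "no_treat"
        assert decide(0.6, res, aml_pessimistic) == "treat"

    def test_exact_threshold_is_indifferent(self, pe_worst_profile, pe_weights):
        res = dual_threshold(pe_worst_profile, pe_weights)
        assert decide(res.p_dual_raw, res, pe_worst_profile) == "indifferent"

    def test_pure_system1_decides_by_felt_balance(self):
        prof = BenefitHarmProfile(b2=0.1, h2=0.1, b1=0.3, h1=0.1)
        res = dual_threshold(prof, DualWeights(gamma=1.0))
        for p in (0.0, 0.5, 1.0):
            assert decide(p, res, prof) == "treat"
        harm = BenefitHarmProfile(b2=0.1, h2=0.1, b1=0.1, h1=0.3)
        res_h = dual_threshold(harm, DualWeights(gamma=1.0))
        assert decide(0.99, res_h, harm) == "no_treat"

    def test_probability_out_of_range_rejected(self, aml_pessimistic):
        res = dual_threshold(aml_pessimistic, DualWeights(gamma=0.0))
        with pytest.raises(ValueError):
            decide(1.5, res, aml_pessimistic)


class TestCriticalGamma:
    def test_neutral_system1_has_no_boundary(self):
        prof = BenefitHarmProfile(b2=0.2, h2=0.1, b1=0.15, h1=0.15)
        assert critical_gamma(prof, 1.0, "never_treat") is None
        assert critical_gamma(prof, 1.0, "always_treat") is None

    def test_aml_never_treat_boundary(self, aml_pessimistic):
        g = critical_gamma(aml_pessimistic, 1.0, "never_treat")
        assert g == pytest.approx(0.12 / 0.22, abs=1e-15)
        assert round(100 * g) == 55

    def test_aml_always_treat_boundary(self, aml_optimistic):
        g = critical_gamma(aml_optimistic, 1.0, "always_treat")
        assert g == pytest.approx(0.16 / 0.18, abs=1e-12)
        assert round(100 * g) == 89

    @settings(max_examples=100, derandomize=True)
    @given(standard_quads(), interior_weights())
    def test_boundary_brackets_the_regime_change(self, quad, w):
        prof = profile_from_outcomes(quad, w)
        for boundary, target in (("never_treat", 1.0), ("always_treat", 0.0)):
            g = critical_gamma(prof, w.k, boundary)
            if g is None:
                continue
            assert 0.0 < g < 1.0
            eps = 1e-6
            below = dual_threshold(
                prof, DualWeights(gamma=max(g - eps, 0.0), k=w.k)).p_dual_raw
            above = dual_threshold(
                prof, DualWeights(gamma=min(g + eps, 1 - 1e-9), k=w.k)).p_dual_raw
            if boundary == "never_treat":
                assert below < target < above or below <= target <= above
            else:
                assert above < target < below or above <= target <= below


class TestOracleEquivalence:
    def test_closed_form_matches_bisection_on_1000_scenarios(self):
        """The threshold expression and a root-bracketing search over the two
        valuation functions must agree wherever the root exists."""
        worst = 0.0
        compared = 0
        for fx in random_scenarios(20120903, 1000):
            res = dual_threshold(fx.profile, fx.weights)
            root = numeric_indifference(fx.quad, fx.weights)
            if root is None:
                # root outside the extended bracket: raw threshold must be too
                assert abs(res.p_dual_raw) > 9.9
                continue
            worst = max(worst, abs(root - res.p_dual_raw))
            compared += 1
        assert compared > 900
        assert worst < 1e-12
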