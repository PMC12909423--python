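"""Carbonate speciation, alkalinity inversion, pH solving and titration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methalk.carbonate_system import (
    CarbonateError,
    dic_from_alkalinity_ph,
    equilibrium_constants,
    ph_from_composition,
    speciate_from_ph_dic,
    speciation_fractions,
    titration_total_alkalinity,
)


class TestEquilibriumConstants:
    def test_ideal_defaults_reproduce_printed_pka(self, ideal25):
        assert -math.log10(ideal25.ka1) == pytest.approx(6.33, abs=1e-12)
        assert -math.log10(ideal25.ka2) == pytest.approx(10.33, abs=1e-12)
        assert ideal25.gamma_mono == 1.0 and ideal25.gamma_di == 1.0

    def test_davies_reduces_to_ideal_at_zero_ionic_strength(self, ideal25):
        davies0 = equilibrium_constants(298.15, 0.0, "davies")
        assert davies0.gamma_mono == ideal25.gamma_mono == 1.0
        assert davies0.ka1_cond == ideal25.ka1_cond
        assert davies0.ka2_cond == ideal25.ka2_cond

    def test_davies_coefficients_at_tenth_molar(self, davies01):
        # hand evaluation: -0.509 * (sqrt(.1)/(1+sqrt(.1)) - 0.03) = -0.1070188
        assert math.log10(davies01.gamma_mono) == pytest.approx(-0.1070188, abs=1e-6)
        assert math.log10(davies01.gamma_di) == pytest.approx(4 * -0.1070188, abs=1e-6)
        assert 0 < davies01.gamma_di < davies01.gamma_mono < 1

    def test_davies_outside_validity_raises(self):
        with pytest.raises(CarbonateError, match="Davies"):
            equilibrium_constants(298.15, 2.5, "davies")

    def test_temperature_outside_liquid_range_raises(self):
        with pytest.raises(CarbonateError):
            equilibrium_constants(200.0)

    def test_vant_hoff_hook_is_identity_at_reference_temperature(self, ideal25):
        shifted = ideal25.with_vant_hoff(298.15, dh_ka1=7.7, dh_ka2=14.9)
        assert shifted.ka1 == pytest.approx(ideal25.ka1, rel=1e-12)
        # a positive enthalpy raises Ka with temperature
        warm = ideal25.with_vant_hoff(308.15, dh_ka1=7.7, dh_ka2=14.9)
        assert warm.ka1 > ideal25.ka1


class TestSpeciation:
    def test_closed_form_fractions_at_ph9(self, ideal25):
        # oracle: f = 1/(1 + Ka1/aH + Ka1 Ka2/aH^2) etc., Ka = 10^-6.33 / 10^-10.33
        state = speciate_from_ph_dic(9.0, 0.100, ideal25)
        assert state.conc_co2aq == pytest.approx(2.0383e-4, rel=1e-4)
        assert state.conc_hco3 == pytest.approx(9.5337e-2, rel=1e-4)
        assert state.conc_co3 == pytest.approx(4.4592e-3, rel=1e-4)
        assert state.dic == pytest.approx(0.100, rel=1e-12)

    def test_zero_dic_leaves_only_water(self, ideal25):
        state = speciate_from_ph_dic(8.0, 0.0, ideal25)
        assert state.conc_co2aq == state.conc_hco3 == state.conc_co3 == 0.0
        assert state.carbonate_alkalinity == pytest.approx(state.conc_oh - state.conc_h, rel=1e-12)

    def test_co2_equals_bicarbonate_at_pka1(self, ideal25):
        state = speciate_from_ph_dic(6.33, 0.05, ideal25)
        assert state.conc_co2aq == pytest.approx(state.conc_hco3, rel=1e-12)

    def test_negative_dic_rejected(self, ideal25):
        with pytest.raises(CarbonateError):
            speciate_from_ph_dic(8.0, -0.1, ideal25)

    @pytest.mark.parametrize("model,i", [("ideal", 0.0), ("davies", 0.1), ("davies", 0.5)])
    def test_fractions_sum_to_one_and_are_monotone(self, model, i):
        consts = equilibrium_constants(298.15, i, model)
        grid = np.arange(2.0, 13.01, 0.5)
        fracs = np.array([speciation_fractions(ph, consts) for ph in grid])
        assert np.all(np.abs(fracs.sum(axis=1) - 1.0) < 1e-12)
        assert np.all(np.diff(fracs[:, 0]) < 0)  # f_CO2 strictly decreasing
        assert np.all(np.diff(fracs[:, 2]) > 0)  # f_CO3 strictly increasing


class TestAlkalinityInversion:
    def test_algebraic_solution_at_ph10(self, ideal25):
        # oracle: DIC = (alk - [OH] + [H]) / (f1 + 2 f2), ratio 10^(pH - pKa2)
        state = dic_from_alkalinity_ph(0.6, 10.0, ideal25)
        assert state.dic == pytest.approx(0.45499, rel=1e-4)
        assert state.conc_hco3 == pytest.approx(0.30995, rel=1e-4)
        assert state.conc_co3 == pytest.approx(0.14497, rel=1e-4)
        assert state.conc_co2aq == pytest.approx(6.627e-5, rel=1e-3)
        assert state.carbonate_alkalinity == pytest.approx(0.6, rel=1e-10)

    def test_algebraic_solution_at_ph9(self, ideal25):
        state = dic_from_alkalinity_ph(0.1, 9.0, ideal25)
        assert state.conc_hco3 == pytest.approx(0.09144, rel=1e-3)
        assert state.conc_co3 == pytest.approx(4.277e-3, rel=1e-3)

    def test_infeasible_alkalinity_raises(self, ideal25):
        with pytest.raises(CarbonateError, match="infeasible"):
            dic_from_alkalinity_ph(5e-5, 10.0, ideal25)  # below the water contribution

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        alk=st.floats(min_value=0.01, max_value=1.2),
        ph=st.floats(min_value=7.0, max_value=11.0),
    )
    def test_round_trip_alkalinity(self, alk, ph):
        consts = equilibrium_constants()
        state = dic_from_alkalinity_ph(alk, ph, consts)
        assert state.carbonate_alkalinity == pytest.approx(alk, rel=1e-9)
        again = speciate_from_ph_dic(ph, state.dic, consts)
        assert again.carbonate_alkalinity == pytest.approx(alk, rel=1e-9)


class TestPhFromComposition:
    def test_pure_water_is_neutral(self, ideal25):
        state = ph_from_composition({}, 0.0, ideal25)
        assert state.ph == pytest.approx(7.0, abs=1e-9)

    def test_equimolar_buffer_sits_at_pka2(self, ideal25):
        # Na+ exactly balancing HCO3- + 2 CO3-- of an equimolar mix
        c = 0.2
        state = ph_from_composition({"Na+": 3 * c}, 2 * c, ideal25)
        assert state.ph == pytest.approx(10.33, abs=0.01)
        assert state.conc_hco3 == pytest.approx(state.conc_co3, rel=0.02)

    def test_printed_recipe_buffer_ph(self):
        # the 0.6 eq/L / pH 9 published recipe should land near its measured
        # buffer pH of 9.04 under the Davies default
        from methalk.medium_design import predict_buffer_ph, printed_recipe

        state = predict_buffer_ph(printed_recipe(0.6, 9.0))
        assert state.ph == pytest.approx(9.04, abs=0.15)

    def test_charge_balance_residual_is_tiny(self, ideal25):
        state = ph_from_composition({"Na+": 0.35, "Cl-": -0.05}, 0.25, ideal25)
        residual = 0.30 - state.carbonate_alkalinity
        assert abs(residual) < 1e-10

    def test_unreachable_charge_raises(self, ideal25):
        with pytest.raises(CarbonateError, match="no charge-balance root"):
            ph_from_composition({"Na+": -5.0}, 0.0, ideal25)


class TestTitration:
    def test_carbonate_only_converges_to_alkalinity(self, ideal25):
        state = dic_from_alkalinity_ph(0.10, 9.0, ideal25)
        acid = titration_total_alkalinity(state, 1e-4, 4.3, ideal25)
        assert acid == pytest.approx(0.100, abs=1e-3)

    def test_fine_step_matches_closed_form(self, ideal25):
        # closed system: acid to endpoint = TA(start) - TA(end) exactly
        state = dic_from_alkalinity_ph(0.05, 9.5, ideal25)
        end = speciate_from_ph_dic(4.3, state.dic, ideal25)
        expected = state.carbonate_alkalinity - end.carbonate_alkalinity
        acid = titration_total_alkalinity(state, 2e-5, 4.3, ideal25)
        assert acid == pytest.approx(expected, rel=5e-3)

    def test_unbuffered_water_consumes_almost_nothing(self, ideal25):
        state = speciate_from_ph_dic(7.0, 0.0, ideal25)
        acid = titration_total_alkalinity(state, 1e-5, 4.3, ideal25)
        assert acid < 2e-4

    def test_acetate_adds_its_weak_base_contribution(self, ideal25):
        # Henderson-Hasselbalch oracle (pKa 4.76): acetate protonated between
        # pH 9 and the 4.3 endpoint adds 0.015*(0.9999 - 0.2575) = 0.01114 eq/L
        state = dic_from_alkalinity_ph(0.10, 9.0, ideal25)
        acid = titration_total_alkalinity(state, 1e-4, 4.3, ideal25, total_acetate=0.015)
        plain = titration_total_alkalinity(state, 1e-4, 4.3, ideal25)
        assert acid - plain == pytest.approx(0.01114, abs=5e-4)

    def test_endpoint_above_sample_ph_rejected(self, ideal25):
        state = dic_from_alkalinity_ph(0.10, 9.0, ideal25)
        with pytest.raises(CarbonateError):
            titration_total_alkalinity(state, 1e-4, 9.5, ideal25)
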