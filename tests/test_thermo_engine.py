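"""Reaction energetics: dG1 arithmetic, additivity, and landscape structure."""

import math

import numpy as np
import pytest

from methalk.carbonate_system import CarbonateError, R_GAS
from methalk.thermo_engine import (
    ACETATE_OXIDATION,
    ACETOCLASTIC,
    ALL_REACTIONS,
    HYDROGENOTROPHIC,
    ConditionSet,
    Reaction,
    build_initial_conditions,
    combine_reactions,
    compute_landscape,
    delta_g1,
    element_imbalance,
    gibbs_helmholtz_dg0,
)


def reference_delta_g1(reaction, cond):
    """Independent term-by-term oracle using plain math on the quotient."""
    q = 1.0
    for species, coeff in reaction.stoichiometry.items():
        if species == "H2O":
            continue
        q *= (cond.gamma(species) * cond.concentration(species)) ** coeff
    return reaction.delta_g0 + R_GAS * cond.temperature * math.log(q)


def random_condition(rng):
    return ConditionSet(
        temperature=rng.uniform(280, 320),
        ph=rng.uniform(5, 11),
        acetate=10 ** rng.uniform(-4, -1),
        h2=10 ** rng.uniform(-7, -3),
        ch4=10 ** rng.uniform(-6, -2),
        co2aq=10 ** rng.uniform(-5, -0.5),
    )


class TestReactions:
    @pytest.mark.parametrize("reaction", ALL_REACTIONS, ids=lambda r: r.name)
    def test_element_and_charge_balance(self, reaction):
        imbalance = element_imbalance(reaction)
        assert all(abs(v) < 1e-12 for v in imbalance.values()), imbalance

    def test_standard_energies(self):
        assert ACETOCLASTIC.delta_g0 == -65.83
        assert HYDROGENOTROPHIC.delta_g0 == -140.82
        assert ACETATE_OXIDATION.delta_g0 == 75.0


class TestDeltaG1:
    @pytest.mark.parametrize("reaction", ALL_REACTIONS, ids=lambda r: r.name)
    def test_all_unit_concentrations_return_dg0(self, reaction):
        ones = ConditionSet(temperature=308.15, ph=0.0, acetate=1, h2=1, ch4=1, co2aq=1)
        assert delta_g1(reaction, ones) == pytest.approx(reaction.delta_g0, abs=1e-12)

    def test_acetoclastic_at_ph9_alkalinity06(self):
        # hand evaluation of dG0 + RT sum Y ln c with the closed-form
        # speciation giving CO2(aq) = 1.173e-3 M
        cond = build_initial_conditions(0.6, 9.0)
        assert cond.co2aq == pytest.approx(1.173e-3, rel=1e-3)
        assert delta_g1(ACETOCLASTIC, cond) == pytest.approx(-47.72, abs=0.05)

    def test_oracle_equivalence_on_random_conditions(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            cond = random_condition(rng)
            for reaction in ALL_REACTIONS:
                assert delta_g1(reaction, cond) == pytest.approx(
                    reference_delta_g1(reaction, cond), abs=1e-9
                )

    def test_additivity_of_combined_reactions(self):
        rng = np.random.default_rng(7)
        combined = combine_reactions(ACETATE_OXIDATION, 1, HYDROGENOTROPHIC, 1)
        for _ in range(25):
            cond = random_condition(rng)
            expected = delta_g1(ACETATE_OXIDATION, cond) + delta_g1(HYDROGENOTROPHIC, cond)
            assert delta_g1(combined, cond) == pytest.approx(expected, abs=1e-9)

    def test_activity_coefficients_enter_the_quotient(self):
        cond = ConditionSet(
            temperature=308.15, ph=9.0, acetate=0.015, h2=2.85e-6, ch4=1.5e-5,
            co2aq=1e-3, activity_coefficients={"acetate": 0.7},
        )
        base = ConditionSet(temperature=308.15, ph=9.0, acetate=0.015 * 0.7, h2=2.85e-6,
                            ch4=1.5e-5, co2aq=1e-3)
        assert delta_g1(ACETOCLASTIC, cond) == pytest.approx(delta_g1(ACETOCLASTIC, base), abs=1e-9)

    def test_non_positive_concentration_rejected(self):
        cond = ConditionSet(temperature=308.15, ph=9.0, acetate=0.0, h2=1e-6, ch4=1e-5, co2aq=1e-3)
        with pytest.raises(CarbonateError, match="non-positive"):
            delta_g1(ACETOCLASTIC, cond)

    def test_missing_species_reported(self):
        bare = Reaction("odd", {"NH3": -1.0}, 0.0)
        cond = ConditionSet(temperature=308.15, ph=9.0, acetate=1, h2=1, ch4=1, co2aq=1)
        with pytest.raises(CarbonateError, match="lacks a concentration"):
            delta_g1(bare, cond)


class TestCombineReactions:
    def test_oxidation_plus_hydrogenotrophic_is_acetoclastic(self):
        net = combine_reactions(ACETATE_OXIDATION, 1, HYDROGENOTROPHIC, 1)
        assert dict(net.stoichiometry) == dict(ACETOCLASTIC.stoichiometry)
        assert net.delta_g0 == pytest.approx(-65.82, abs=1e-12)
        # the published acetoclastic value agrees to the printed precision
        assert net.delta_g0 == pytest.approx(ACETOCLASTIC.delta_g0, abs=0.011)

    def test_identity_and_annihilation(self):
        same = combine_reactions(ACETOCLASTIC, 1, HYDROGENOTROPHIC, 0)
        assert dict(same.stoichiometry) == dict(ACETOCLASTIC.stoichiometry)
        assert same.delta_g0 == ACETOCLASTIC.delta_g0
        nothing = combine_reactions(ACETOCLASTIC, 1, ACETOCLASTIC, -1)
        assert nothing.stoichiometry == {}
        assert nothing.delta_g0 == 0.0


class TestInitialConditions:
    def test_fixed_background_concentrations(self):
        cond = build_initial_conditions(0.6, 9.0)
        assert cond.acetate == 0.015
        assert cond.h2 == 2.85e-6
        assert cond.ch4 == 1.5e-5
        assert cond.temperature == 308.15

    def test_co2_scales_linearly_with_alkalinity_at_fixed_ph(self):
        low = build_initial_conditions(0.1, 6.0)
        high = build_initial_conditions(1.2, 6.0)
        assert high.co2aq / low.co2aq == pytest.approx(12.0, rel=1e-3)


@pytest.fixture(scope="module")
def landscape():
    return compute_landscape(n_points=41)


class TestLandscape:
    def test_shape_and_finiteness(self, landscape):
        assert landscape.delta_g.shape == (3, 3, 41)
        assert np.all(np.isfinite(landscape.delta_g))

    def test_acetoclastic_always_most_favourable(self, landscape):
        aceto = landscape.delta_g[0]
        assert np.all(aceto < landscape.delta_g[1])
        assert np.all(aceto < landscape.delta_g[2])
        assert np.all(aceto < 0)

    def test_hydrogenotrophic_monotonicities(self, landscape):
        hydro = landscape.delta_g[1]
        # more alkalinity -> more CO2 -> more exergonic
        assert np.all(hydro[2] < hydro[1]) and np.all(hydro[1] < hydro[0])
        # higher pH -> less CO2 -> less favourable
        assert np.all(np.diff(hydro, axis=1) > 0)

    def test_oxidation_monotonicities(self, landscape):
        oxid = landscape.delta_g[2]
        assert np.all(np.diff(oxid, axis=1) < 0)  # more favourable at high pH
        assert np.all(oxid[2] > oxid[1]) and np.all(oxid[1] > oxid[0])

    def test_long_format_frame(self, landscape):
        df = landscape.to_frame()
        assert len(df) == 3 * 3 * 41
        assert set(df.columns) == {"reaction", "alkalinity", "ph", "delta_g_kj_mol"}

    def test_gibbs_helmholtz_mode(self):
        assert gibbs_helmholtz_dg0(-65.83, -30.0, 298.15) == pytest.approx(-65.83, abs=1e-12)
        adjusted = compute_landscape(
            n_points=5, delta_h0={r.name: -20.0 for r in ALL_REACTIONS}
        )
        assert "gibbs-helmholtz" in adjusted.metadata["dg0_mode"]
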