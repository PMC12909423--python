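"""Henry's-law partitioning and closed-bottle mass balance.

Batch incubations run in sealed 115 mL serum bottles with 65 mL of liquid
and an argon headspace. Converting acetate produces, per mole, one mole of
CH4 and one mole of inorganic carbon while raising the carbonate alkalinity
by one equivalent (an anion is consumed together with a proton at fixed
Na+); both the acetoclastic route and the syntrophic-oxidation +
hydrogenotrophic route net out to the same totals. The bottle equilibrium
couples three constraints solved simultaneously for the final pH:

* liquid charge balance (fixed cations vs carbonate/phosphate/acetate anions),
* carbon balance with CO2(aq) <-> headspace CO2 via Henry's law + ideal gas,
* CH4 and H2 partitioning between liquid and headspace.

The bottle is rigid: produced gas raises total pressure above the 1 bar of
argon fill rather than venting, which conserves moles exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from scipy.optimize import brentq

from .carbonate_system import (
    CarbonateError,
    CarbonateState,
    EquilibriumConstants,
    acetate_anion_fraction,
    equilibrium_constants,
    phosphate_charge,
    speciate_from_ph_dic,
    speciation_fractions,
)
from .medium_design import MediumRecipe

#: ideal-gas constant in L bar / (mol K)
R_LBAR = 0.0831446

#: mol H2 made per mol acetate oxidised, mol CH4 per mol acetate (net, both routes)
_CH4_PER_ACETATE = 1.0
_DIC_PER_ACETATE = 1.0
_ALK_PER_ACETATE = 1.0


@dataclass(frozen=True)
class HenryConstants:
    """Henry solubilities in mmol/(kg bar); 1 kg of medium taken as 1 L.

    H2 and CH4 are the study's stated values; CO2 (needed for the bottle
    balance but not stated) defaults to a 35 degC textbook value.
    """

    h2: float = 0.78
    ch4: float = 1.4
    co2: float = 29.4

    def __post_init__(self) -> None:
        if min(self.h2, self.ch4, self.co2) <= 0:
            raise CarbonateError("Henry constants must be > 0")


@dataclass(frozen=True)
class BatchGeometry:
    """Serum-bottle geometry and headspace fill."""

    total_volume: float = 0.115  # L
    liquid_volume: float = 0.065  # L
    temperature: float = 308.15  # K
    fill_pressure: float = 1.0  # bar of inert gas (argon)

    def __post_init__(self) -> None:
        if self.headspace_volume <= 0:
            raise CarbonateError("headspace volume must be positive")

    @property
    def headspace_volume(self) -> float:
        return self.total_volume - self.liquid_volume

    @property
    def inert_moles(self) -> float:
        return self.fill_pressure * self.headspace_volume / (R_LBAR * self.temperature)


def dissolved_concentration(partial_pressure: float, henry: float) -> float:
    """Dissolved concentration (mmol/L) at a gas partial pressure (bar)."""
    if partial_pressure < 0:
        raise CarbonateError("partial pressure must be >= 0")
    return henry * partial_pressure


def apply_conversion(
    recipe: MediumRecipe, acetate_converted: float, pathway: str = "acetoclastic"
) -> tuple[float, float, float]:
    """Net (delta_dic, delta_ch4, delta_alkalinity) for converted acetate (mol/L).

    ``pathway`` is "acetoclastic" or "sao_hydrogenotrophic"; the two routes
    share the same net stoichiometry (2 CO2 made, 1 consumed on the SAO
    route), so the deltas are identical.
    """
    if pathway not in ("acetoclastic", "sao_hydrogenotrophic"):
        raise CarbonateError(f"unknown pathway {pathway!r}")
    if not (0.0 <= acetate_converted <= recipe.na_acetate + 1e-15):
        raise CarbonateError(
            f"acetate_converted {acetate_converted} outside [0, {recipe.na_acetate}]"
        )
    return (
        _DIC_PER_ACETATE * acetate_converted,
        _CH4_PER_ACETATE * acetate_converted,
        _ALK_PER_ACETATE * acetate_converted,
    )


@dataclass(frozen=True)
class ConversionOutcome:
    """Equilibrated bottle after a given acetate conversion."""

    final_state: CarbonateState
    final_ph: float
    total_pressure: float  # bar
    headspace_fractions: Mapping[str, float]  # % incl. inert, sums to 100
    measured_fractions: Mapping[str, float]  # % of CO2+CH4+H2 only (gas-bag basis)
    gas_moles: Mapping[str, float]  # mol in headspace
    liquid_moles: Mapping[str, float]  # mol dissolved
    residual_acetate: float  # mol/L


def _dissolved_gas(total_moles: float, henry: float, geometry: BatchGeometry) -> tuple[float, float]:
    """Partition a fixed gas inventory; returns (conc mol/L, partial pressure bar)."""
    # n_tot = c*Vl + (c/H) * Vg/(R T)   with H in mol/(L bar)
    h = henry * 1e-3
    denom = geometry.liquid_volume + geometry.headspace_volume / (h * R_LBAR * geometry.temperature)
    conc = total_moles / denom
    return conc, conc / h


def equilibrate_bottle(
    recipe: MediumRecipe,
    acetate_converted: float,
    geometry: BatchGeometry | None = None,
    henry: HenryConstants | None = None,
    consts: EquilibriumConstants | None = None,
    initial_h2: float = 0.0,
    initial_ch4: float = 0.0,
) -> ConversionOutcome:
    """Solve the coupled bottle equilibrium after converting acetate.

    The single unknown is the final pH: at a trial pH the carbon balance
    fixes CO2(aq) (and hence DIC and headspace CO2), and the charge-balance
    residual is driven to zero by bracketed root finding. ``initial_h2`` and
    ``initial_ch4`` are dissolved abiotic background levels (mol/L).
    """
    geometry = geometry or BatchGeometry()
    henry = henry or HenryConstants()
    if consts is None:
        consts = equilibrium_constants(298.15, 0.0, "ideal")

    v_l = geometry.liquid_volume
    delta_dic, delta_ch4, _ = apply_conversion(recipe, acetate_converted)

    # total inventories (mol)
    dic_total = (recipe.total_carbonate + delta_dic) * v_l
    ch4_total = (initial_ch4 + delta_ch4) * v_l
    h2_total = initial_h2 * v_l
    residual_acetate = recipe.na_acetate - acetate_converted

    # fixed (non-protolytic) net charge in the liquid, eq/L: all Na+ and NH4+
    # against Cl- and HS-; NH4+/NH3 speciation neglected (<= 5 meq/L).
    na_total = (
        recipe.nahco3
        + 2 * recipe.na2co3
        + recipe.nah2po4
        + 2 * recipe.na2hpo4
        + recipe.nacl
        + 2 * recipe.na2s
        + recipe.na_acetate
    )
    net_fixed = na_total + recipe.nh4cl - (recipe.nacl + recipe.nh4cl) - recipe.na2s

    h_gas = henry.co2 * 1e-3  # mol/(L bar)
    gas_term = geometry.headspace_volume / (h_gas * R_LBAR * geometry.temperature)

    def co2aq_at(ph: float) -> float:
        f0, _, _ = speciation_fractions(ph, consts)
        # dic_total = co2aq * (Vl / f0) + (co2aq / H) * Vg / (R T)
        return dic_total / (v_l / f0 + gas_term)

    def charge_residual(ph: float) -> float:
        co2aq = co2aq_at(ph)
        f0, f1, f2 = speciation_fractions(ph, consts)
        dic_liquid = co2aq / f0
        carb_charge = dic_liquid * (f1 + 2.0 * f2)
        res = net_fixed + consts.conc_h(ph) - consts.conc_oh(ph)
        res -= carb_charge
        res -= phosphate_charge(ph, recipe.total_phosphate, consts)
        res -= residual_acetate * acetate_anion_fraction(ph, consts)
        return res

    lo, hi = 4.0, 13.0
    if charge_residual(lo) * charge_residual(hi) > 0:
        raise CarbonateError(
            "bottle equilibrium: no charge-balance root in pH [4, 13]; residuals "
            f"{charge_residual(lo):.3e}, {charge_residual(hi):.3e} eq/L"
        )
    ph = brentq(charge_residual, lo, hi, xtol=1e-13, rtol=8.9e-16)

    co2aq = co2aq_at(ph)
    f0, _, _ = speciation_fractions(ph, consts)
    state = speciate_from_ph_dic(ph, co2aq / f0, consts)
    p_co2 = co2aq / h_gas
    n_co2_gas = p_co2 * geometry.headspace_volume / (R_LBAR * geometry.temperature)

    ch4_aq, p_ch4 = _dissolved_gas(ch4_total, henry.ch4, geometry)
    h2_aq, p_h2 = _dissolved_gas(h2_total, henry.h2, geometry) if h2_total > 0 else (0.0, 0.0)

    p_inert = geometry.inert_moles * R_LBAR * geometry.temperature / geometry.headspace_volume
    pressures = {"CO2": p_co2, "CH4": p_ch4, "H2": p_h2, "inert": p_inert}
    p_total = sum(pressures.values())
    fractions = {gas: 100.0 * p / p_total for gas, p in pressures.items()}
    p_measured = p_co2 + p_ch4 + p_h2
    measured = {
        gas: (100.0 * pressures[gas] / p_measured if p_measured > 0 else math.nan)
        for gas in ("CO2", "CH4", "H2")
    }

    gas_moles = {
        "CO2": n_co2_gas,
        "CH4": p_ch4 * geometry.headspace_volume / (R_LBAR * geometry.temperature),
        "H2": p_h2 * geometry.headspace_volume / (R_LBAR * geometry.temperature),
        "inert": geometry.inert_moles,
    }
    liquid_moles = {
        "DIC": state.dic * v_l,
        "CH4": ch4_aq * v_l,
        "H2": h2_aq * v_l,
        "acetate": residual_acetate * v_l,
    }
    return ConversionOutcome(
        final_state=state,
        final_ph=ph,
        total_pressure=p_total,
        headspace_fractions=fractions,
        measured_fractions=measured,
        gas_moles=gas_moles,
        liquid_moles=liquid_moles,
        residual_acetate=residual_acetate,
    )


def carbon_inventory(outcome: ConversionOutcome, recipe: MediumRecipe, geometry: BatchGeometry | None = None) -> dict[str, float]:
    """Mole bookkeeping for the carbon conservation check.

    Returns initial and final carbon pools (mol); acetate carries 2 C.
    """
    geometry = geometry or BatchGeometry()
    v_l = geometry.liquid_volume
    initial = recipe.total_carbonate * v_l + 2.0 * recipe.na_acetate * v_l
    final = (
        outcome.liquid_moles["DIC"]
        + outcome.gas_moles["CO2"]
        + outcome.liquid_moles["CH4"]
        + outcome.gas_moles["CH4"]
        + 2.0 * outcome.liquid_moles["acetate"]
    )
    return {"initial": initial, "final": final, "error": final - initial}
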