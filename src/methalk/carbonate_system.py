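"""Equilibrium chemistry of the CO2-H2O (plus optional phosphate) system.

The CO2-H2O acid-base system has three dissolved inorganic carbon species,
CO2(aq), HCO3- and CO3(2-), linked by two dissociation steps with pKa values
of 6.33 and 10.33 at 25 degC. Two derived quantities describe the system:

* DIC (dissolved inorganic carbon) = [CO2(aq)] + [HCO3-] + [CO3(2-)],
  the carbon balance, and
* carbonate alkalinity = [HCO3-] + 2[CO3(2-)] + [OH-] - [H+],
  the charge balance / buffering capacity.

This module provides speciation at a given pH, inversion from alkalinity,
a charge-balance pH solver for arbitrary salt mixtures, and a simulated
strong-acid titration. Non-ideality is handled with the Davies single-ion
activity model; all equilibrium quotients are expressed as conditional
(concentration-based) constants with [H+] carried as the activity 10^-pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

from scipy.optimize import brentq

#: gas constant, kJ/(mol K)
R_GAS = 8.314e-3

#: carbonate dissociation pKa values at 25 degC, infinite dilution
PKA1_25C = 6.33
PKA2_25C = 10.33
PKW_25C = 14.0

#: Debye-Hueckel limiting slope at 25 degC (Davies equation prefactor)
DAVIES_A = 0.509
#: Davies validity ceiling, mol/L
DAVIES_I_MAX = 2.0

#: phosphoric acid pKa values at 25 degC (pKp2 = 7.2 is the one that matters
#: for the pH 7-9 media; pKp1/pKp3 are far from the working range)
PKP1_25C = 2.15
PKP2_25C = 7.20
PKP3_25C = 12.35

#: acetic acid pKa at 25 degC (acetate is a weak base in titrations)
PKA_ACETATE = 4.76

PH_BRACKET = (2.0, 13.0)


class CarbonateError(ValueError):
    """Domain or solver error in the carbonate-system calculations."""


def davies_log10_gamma(ionic_strength: float, charge: int, a: float = DAVIES_A) -> float:
    """Davies equation: log10 gamma = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I)."""
    if ionic_strength < 0:
        raise CarbonateError("ionic strength must be >= 0")
    if ionic_strength == 0:
        return 0.0
    s = math.sqrt(ionic_strength)
    return -a * charge**2 * (s / (1.0 + s) - 0.3 * ionic_strength)


@dataclass(frozen=True)
class EquilibriumConstants:
    """Dissociation constants and single-ion activity coefficients.

    ``ka1``/``ka2``/``kw``/``kp*`` are thermodynamic (activity) constants;
    ``gamma_mono``/``gamma_di`` convert them to the conditional concentration
    quotients used throughout (``ka1_cond`` etc.). Under ``activity_model
    = "ideal"`` both coefficients are 1 and conditional equals thermodynamic.
    """

    temperature: float = 298.15
    ionic_strength: float = 0.0
    activity_model: str = "ideal"
    ka1: float = 10.0**-PKA1_25C
    ka2: float = 10.0**-PKA2_25C
    kw: float = 10.0**-PKW_25C
    gamma_mono: float = 1.0
    gamma_di: float = 1.0
    kp1: float = 10.0**-PKP1_25C
    kp2: float = 10.0**-PKP2_25C
    kp3: float = 10.0**-PKP3_25C

    def __post_init__(self) -> None:
        if not (self.ka1 > self.ka2 > 0):
            raise CarbonateError("require Ka1 > Ka2 > 0")
        if not (0 < self.gamma_di <= self.gamma_mono <= 1.0):
            raise CarbonateError("require 0 < gamma_di <= gamma_mono <= 1")

    # conditional constants: concentration quotients with a_H = 10^-pH
    @property
    def ka1_cond(self) -> float:
        # Ka1 = a_H * gamma1 [HCO3] / [CO2(aq)]  (neutral CO2: gamma = 1)
        return self.ka1 / self.gamma_mono

    @property
    def ka2_cond(self) -> float:
        # Ka2 = a_H * gamma2 [CO3] / (gamma1 [HCO3])
        return self.ka2 * self.gamma_mono / self.gamma_di

    @property
    def kp2_cond(self) -> float:
        return self.kp2 * self.gamma_mono / self.gamma_di

    @property
    def kp1_cond(self) -> float:
        return self.kp1 / self.gamma_mono

    @property
    def kp3_cond(self) -> float:
        # HPO4(2-) <-> PO4(3-): gamma ratio approximated with the Davies
        # trivalent coefficient gamma_mono^9 ~ (z^2 scaling)
        gamma_tri = self.gamma_mono**9
        return self.kp3 * self.gamma_di / gamma_tri

    def conc_h(self, ph: float) -> float:
        """[H+] in mol/L from the pH (an activity measurement)."""
        return 10.0**-ph / self.gamma_mono

    def conc_oh(self, ph: float) -> float:
        """[OH-] in mol/L: Kw = a_H * gamma1 [OH-]."""
        return self.kw / (10.0**-ph * self.gamma_mono)

    def with_vant_hoff(self, temperature: float, dh_ka1: float, dh_ka2: float) -> "EquilibriumConstants":
        """Optional van't Hoff temperature correction of Ka1/Ka2.

        ``dh_ka*`` are standard reaction enthalpies in kJ/mol supplied by the
        user; no default temperature dependence is applied by the package.
        """
        t0 = 298.15
        factor1 = math.exp(-dh_ka1 / R_GAS * (1.0 / temperature - 1.0 / t0))
        factor2 = math.exp(-dh_ka2 / R_GAS * (1.0 / temperature - 1.0 / t0))
        return replace(self, temperature=temperature, ka1=self.ka1 * factor1, ka2=self.ka2 * factor2)


def equilibrium_constants(
    temperature: float = 298.15,
    ionic_strength: float = 0.0,
    activity_model: str = "ideal",
) -> EquilibriumConstants:
    """Build the constant set for a given ionic strength and activity model.

    ``activity_model="davies"`` computes mono- and divalent activity
    coefficients from the Davies equation; ``"ideal"`` returns gamma = 1.
    No temperature correction of Ka is applied (see ``with_vant_hoff``).
    """
    if not (273.0 < temperature < 373.0):
        raise CarbonateError(f"temperature {temperature} K outside liquid-water range")
    if ionic_strength < 0:
        raise CarbonateError("ionic_strength must be >= 0")
    if activity_model == "ideal":
        gamma_mono = gamma_di = 1.0
    elif activity_model == "davies":
        if ionic_strength > DAVIES_I_MAX:
            raise CarbonateError(
                f"ionic strength {ionic_strength} mol/L outside Davies validity (<= {DAVIES_I_MAX})"
            )
        gamma_mono = 10.0 ** davies_log10_gamma(ionic_strength, 1)
        gamma_di = 10.0 ** davies_log10_gamma(ionic_strength, 2)
    else:
        raise CarbonateError(f"unknown activity model {activity_model!r}")
    return EquilibriumConstants(
        temperature=temperature,
        ionic_strength=ionic_strength,
        activity_model=activity_model,
        gamma_mono=gamma_mono,
        gamma_di=gamma_di,
    )


@dataclass(frozen=True)
class CarbonateState:
    """Fully speciated CO2-H2O system at one pH."""

    temperature: float
    ph: float
    conc_co2aq: float
    conc_hco3: float
    conc_co3: float
    conc_h: float
    conc_oh: float
    ionic_strength: float = 0.0

    @property
    def dic(self) -> float:
        return self.conc_co2aq + self.conc_hco3 + self.conc_co3

    @property
    def carbonate_alkalinity(self) -> float:
        return self.conc_hco3 + 2.0 * self.conc_co3 + self.conc_oh - self.conc_h


def speciation_fractions(ph: float, consts: EquilibriumConstants) -> tuple[float, float, float]:
    """DIC fractions (f_CO2, f_HCO3, f_CO3) at a given pH.

    Closed form: f_CO2 = 1 / (1 + K'a1/aH + K'a1 K'a2 / aH^2), etc.
    """
    a_h = 10.0**-ph
    r1 = consts.ka1_cond / a_h
    r2 = consts.ka2_cond / a_h
    denom = 1.0 + r1 + r1 * r2
    return 1.0 / denom, r1 / denom, r1 * r2 / denom


def speciate_from_ph_dic(ph: float, dic: float, consts: EquilibriumConstants) -> CarbonateState:
    """Distribute a known DIC over the three carbonate species at a given pH."""
    if not (0.0 < ph < 14.0):
        raise CarbonateError(f"pH {ph} outside (0, 14)")
    if dic < 0:
        raise CarbonateError("DIC must be >= 0")
    f0, f1, f2 = speciation_fractions(ph, consts)
    return CarbonateState(
        temperature=consts.temperature,
        ph=ph,
        conc_co2aq=f0 * dic,
        conc_hco3=f1 * dic,
        conc_co3=f2 * dic,
        conc_h=consts.conc_h(ph),
        conc_oh=consts.conc_oh(ph),
        ionic_strength=consts.ionic_strength,
    )


def dic_from_alkalinity_ph(
    carbonate_alkalinity: float, ph: float, consts: EquilibriumConstants
) -> CarbonateState:
    """Solve for DIC such that the state has the requested carbonate alkalinity.

    Algebraic inversion: alkalinity - ([OH-] - [H+]) = DIC * (f1 + 2 f2).
    """
    water_alk = consts.conc_oh(ph) - consts.conc_h(ph)
    if carbonate_alkalinity <= water_alk:
        raise CarbonateError(
            f"alkalinity {carbonate_alkalinity} eq/L infeasible at pH {ph}: "
            f"water alone contributes {water_alk:.3e} eq/L"
        )
    _, f1, f2 = speciation_fractions(ph, consts)
    dic = (carbonate_alkalinity - water_alk) / (f1 + 2.0 * f2)
    return speciate_from_ph_dic(ph, dic, consts)


def phosphate_charge(ph: float, total_phosphate: float, consts: EquilibriumConstants) -> float:
    """Negative charge (eq/L) carried by phosphate species at a given pH."""
    if total_phosphate <= 0:
        return 0.0
    a_h = 10.0**-ph
    r1 = consts.kp1_cond / a_h
    r2 = consts.kp2_cond / a_h
    r3 = consts.kp3_cond / a_h
    denom = 1.0 + r1 + r1 * r2 + r1 * r2 * r3
    f1 = r1 / denom
    f2 = r1 * r2 / denom
    f3 = r1 * r2 * r3 / denom
    return total_phosphate * (f1 + 2.0 * f2 + 3.0 * f3)


def acetate_anion_fraction(ph: float, consts: EquilibriumConstants) -> float:
    """Fraction of total acetate present as the acetate anion."""
    ratio = (10.0**-PKA_ACETATE / consts.gamma_mono) / 10.0**-ph
    return ratio / (1.0 + ratio)


def _charge_residual(
    ph: float,
    net_fixed_charge: float,
    total_carbonate: float,
    consts: EquilibriumConstants,
    total_phosphate: float,
    total_acetate: float,
) -> float:
    """Charge balance: fixed cations + [H+] - [OH-] - weak-acid anions."""
    state = speciate_from_ph_dic(ph, total_carbonate, consts)
    res = net_fixed_charge + state.conc_h - state.conc_oh
    res -= state.conc_hco3 + 2.0 * state.conc_co3
    res -= phosphate_charge(ph, total_phosphate, consts)
    res -= total_acetate * acetate_anion_fraction(ph, consts)
    return res


def ph_from_composition(
    component_charges: Mapping[str, float],
    total_carbonate: float,
    consts: EquilibriumConstants,
    total_phosphate: float = 0.0,
    total_acetate: float = 0.0,
) -> CarbonateState:
    """Solve the charge balance for pH given a salt inventory.

    ``component_charges`` maps fixed (non-protolytic) ion names to their
    signed charge contribution in eq/L, e.g. ``{"Na+": 0.60, "Cl-": -0.05}``.
    Carbonate, phosphate and acetate are passed as totals and speciated at
    the trial pH. Bracketed root finding on pH in [2, 13].
    """
    if total_carbonate < 0:
        raise CarbonateError("total_carbonate must be >= 0")
    net = float(sum(component_charges.values()))
    if not math.isfinite(net):
        raise CarbonateError("non-finite net fixed charge")

    def residual(ph: float) -> float:
        return _charge_residual(ph, net, total_carbonate, consts, total_phosphate, total_acetate)

    lo, hi = PH_BRACKET
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0:
        raise CarbonateError(
            f"no charge-balance root in pH [{lo}, {hi}]: residuals {r_lo:.3e}, {r_hi:.3e} eq/L"
        )
    ph = brentq(residual, lo, hi, xtol=1e-13, rtol=8.9e-16)
    return speciate_from_ph_dic(ph, total_carbonate, consts)


def titration_total_alkalinity(
    state: CarbonateState,
    acid_step: float,
    endpoint_ph: float,
    consts: EquilibriumConstants | None = None,
    total_acetate: float = 0.0,
    total_phosphate: float = 0.0,
) -> float:
    """Simulated strong-acid titration to an endpoint pH; returns eq/L consumed.

    The sample is closed (no CO2 loss); each increment of strong acid reduces
    the net fixed positive charge and the pH is re-solved from the charge
    balance. As ``acid_step -> 0`` the result converges to the carbonate
    alkalinity plus any weak-base (acetate, phosphate) contribution between
    the start and endpoint pH.
    """
    if consts is None:
        consts = equilibrium_constants(state.temperature, state.ionic_strength)
    if endpoint_ph >= state.ph:
        raise CarbonateError("endpoint pH must lie below the sample pH")
    if acid_step <= 0:
        raise CarbonateError("acid_step must be > 0")

    # infer the fixed net charge that supports the current pH
    dic = state.dic
    net0 = -_charge_residual(state.ph, 0.0, dic, consts, total_phosphate, total_acetate)

    def ph_at(acid: float) -> float:
        def residual(ph: float) -> float:
            return _charge_residual(ph, net0 - acid, dic, consts, total_phosphate, total_acetate)

        return brentq(residual, PH_BRACKET[0], PH_BRACKET[1], xtol=1e-13)

    acid = 0.0
    ph_prev, ph_cur = state.ph, state.ph
    # hard ceiling well above any alkalinity of interest
    while ph_cur > endpoint_ph:
        acid += acid_step
        ph_prev, ph_cur = ph_cur, ph_at(acid)
        if acid > 10.0:
            raise CarbonateError("titration failed to reach endpoint below 10 eq/L acid")
    if ph_prev == ph_cur:
        return acid
    # linear interpolation inside the final increment
    frac = (ph_prev - endpoint_ph) / (ph_prev - ph_cur)
    return acid - acid_step * (1.0 - frac)
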