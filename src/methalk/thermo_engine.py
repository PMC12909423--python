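"""Non-ideal Gibbs free energy of the three acetate-linked catabolisms.

Three catabolic routes compete for acetate in a haloalkaline methanogenic
community:

* acetoclastic methanogenesis:    CH3COO- + H+ -> CO2 + CH4        (dG0 -65.83 kJ/mol)
* hydrogenotrophic methanogenesis: 4 H2 + CO2 -> CH4 + 2 H2O       (dG0 -140.82 kJ/mol)
* (syntrophic) acetate oxidation: CH3COO- + 2 H2O + H+ -> 4 H2 + 2 CO2  (dG0 +75 kJ/mol)

The concentration-corrected (non-ideal) free energy is

    dG1 = dG0 + R T sum_i Y_i ln(gamma_i c_i)

with Y_i the signed stoichiometric coefficients (negative = consumed),
gamma_i activity coefficients (all 1 by default), water excluded (activity
1) and H+ entered as the activity 10^-pH. Only dissolved CO2 counts among
the inorganic carbon species; its concentration at a given pH/alkalinity
comes from the carbonate speciation solver. Landscapes over pH 6-10 at the
three study alkalinities (0.1, 0.6, 1.2 eq/L) reproduce the feasibility
orderings of the three pathways.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .carbonate_system import (
    R_GAS,
    CarbonateError,
    EquilibriumConstants,
    dic_from_alkalinity_ph,
    equilibrium_constants,
)

#: experimental incubation temperature, K (35 degC)
T_EXPERIMENT = 308.15

#: initial concentrations fixed across all calculations, mol/L
ACETATE_INITIAL = 0.015
H2_INITIAL = 2.85e-6
CH4_INITIAL = 1.5e-5

WATER = "H2O"
H_PLUS = "H+"


@dataclass(frozen=True)
class Reaction:
    """Named stoichiometry map with its standard Gibbs energy (298.15 K)."""

    name: str
    stoichiometry: Mapping[str, float]
    delta_g0: float

    def coefficient(self, species: str) -> float:
        return self.stoichiometry.get(species, 0.0)


ACETOCLASTIC = Reaction(
    "acetoclastic methanogenesis",
    {"acetate": -1.0, H_PLUS: -1.0, "CO2": 1.0, "CH4": 1.0},
    -65.83,
)
HYDROGENOTROPHIC = Reaction(
    "hydrogenotrophic methanogenesis",
    {"H2": -4.0, "CO2": -1.0, "CH4": 1.0, WATER: 2.0},
    -140.82,
)
ACETATE_OXIDATION = Reaction(
    "acetate oxidation",
    {"acetate": -1.0, WATER: -2.0, H_PLUS: -1.0, "H2": 4.0, "CO2": 2.0},
    75.0,
)

ALL_REACTIONS = (ACETOCLASTIC, HYDROGENOTROPHIC, ACETATE_OXIDATION)

#: element and charge composition used for the balance invariant
_COMPOSITION = {
    "acetate": {"C": 2, "H": 3, "O": 2, "charge": -1},
    H_PLUS: {"H": 1, "charge": 1},
    "CO2": {"C": 1, "O": 2},
    "CH4": {"C": 1, "H": 4},
    "H2": {"H": 2},
    WATER: {"H": 2, "O": 1},
}


def element_imbalance(reaction: Reaction) -> dict[str, float]:
    """Net C/H/O/charge created by the reaction (all zero when balanced)."""
    totals: dict[str, float] = {"C": 0.0, "H": 0.0, "O": 0.0, "charge": 0.0}
    for species, coeff in reaction.stoichiometry.items():
        for element, count in _COMPOSITION[species].items():
            totals[element] += coeff * count
    return totals


def combine_reactions(a: Reaction, na: float, b: Reaction, nb: float) -> Reaction:
    """Linear combination na*a + nb*b; zero coefficients are dropped."""
    stoich: dict[str, float] = {}
    for species in set(a.stoichiometry) | set(b.stoichiometry):
        coeff = na * a.coefficient(species) + nb * b.coefficient(species)
        if coeff != 0.0:
            stoich[species] = coeff
    return Reaction(
        name=f"{na:g}x({a.name}) + {nb:g}x({b.name})",
        stoichiometry=stoich,
        delta_g0=na * a.delta_g0 + nb * b.delta_g0,
    )


@dataclass(frozen=True)
class ConditionSet:
    """Concentrations and activities entering dG1 at one pH-alkalinity point."""

    temperature: float
    ph: float
    acetate: float
    h2: float
    ch4: float
    co2aq: float
    activity_coefficients: Mapping[str, float] = field(default_factory=dict)
    alkalinity_label: float | None = None

    @property
    def h_plus(self) -> float:
        return 10.0**-self.ph

    def concentration(self, species: str) -> float:
        if species == H_PLUS:
            return self.h_plus
        if species == "acetate":
            return self.acetate
        if species == "H2":
            return self.h2
        if species == "CH4":
            return self.ch4
        if species == "CO2":
            return self.co2aq
        raise KeyError(species)

    def gamma(self, species: str) -> float:
        return self.activity_coefficients.get(species, 1.0)


def gibbs_helmholtz_dg0(delta_g0_298: float, delta_h0: float, temperature: float) -> float:
    """Shift dG0 from 298.15 K to ``temperature`` given the reaction enthalpy.

    Gibbs-Helmholtz with constant dH0:
    dG0(T) = dH0 - T (dH0 - dG0(298.15)) / 298.15.
    """
    return delta_h0 - temperature * (delta_h0 - delta_g0_298) / 298.15


def delta_g1(
    reaction: Reaction,
    cond: ConditionSet,
    delta_h0: float | None = None,
) -> float:
    """Non-ideal reaction energy dG1 = dG0 + R T sum Y ln(gamma c), kJ/mol.

    Water is excluded (activity 1). When ``delta_h0`` (kJ/mol) is supplied,
    dG0 is first moved to the condition temperature via Gibbs-Helmholtz;
    by default the 298.15 K value is used and only the R T ln Q term carries
    the temperature.
    """
    dg0 = reaction.delta_g0
    if delta_h0 is not None:
        dg0 = gibbs_helmholtz_dg0(dg0, delta_h0, cond.temperature)
    log_q = 0.0
    for species, coeff in reaction.stoichiometry.items():
        if species == WATER:
            continue
        try:
            conc = cond.concentration(species)
        except KeyError:
            raise CarbonateError(f"condition set lacks a concentration for {species!r}") from None
        activity = cond.gamma(species) * conc
        if activity <= 0.0:
            raise CarbonateError(f"non-positive activity for {species!r}: {activity}")
        log_q += coeff * np.log(activity)
    return dg0 + R_GAS * cond.temperature * log_q


def build_initial_conditions(
    alkalinity: float,
    ph: float,
    consts: EquilibriumConstants | None = None,
    temperature: float = T_EXPERIMENT,
) -> ConditionSet:
    """Initial-condition set for one pH-alkalinity point.

    Acetate 15 mM, dissolved H2 0.00285 mM and CH4 0.015 mM (abiotic-control
    levels via Henry's law); CO2(aq) from the ideal carbonate speciation at
    the given alkalinity and pH; all activity coefficients 1.
    """
    if consts is None:
        consts = equilibrium_constants(298.15, 0.0, "ideal")
    state = dic_from_alkalinity_ph(alkalinity, ph, consts)
    return ConditionSet(
        temperature=temperature,
        ph=ph,
        acetate=ACETATE_INITIAL,
        h2=H2_INITIAL,
        ch4=CH4_INITIAL,
        co2aq=state.conc_co2aq,
        alkalinity_label=alkalinity,
    )


@dataclass(frozen=True)
class GibbsLandscape:
    """dG1 surfaces over a pH grid for several alkalinities and reactions."""

    ph_grid: np.ndarray
    alkalinities: tuple[float, ...]
    reactions: tuple[Reaction, ...]
    delta_g: np.ndarray  # shape (n_reactions, n_alkalinities, n_ph)
    metadata: Mapping[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: reaction, alkalinity, pH, delta_g_kj_mol."""
        rows = []
        for (i, rxn), (j, alk) in itertools.product(
            enumerate(self.reactions), enumerate(self.alkalinities)
        ):
            for k, ph in enumerate(self.ph_grid):
                rows.append(
                    {
                        "reaction": rxn.name,
                        "alkalinity": alk,
                        "ph": ph,
                        "delta_g_kj_mol": self.delta_g[i, j, k],
                    }
                )
        return pd.DataFrame(rows)

    def surface(self, reaction: Reaction, alkalinity: float) -> np.ndarray:
        i = self.reactions.index(reaction)
        j = self.alkalinities.index(alkalinity)
        return self.delta_g[i, j]


def compute_landscape(
    ph_min: float = 6.0,
    ph_max: float = 10.0,
    n_points: int = 81,
    alkalinities: tuple[float, ...] = (0.1, 0.6, 1.2),
    reactions: tuple[Reaction, ...] = ALL_REACTIONS,
    temperature: float = T_EXPERIMENT,
    delta_h0: Mapping[str, float] | None = None,
) -> GibbsLandscape:
    """Evaluate dG1 for each reaction on a pH grid at each alkalinity."""
    if n_points < 2:
        raise CarbonateError("need at least 2 grid points")
    ph_grid = np.linspace(ph_min, ph_max, n_points)
    out = np.empty((len(reactions), len(alkalinities), n_points))
    for j, alk in enumerate(alkalinities):
        for k, ph in enumerate(ph_grid):
            cond = build_initial_conditions(alk, ph, temperature=temperature)
            for i, rxn in enumerate(reactions):
                dh = delta_h0.get(rxn.name) if delta_h0 else None
                out[i, j, k] = delta_g1(rxn, cond, delta_h0=dh)
    mode = "gibbs-helmholtz dG0(T)" if delta_h0 else "dG0 at 298.15 K, T only in RTlnQ"
    return GibbsLandscape(
        ph_grid=ph_grid,
        alkalinities=tuple(alkalinities),
        reactions=tuple(reactions),
        delta_g=out,
        metadata={
            "temperature_K": f"{temperature}",
            "dg0_mode": mode,
            "acetate_M": f"{ACETATE_INITIAL}",
            "h2_M": f"{H2_INITIAL}",
            "ch4_M": f"{CH4_INITIAL}",
            "activity": "all coefficients 1; H+ as 10^-pH; water excluded",
        },
    )


def plot_landscape(landscape: GibbsLandscape, path: str | None = None):
    """Three-panel dG1 vs pH plot, one panel per reaction, line per alkalinity."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(landscape.reactions), figsize=(4 * len(landscape.reactions), 3.5), sharex=True)
    for ax, rxn in zip(np.atleast_1d(axes), landscape.reactions):
        for alk in landscape.alkalinities:
            ax.plot(landscape.ph_grid, landscape.surface(rxn, alk), label=f"{alk} eq/L")
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_title(rxn.name, fontsize=9)
        ax.set_xlabel("pH")
    np.atleast_1d(axes)[0].set_ylabel(r"$\Delta G^1$ (kJ/mol)")
    np.atleast_1d(axes)[0].legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
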