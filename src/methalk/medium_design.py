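"""Design of NaHCO3/Na2CO3 (and phosphate) buffered haloalkaline media.

A medium is specified by a target pH and a target total sodium molarity; in
these soda-lake-type media the final Na+ concentration (mol/L) equals the
carbonate alkalinity (eq/L), so "0.6 eq/L alkalinity" means 0.6 M Na+. The
fixed components (NaCl, NH4Cl, Na2S, sodium acetate) contribute a constant
sodium background; the remainder is split between NaHCO3 and Na2CO3 using
the bicarbonate/carbonate equilibrium ratio at the target pH. Media at
pH <= 8.5 additionally receive a phosphate buffer carrying 16% of the total
sodium, split between NaH2PO4 and Na2HPO4 by the pH 7.2 equilibrium ratio.

Buffer design defaults to the Davies activity model with the ionic strength
iterated once from the full recipe ion inventory; the ideal model is kept
available for sensitivity analysis (it visibly mis-predicts the
carbonate/bicarbonate split of concentrated alkaline media).
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import pandas as pd

from .carbonate_system import (
    CarbonateError,
    CarbonateState,
    EquilibriumConstants,
    equilibrium_constants,
    ph_from_composition,
)

#: fixed non-buffer components, mol/L
NACL = 0.05
NH4CL = 0.005
NA2S = 2e-4
NA_ACETATE = 0.015

#: sodium locked in fixed components: NaCl + acetate + 2 x Na2S
FIXED_SODIUM = NACL + NA_ACETATE + 2 * NA2S

#: media at or below this pH get a phosphate buffer
PHOSPHATE_PH_MAX = 8.5
#: fraction of total sodium allocated to phosphate in those media
PHOSPHATE_NA_FRACTION = 0.16


@dataclass(frozen=True)
class MediumRecipe:
    """Component molarities of one buffered medium."""

    target_ph: float
    target_na_total: float
    nahco3: float = 0.0
    na2co3: float = 0.0
    nah2po4: float = 0.0
    na2hpo4: float = 0.0
    nacl: float = 0.0
    nh4cl: float = 0.0
    na2s: float = 0.0
    na_acetate: float = 0.0
    warning: str | None = None

    def __post_init__(self) -> None:
        for name in ("nahco3", "na2co3", "nah2po4", "na2hpo4", "nacl", "nh4cl", "na2s", "na_acetate"):
            if getattr(self, name) < 0:
                raise CarbonateError(f"negative molarity for {name}")

    @property
    def carbonate_sodium(self) -> float:
        return self.nahco3 + 2.0 * self.na2co3

    @property
    def total_carbonate(self) -> float:
        return self.nahco3 + self.na2co3

    @property
    def total_phosphate(self) -> float:
        return self.nah2po4 + self.na2hpo4


def total_sodium(recipe: MediumRecipe) -> float:
    """Stoichiometric total Na+ (mol/L) over all sodium salts."""
    return (
        recipe.nahco3
        + 2.0 * recipe.na2co3
        + recipe.nah2po4
        + 2.0 * recipe.na2hpo4
        + recipe.nacl
        + 2.0 * recipe.na2s
        + recipe.na_acetate
    )


def ionic_strength_of(recipe: MediumRecipe) -> float:
    """Ionic strength (mol/L) of the full recipe ion inventory.

    Added salts are counted at their nominal speciation (HCO3- for NaHCO3,
    CO3(2-) for Na2CO3, HS- for Na2S); re-speciation at the actual pH shifts
    I by well under 1% for these compositions.
    """
    na = total_sodium(recipe)
    contributions = [
        na,  # Na+, z=1
        recipe.nh4cl,  # NH4+
        recipe.nacl + recipe.nh4cl,  # Cl-
        recipe.nahco3,  # HCO3-
        4.0 * recipe.na2co3,  # CO3(2-)
        recipe.nah2po4,  # H2PO4-
        4.0 * recipe.na2hpo4,  # HPO4(2-)
        recipe.na2s,  # HS-
        recipe.na_acetate,  # acetate-
    ]
    return 0.5 * sum(contributions)


def design_carbonate_buffer(
    target_ph: float, carbonate_na: float, consts: EquilibriumConstants
) -> tuple[float, float]:
    """Split a sodium pool (eq/L) between NaHCO3 and Na2CO3 for a target pH.

    With r = [CO3(2-)]/[HCO3-] = K'a2 / 10^-pH at the target pH,
    NaHCO3 = carbonate_na / (1 + 2r) and Na2CO3 = r * NaHCO3.
    """
    if carbonate_na <= 0:
        raise CarbonateError("carbonate sodium pool must be > 0")
    if not (7.0 < target_ph < 12.0):
        raise CarbonateError(f"target pH {target_ph} outside carbonate design range (7, 12)")
    r = consts.ka2_cond / 10.0**-target_ph
    nahco3 = carbonate_na / (1.0 + 2.0 * r)
    return nahco3, r * nahco3


def _phosphate_split(
    target_ph: float, phosphate_na: float, consts: EquilibriumConstants
) -> tuple[float, float]:
    """Split a sodium pool between NaH2PO4 and Na2HPO4 by the pKa2 ratio."""
    rho = consts.kp2_cond / 10.0**-target_ph
    nah2po4 = phosphate_na / (1.0 + 2.0 * rho)
    return nah2po4, rho * nah2po4


def build_medium(
    target_ph: float,
    target_na_total: float,
    consts: EquilibriumConstants | None = None,
    activity_model: str = "davies",
    temperature: float = 298.15,
) -> MediumRecipe:
    """Design the full medium for a target pH and total Na+ (= alkalinity).

    When ``consts`` is not supplied, the equilibrium constants are computed
    under ``activity_model`` with the ionic strength taken from the full
    recipe ion inventory, iterated once (ideal split -> I -> gamma -> final
    split; a further pass changes I by < 0.5% at these strengths).
    """
    if target_na_total <= FIXED_SODIUM:
        raise CarbonateError(
            f"total Na+ {target_na_total} M below the fixed-component sodium {FIXED_SODIUM:.4f} M"
        )

    phosphate_na = PHOSPHATE_NA_FRACTION * target_na_total if target_ph <= PHOSPHATE_PH_MAX else 0.0
    carbonate_na = target_na_total - FIXED_SODIUM - phosphate_na

    def assemble(c: EquilibriumConstants) -> MediumRecipe:
        nahco3, na2co3 = design_carbonate_buffer(target_ph, carbonate_na, c)
        nah2po4 = na2hpo4 = 0.0
        if phosphate_na > 0:
            nah2po4, na2hpo4 = _phosphate_split(target_ph, phosphate_na, c)
        warning = None
        if not (c.temperature and 7.5 <= target_ph <= 11.5):
            warning = "target pH outside the carbonate buffering range"
        return MediumRecipe(
            target_ph=target_ph,
            target_na_total=target_na_total,
            nahco3=nahco3,
            na2co3=na2co3,
            nah2po4=nah2po4,
            na2hpo4=na2hpo4,
            nacl=NACL,
            nh4cl=NH4CL,
            na2s=NA2S,
            na_acetate=NA_ACETATE,
            warning=warning,
        )

    if consts is not None:
        return assemble(consts)
    if activity_model == "ideal":
        return assemble(equilibrium_constants(temperature, 0.0, "ideal"))
    draft = assemble(equilibrium_constants(temperature, 0.0, "ideal"))
    ion_i = ionic_strength_of(draft)
    return assemble(equilibrium_constants(temperature, ion_i, "davies"))


def predict_buffer_ph(recipe: MediumRecipe, consts: EquilibriumConstants | None = None) -> CarbonateState:
    """Charge-balance pH of the carbonate/phosphate buffer alone.

    Mirrors the measured "buffer pH": the buffer salts plus NaCl, without
    acetate, ammonium or inoculum. When ``consts`` is omitted they are built
    with the Davies model at the recipe's ionic strength.
    """
    if consts is None:
        consts = equilibrium_constants(298.15, ionic_strength_of(recipe), "davies")
    buffer_na = recipe.carbonate_sodium + recipe.nah2po4 + 2.0 * recipe.na2hpo4
    charges = {"Na+": buffer_na + recipe.nacl, "Cl-": -recipe.nacl}
    return ph_from_composition(
        charges, recipe.total_carbonate, consts, total_phosphate=recipe.total_phosphate
    )


# ---------------------------------------------------------------------------
# study conditions and the printed recipe table (validation surface)
# ---------------------------------------------------------------------------

#: the 18 studied (alkalinity eq/L, initial pH) combinations; the 0.1 eq/L
#: group targets pH 10.5 instead of 10.0 because of its low buffering capacity
STUDY_CONDITIONS: tuple[tuple[float, float], ...] = (
    (0.1, 8.2), (0.1, 8.5), (0.1, 9.0), (0.1, 9.2), (0.1, 9.5), (0.1, 10.5),
    (0.6, 8.2), (0.6, 8.5), (0.6, 9.0), (0.6, 9.2), (0.6, 9.5), (0.6, 10.0),
    (1.2, 8.2), (1.2, 8.5), (1.2, 9.0), (1.2, 9.2), (1.2, 9.5), (1.2, 10.0),
)

#: published medium compositions (mol/L) for the same 18 combinations
_PRINTED_RECIPES_CSV = """\
alkalinity,ph,nahco3,na2co3,nah2po4,na2hpo4,nacl,nh4cl,na2s,na_acetate,final_na
0.1,8.2,0.019,0.000,2.98e-4,7.85e-3,0.05,0.005,2e-4,0.015,0.10
0.1,8.5,0.018,0.001,9.56e-5,7.95e-3,0.05,0.005,2e-4,0.015,0.10
0.1,9.0,0.029,0.003,0,0,0.05,0.005,2e-4,0.015,0.10
0.1,9.2,0.027,0.004,0,0,0.05,0.005,2e-4,0.015,0.10
0.1,9.5,0.021,0.007,0,0,0.05,0.005,2e-4,0.015,0.10
0.1,10.5,0.002,0.017,0,0,0.05,0.005,2e-4,0.015,0.10
0.6,8.2,0.429,0.004,0.002,0.047,0.05,0.005,2e-4,0.015,0.60
0.6,8.5,0.412,0.013,0.001,0.048,0.05,0.005,2e-4,0.015,0.60
0.6,9.0,0.445,0.044,0,0,0.05,0.005,2e-4,0.015,0.60
0.6,9.2,0.405,0.064,0,0,0.05,0.005,2e-4,0.015,0.60
0.6,9.5,0.327,0.103,0,0,0.05,0.005,2e-4,0.015,0.60
0.6,10.0,0.178,0.178,0,0,0.05,0.005,2e-4,0.015,0.60
1.2,8.2,0.924,0.009,0.004,0.094,0.05,0.005,2e-4,0.015,1.20
1.2,8.5,0.887,0.027,0.001,0.095,0.05,0.005,2e-4,0.015,1.20
1.2,9.0,0.945,0.094,0,0,0.05,0.005,2e-4,0.015,1.20
1.2,9.2,0.861,0.136,0,0,0.05,0.005,2e-4,0.015,1.20
1.2,9.5,0.694,0.220,0,0,0.05,0.005,2e-4,0.015,1.20
1.2,10.0,0.378,0.378,0,0,0.05,0.005,2e-4,0.015,1.20
"""


def printed_recipes() -> pd.DataFrame:
    """Published composition table as a DataFrame (mol/L)."""
    return pd.read_csv(StringIO(_PRINTED_RECIPES_CSV))


def printed_recipe(alkalinity: float, ph: float) -> MediumRecipe:
    """One published recipe as a MediumRecipe."""
    df = printed_recipes()
    row = df[(df.alkalinity == alkalinity) & (df.ph == ph)]
    if row.empty:
        raise KeyError(f"no published recipe for alkalinity {alkalinity}, pH {ph}")
    r = row.iloc[0]
    return MediumRecipe(
        target_ph=ph,
        target_na_total=float(r.final_na),
        nahco3=float(r.nahco3),
        na2co3=float(r.na2co3),
        nah2po4=float(r.nah2po4),
        na2hpo4=float(r.na2hpo4),
        nacl=float(r.nacl),
        nh4cl=float(r.nh4cl),
        na2s=float(r.na2s),
        na_acetate=float(r.na_acetate),
    )


def emit_recipe_table(
    conditions: tuple[tuple[float, float], ...] = STUDY_CONDITIONS,
    activity_model: str = "davies",
) -> pd.DataFrame:
    """Design every condition and audit the sodium balance of each row."""
    rows = []
    for alk, ph in conditions:
        recipe = build_medium(ph, alk, activity_model=activity_model)
        rows.append(
            {
                "alkalinity": alk,
                "ph": ph,
                "nahco3": recipe.nahco3,
                "na2co3": recipe.na2co3,
                "nah2po4": recipe.nah2po4,
                "na2hpo4": recipe.na2hpo4,
                "nacl": recipe.nacl,
                "nh4cl": recipe.nh4cl,
                "na2s": recipe.na2s,
                "na_acetate": recipe.na_acetate,
                "final_na": total_sodium(recipe),
            }
        )
    return pd.DataFrame(rows)


def compare_to_printed(activity_model: str = "davies") -> pd.DataFrame:
    """Designed vs published compositions, with relative errors.

    Na2CO3 entries printed as 0.000 cannot carry a relative error and get NaN.
    """
    designed = emit_recipe_table(activity_model=activity_model)
    printed = printed_recipes()
    merged = designed.merge(printed, on=["alkalinity", "ph"], suffixes=("_design", "_printed"))
    merged["nahco3_rel_err"] = merged.nahco3_design / merged.nahco3_printed - 1.0
    merged["na2co3_rel_err"] = (merged.na2co3_design / merged.na2co3_printed - 1.0).where(
        merged.na2co3_printed > 0
    )
    return merged
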