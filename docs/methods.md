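# Methods

## Carbonate system

The CO₂–H₂O system is modelled with the two dissociation steps
CO₂(aq)/HCO₃⁻ (pKa₁ 6.33) and HCO₃⁻/CO₃²⁻ (pKa₂ 10.33) at 25 °C, plus the
water ion product (pKw 14). No default temperature dependence of the
constants is applied; `EquilibriumConstants.with_vant_hoff` exposes a
van't Hoff correction for user-supplied reaction enthalpies. Speciation at
a given pH uses the closed-form DIC fractions; inversion from carbonate
alkalinity is algebraic (`DIC = (alk − [OH⁻] + [H⁺]) / (f₁ + 2f₂)`).

Non-ideality uses the Davies equation
`log₁₀γ = −0.509 z² (√I/(1+√I) − 0.3 I)`, valid to roughly I ≈ 0.5 mol/L
and rejected above 2 mol/L. pH is treated as a proton-activity
measurement: all equilibrium quotients are converted to conditional
(concentration) constants with `a_H = 10^−pH`, e.g.
`K'a2 = Ka2 γ₁/γ₂`. Phosphate (pKp 2.15 / 7.20 / 12.35) and acetate
(pKa 4.76) enter the charge balance as totals speciated at the trial pH.

pH solving is bracketed root finding (Brent) on the charge balance over
pH ∈ [2, 13] with machine-precision tolerance; the residual at the root is
below 10⁻¹⁰ eq/L. The titration simulator removes fixed positive charge in
user-chosen strong-acid increments, re-solves the pH after each increment
(closed system, no CO₂ loss), and interpolates linearly inside the final
increment; as the step size shrinks it converges to the exact
total-alkalinity difference between the start and endpoint states.

Concentrations are mol/L throughout; molality–molarity differences
(< 3% at these salinities) are ignored, as is NH₄⁺/NH₃ speciation in
charge balances (≤ 5 meq/L at 5 mM total ammonium).

## Medium design

A medium is defined by its target pH and total Na⁺ (operationally equal to
the alkalinity in eq/L). Fixed components — 50 mM NaCl, 5 mM NH₄Cl, 0.2 mM
Na₂S, 15 mM sodium acetate — lock 0.0654 M of sodium; media at pH ≤ 8.5
additionally allocate 16% of total sodium to a NaH₂PO₄/Na₂HPO₄ pair split
by the pH-7.2 equilibrium ratio. The remaining sodium is split between
NaHCO₃ and Na₂CO₃ with the ratio rule `r = [CO₃²⁻]/[HCO₃⁻] = K'a2·10^pH`,
`NaHCO₃ = Na_carb/(1+2r)`.

Buffer design defaults to the Davies model with ionic strength computed
from the full recipe ion inventory and iterated once (ideal split → I →
γ → final split); a second pass changes I by well under 0.5%. The ideal
model is retained for sensitivity analysis: it misplaces the
carbonate/bicarbonate split of every alkaline medium by a factor of ~2 in
the Na₂CO₃ term, while the Davies default tracks the published table with
~3% (NaHCO₃) and ~13% (Na₂CO₃) median error. Residual mismatches
concentrate in the rows with the smallest printed amounts (the pH 8.2 rows
and the pH 10.5 low-alkalinity row), whose printed splits are not
consistent with any single activity model we tried; the comparison table
(`medium_design.compare_to_printed`) reports them untouched. The ratio
rule ignores the CO₂(aq) share of DIC, so designed media re-solve to their
target pH within 0.05 units at pH ≥ 9 but only within ~0.15 at pH 8.2.

## Reaction energetics

The three catabolisms are stored as signed stoichiometry maps with their
standard energies at 298.15 K (−65.83, −140.82, +75 kJ/mol); element and
charge balance are enforced by tests, and the acetate-oxidation +
hydrogenotrophic sum reproduces the acetoclastic reaction with
ΔG⁰ = −65.82 kJ/mol (printed: −65.83, a rounding residue).

ΔG¹ = ΔG⁰ + RT Σ Yᵢ ln(γᵢcᵢ) with R = 8.314×10⁻³ kJ/mol/K. Conventions
where the source text is silent: water is excluded from the quotient
(activity 1), H⁺ enters as the activity 10^−pH, and all other γ default
to 1. "CO₂" means dissolved CO₂ only, taken from the ideal-activity
speciation at the given (alkalinity, pH). The stated 35 °C adjustment is
implemented as T = 308.15 K in the RT ln Q term while ΔG⁰ stays at its
298.15 K value; a Gibbs–Helmholtz shift of ΔG⁰ with user-supplied ΔH⁰ is
available and flagged in the landscape metadata, since which of the two
the study used cannot be determined. Initial concentrations are fixed at
15 mM acetate, 2.85 µM H₂ and 15 µM CH₄ (abiotic-control levels through
Henry's law). The default landscape grid is pH 6–10 at 0.05-unit
resolution (81 points) for alkalinities 0.1/0.6/1.2 eq/L.

On this grid acetoclastic methanogenesis is strictly the most exergonic
pathway at every node, hydrogenotrophic methanogenesis becomes more
favourable with alkalinity and less with pH, and acetate oxidation the
reverse — the orderings the batch community data are compared against.
Note that acetate oxidation is already exergonic at pH 6 under these
inputs (≈ −18 kJ/mol at 0.1 eq/L): the 2.85 µM dissolved H₂ is low enough
to pull the reaction forward everywhere on the grid, so feasibility
statements about oxidation rest on the orderings, not on a sign change.

## Bottle partitioning

The serum bottle is rigid (115 mL total, 65 mL liquid) and filled with
1 bar argon at the 35 °C incubation temperature; produced gas raises the
total pressure instead of venting, so moles are conserved exactly.
Converting x mol/L acetate adds x to DIC, x to CH₄ and x eq/L to carbonate
alkalinity regardless of route (the SAO + hydrogenotrophic chain nets to
the acetoclastic stoichiometry). The equilibrium has one unknown, the
final pH: at a trial pH the carbon balance fixes CO₂(aq) through the
Henry/ideal-gas partition, and Brent root finding drives the liquid charge
balance to zero. CH₄ and H₂ partition independently of pH.

Henry constants are 0.78 (H₂) and 1.4 (CH₄) mmol/(kg·bar) as stated;
CO₂ is needed but not stated and defaults to 29.4 mmol/(kg·bar), a 35 °C
textbook value, overridable. Biomass carbon is neglected (growth treated
as negligible). Predicted headspace compositions are abiotic equilibrium
endpoints without inoculum carryover, so only trend directions — CO₂
share falling with initial pH, rising with alkalinity, final pH below the
abiotic-equilibrium pH — are compared with the measured table, not the
percentages themselves.

## Rate estimation

Acetate uptake is modelled as linear to depletion; the rate is −slope of
an OLS fit in mM vs days. Samples on the post-depletion plateau are
excluded by a 0.5 mM cutoff refined iteratively: the final fit keeps the
samples taken before the *fitted line* crosses the cutoff, rather than
gating each point on its own noisy observation — observation gating
truncates the noise distribution at the boundary and biases the slope
low by about 1% under the default conditions. With the predicted-time
gate the estimator is unbiased to ~0.1% over 500 simulated series at
0.5 mM noise. A constant series returns rate 0 with R² = 0.

Contrasts mirror the study's two comparisons: percent change from the
lowest- to highest-pH rate per alkalinity, and the ratio of the 0.1 eq/L
mean rate to the mean of the 0.6/1.2 eq/L groups. Fed the published
rates (0.71/0.54, 0.23/0.15, 0.23/0.16 mmol/L/day) these give a ratio of
3.25 and a mean high-pH decrease of 29.7%.

## qPCR

Standard curves are OLS fits of Ct against log₁₀(copies) with duplicate
Ct values averaged first and no outlier rejection; efficiency is
10^(−1/slope) − 1, flagged outside [0.8, 1.1]. Quantification inverts the
fitted line; extrapolation is allowed. Relative abundance of the two
marker organisms is a/(a+b)·100 and fold changes compare the highest- to
the lowest-pH sample in a group, invariant to common rescaling.

## Synthetic data

Generators emulate measurement noise only: Gaussian noise on acetate (mM)
and on Ct (cycles), one seeded numpy Generator stream per call, fixed
seed ⇒ identical output. Defaults are the study conditions — 15 mM
initial acetate, 0.23 mmol/L/day true rate (the 0.6 eq/L scale, depleting
in ~65 days), 0.5 mM acetate noise, ten-ish samples over the incubation,
a −3.4/38 standard curve, 0.2-cycle Ct noise, duplicate reactions, and
10⁵ copies/reaction per sample. Batch bottles optionally carry pH and
headspace observations computed by pushing the noiseless conversion
through the bottle equilibrium. What the generators do *not* contain —
growth dynamics, community competition, inoculum carryover, drifting
rates, pipetting error structure — bounds what passing recovery tests
show: they validate the estimators under the assumed noise model, not the
biology.

A note on recovery tolerances: a 2·SE interval from a 6-point calibration
fit is a t-interval with 4 degrees of freedom (~88% nominal coverage),
so slope-recovery checks assert ≥80% coverage plus unbiasedness of the
mean slope rather than a per-seed 95% criterion.

## Problem sizes

Default test and driver sizes are chosen to keep every stage interactive:
81-point landscape grids, 200-seed recovery ensembles, 15-scenario
mass-balance sweeps and 25-seed fold-change ensembles. All are arguments,
not constants.
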