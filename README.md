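# methalk

Carbonate-system chemistry and bioenergetics of acetate-driven
methanogenesis in haloalkaline (soda-lake-type) media.

## The problem

At high pH, CO₂ speciates into bicarbonate and carbonate, which makes
alkaline solutions attractive carbon-capture absorbents — and makes the
fate of that captured carbon depend on which methanogenic catabolism wins.
Haloalkaliphilic communities fed acetate can route it either through
**acetoclastic methanogenesis**

CH₃COO⁻ + H⁺ → CO₂ + CH₄  (ΔG⁰ = −65.83 kJ/mol)

or through **syntrophic acetate oxidation** coupled to **hydrogenotrophic
methanogenesis**

CH₃COO⁻ + 2 H₂O + H⁺ → 4 H₂ + 2 CO₂  (ΔG⁰ = +75 kJ/mol)
4 H₂ + CO₂ → CH₄ + 2 H₂O  (ΔG⁰ = −140.82 kJ/mol)

This package implements the computational side of a batch study of that
competition across pH 8.2–10.5 and carbonate alkalinities of 0.1, 0.6 and
1.2 eq/L (where 1 eq/L alkalinity ≡ 1 M Na⁺):

* `carbonate_system` — CO₂–H₂O (± phosphate) speciation, DIC
  (`[CO₂(aq)] + [HCO₃⁻] + [CO₃²⁻]`), carbonate alkalinity
  (`[HCO₃⁻] + 2[CO₃²⁻] + [OH⁻] − [H⁺]`), charge-balance pH solving and
  simulated strong-acid titration, with Davies activity corrections;
* `medium_design` — NaHCO₃/Na₂CO₃ (and phosphate) buffer recipes for a
  target pH and total sodium, audited against the published composition
  table;
* `thermo_engine` — non-ideal reaction energies
  ΔG¹ = ΔG⁰ + RT Σᵢ Yᵢ ln(γᵢcᵢ) for the three catabolisms over pH ×
  alkalinity grids;
* `gas_partition` — Henry's-law partitioning and the closed serum-bottle
  (115 mL / 65 mL) mass balance coupling charge balance, carbon balance
  and headspace equilibria;
* `batch_analysis` — OLS acetate-consumption rates with plateau exclusion
  and the pH/alkalinity rate contrasts;
* `qpcr_quant` — qPCR standard curves, efficiency, absolute
  quantification and two-target fold changes;
* `synthetic_data` — seeded generators reproducing the statistical
  structure of the batch and qPCR measurements.

The numbered scripts under `analysis/` are thin drivers that run each
stage and write tables under `results/`.

## Worked example

```python
from methalk.medium_design import build_medium, total_sodium
from methalk.thermo_engine import ACETOCLASTIC, HYDROGENOTROPHIC, build_initial_conditions, delta_g1

recipe = build_medium(target_ph=9.0, target_na_total=0.6)
print(f"NaHCO3 {recipe.nahco3:.3f} M, Na2CO3 {recipe.na2co3:.3f} M, "
      f"total Na+ {total_sodium(recipe):.3f} M")

cond = build_initial_conditions(alkalinity=0.6, ph=9.0)
print(f"CO2(aq) {cond.co2aq:.2e} M")
print(f"dG1 acetoclastic     {delta_g1(ACETOCLASTIC, cond):6.1f} kJ/mol")
print(f"dG1 hydrogenotrophic {delta_g1(HYDROGENOTROPHIC, cond):6.1f} kJ/mol")
```

prints

```
NaHCO3 0.435 M, Na2CO3 0.050 M, total Na+ 0.600 M
CO2(aq) 1.17e-03 M
dG1 acetoclastic      -47.7 kJ/mol
dG1 hydrogenotrophic  -21.1 kJ/mol
```

i.e. a 0.6 eq/L pH-9 medium needs roughly a 9:1 NaHCO₃:Na₂CO₃ split, and
under the study's initial concentrations (15 mM acetate, 2.85 µM H₂,
15 µM CH₄, 35 °C) acetoclastic methanogenesis is the more exergonic route
at that point — as it is everywhere on the studied grid, even though the
community shifts towards hydrogenotrophic methanogens at high pH and
alkalinity.

Running the drivers in order reproduces the full analysis:

```sh
python analysis/01_design_media.py
python analysis/02_gibbs_landscape.py
python analysis/03_bottle_partitioning.py
python analysis/04_acetate_rates.py --seed 0
python analysis/05_qpcr_abundance.py --seed 0
```

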