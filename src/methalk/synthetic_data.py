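"""Seeded generators emulating the study's measurement structure.

The raw measurements behind the batch and qPCR analyses are not deposited,
so every analysis stage is exercised against synthetic data with the
statistical structure the analyses assume:

* batch time series: linear acetate depletion at study-scale rates
  (0.15-0.71 mmol/L/day) with Gaussian measurement noise, plus pH and
  headspace observations produced by pushing the converted acetate through
  the stoichiometric conversion and the closed-bottle equilibrium;
* qPCR: a log-linear dilution series and duplicate sample Ct values drawn
  from true relative abundances through the same standard curve, with
  Gaussian Ct noise.

Each generator consumes one seeded numpy Generator stream, so a fixed seed
reproduces the output exactly. The generators emulate measurement noise
only: no growth, community dynamics, or drifting rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .batch_analysis import BatchTimeSeries
from .carbonate_system import CarbonateError
from .gas_partition import BatchGeometry, HenryConstants, equilibrate_bottle
from .medium_design import MediumRecipe, build_medium
from .qpcr_quant import Calibration, DilutionSeries, ct_from_copies


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth and noise levels for the generators.

    Defaults are the study conditions: 15 mM initial acetate, a
    0.23 mmol/L/day consumption rate (the 0.6 eq/L scale), 0.5 mM acetate
    noise, Ct noise 0.2 cycles, and a standard curve with slope -3.4 and
    intercept 38 cycles.
    """

    seed: int = 0
    rate_true: float = 0.23  # mmol/L/day
    acetate_initial: float = 15.0  # mM
    noise_acetate_sd: float = 0.5  # mM
    sampling_times: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 64.1, 7.0)
    )  # days
    recipe: MediumRecipe | None = None
    # qPCR truth: (alkalinity, pH) -> hydrogenotrophic relative abundance fraction
    qpcr_truth: Mapping[tuple[float, float], float] = field(default_factory=dict)
    calibration_truth: tuple[float, float] = (-3.4, 38.0)  # (slope, intercept)
    noise_ct_sd: float = 0.2  # cycles
    total_copies: float = 1e5  # copies/reaction per sample, both targets summed

    def __post_init__(self) -> None:
        if min(self.noise_acetate_sd, self.noise_ct_sd) < 0:
            raise CarbonateError("noise SDs must be >= 0")


def simulate_batch(
    config: SyntheticConfig,
    geometry: BatchGeometry | None = None,
    henry: HenryConstants | None = None,
    observe_bottle: bool = True,
) -> BatchTimeSeries:
    """One synthetic batch bottle: noisy linear acetate decay plus, when
    ``observe_bottle`` is set, the pH and headspace composition implied by
    the stoichiometric conversion of the consumed acetate."""
    if config.rate_true <= 0:
        raise CarbonateError("rate_true must be > 0")
    rng = np.random.default_rng(config.seed)
    recipe = config.recipe or build_medium(9.0, 0.6)
    t = np.asarray(config.sampling_times, dtype=float)
    true_acetate = np.maximum(0.0, config.acetate_initial - config.rate_true * t)
    noise = rng.normal(0.0, config.noise_acetate_sd, size=t.shape) if config.noise_acetate_sd else 0.0
    observed = np.maximum(0.0, true_acetate + noise)

    ph = None
    headspace = None
    if observe_bottle:
        geometry = geometry or BatchGeometry()
        henry = henry or HenryConstants()
        ph_list, co2, ch4 = [], [], []
        for conc in true_acetate:
            converted = min(recipe.na_acetate, (config.acetate_initial - conc) * 1e-3)
            out = equilibrate_bottle(recipe, converted, geometry, henry)
            ph_list.append(out.final_ph)
            co2.append(out.measured_fractions["CO2"])
            ch4.append(out.measured_fractions["CH4"])
        ph = np.asarray(ph_list)
        headspace = {"CO2": np.asarray(co2), "CH4": np.asarray(ch4)}

    return BatchTimeSeries(
        condition_id=f"synthetic-seed{config.seed}",
        times=t,
        acetate=observed,
        ph=ph,
        headspace=headspace,
        truth={"rate": config.rate_true, "acetate_initial": config.acetate_initial},
    )


def simulate_qpcr(
    config: SyntheticConfig,
    dilution_copies: Sequence[float] = (1e7, 1e6, 1e5, 1e4, 1e3, 1e2),
    n_replicates: int = 2,
) -> tuple[DilutionSeries, list[dict]]:
    """Synthetic dilution series plus per-sample duplicate Ct values.

    Sample Ct values for the two targets are generated from the true
    relative abundances in ``config.qpcr_truth`` through the true standard
    curve; abundances of exactly 0 or 1 are rejected (the absent target has
    no defined Ct).
    """
    slope, intercept = config.calibration_truth
    if slope >= 0:
        raise CarbonateError("calibration_truth slope must be < 0")
    rng = np.random.default_rng(config.seed)
    cal_true = Calibration(slope=slope, intercept=intercept, r_squared=1.0, slope_se=0.0, n_points=0)

    copies = np.asarray(dilution_copies, dtype=float)
    reps = np.array(
        [
            [ct_from_copies(c, cal_true) + rng.normal(0.0, config.noise_ct_sd) for _ in range(n_replicates)]
            for c in copies
        ]
    )
    series = DilutionSeries(copies, reps.mean(axis=1))

    samples = []
    for condition, frac_hyd in config.qpcr_truth.items():
        if not (0.0 < frac_hyd < 1.0):
            raise CarbonateError(
                f"relative abundance for {condition} must be strictly inside (0, 1)"
            )
        true_copies = {
            "hydrogenotrophic": frac_hyd * config.total_copies,
            "acetoclastic": (1.0 - frac_hyd) * config.total_copies,
        }
        record: dict = {"condition": condition, "truth": dict(true_copies)}
        for target, n in true_copies.items():
            ct_true = ct_from_copies(n, cal_true)
            record[target] = [
                ct_true + rng.normal(0.0, config.noise_ct_sd) for _ in range(n_replicates)
            ]
        samples.append(record)
    return series, samples
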