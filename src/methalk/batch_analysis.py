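"""Acetate consumption rates from batch time series.

Acetate uptake in these batches is linear until depletion, so the rate is
the negative slope of an ordinary least-squares fit of acetate (mM) against
time (days), restricted to points above a depletion cutoff so the
post-depletion plateau does not flatten the fit. Rates are reported
positive for consumption. Contrast summaries mirror the study's two
comparisons: the percent change from the lowest- to the highest-pH rate
within each alkalinity group, and the ratio of the mean rate at 0.1 eq/L to
the mean over the higher alkalinities (0.6 and 1.2 eq/L).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .carbonate_system import CarbonateError

#: acetate concentrations at or below this are treated as depleted, mM
DEPLETION_CUTOFF = 0.5


@dataclass(frozen=True)
class BatchTimeSeries:
    """Timed acetate (and optional pH / headspace) observations for one bottle."""

    condition_id: str
    times: np.ndarray  # days
    acetate: np.ndarray  # mM
    ph: np.ndarray | None = None
    headspace: Mapping[str, np.ndarray] | None = None
    truth: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        acetate = np.asarray(self.acetate, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "acetate", acetate)
        if times.shape != acetate.shape:
            raise CarbonateError("times and acetate must have the same length")
        if np.any(np.diff(times) <= 0):
            raise CarbonateError("times must be strictly increasing")
        if np.any(acetate < 0):
            raise CarbonateError("acetate concentrations must be >= 0")


@dataclass(frozen=True)
class RateEstimate:
    """OLS acetate-consumption rate for one condition."""

    condition_id: str
    rate: float  # mmol/L/day, positive = consumption
    intercept: float  # mM
    r_squared: float
    standard_error: float
    n_points: int


def fit_rate(series: BatchTimeSeries, depletion_cutoff: float = DEPLETION_CUTOFF) -> RateEstimate:
    """Least-squares rate over the pre-depletion portion of the series.

    The plateau window is refined iteratively: an initial fit to the points
    observed above the cutoff predicts the depletion time, and the final fit
    keeps the samples taken before the fitted line crosses the cutoff.
    Gating on the *predicted* rather than the observed concentration keeps
    boundary samples from being censored by their own noise, which would
    bias the slope.
    """
    mask = series.acetate > depletion_cutoff
    if mask.sum() < 2:
        raise CarbonateError(
            f"{series.condition_id}: fewer than 2 points above the {depletion_cutoff} mM cutoff"
        )

    def ols(m):
        t, a = series.times[m], series.acetate[m]
        if np.allclose(a, a[0]):
            return RateEstimate(series.condition_id, 0.0, float(a[0]), 0.0, 0.0, int(t.size))
        res = stats.linregress(t, a)
        return RateEstimate(
            condition_id=series.condition_id,
            rate=-res.slope,
            intercept=res.intercept,
            r_squared=res.rvalue**2,
            standard_error=res.stderr,
            n_points=int(t.size),
        )

    est = ols(mask)
    for _ in range(10):
        if est.rate <= 0:
            break
        t_cut = (est.intercept - depletion_cutoff) / est.rate
        refined = series.times <= t_cut
        if refined.sum() < 2 or np.array_equal(refined, mask):
            break
        mask = refined
        est = ols(mask)
    return est


def summarize_contrasts(
    estimates: Sequence[RateEstimate],
    groups: Mapping[str, tuple[float, float]],
) -> dict:
    """Rate contrasts across pH and alkalinity.

    ``groups`` maps each estimate's condition_id to its (alkalinity, pH).
    Returns a per-alkalinity table with the percent change from the
    lowest-pH to the highest-pH rate, plus the cross-alkalinity ratio of
    mean rates (0.1 eq/L over the mean of the 0.6 and 1.2 eq/L groups when
    present, otherwise over all other alkalinities).
    """
    records = []
    for est in estimates:
        if est.condition_id not in groups:
            raise CarbonateError(f"no group assignment for {est.condition_id}")
        alk, ph = groups[est.condition_id]
        records.append({"alkalinity": alk, "ph": ph, "rate": est.rate})
    df = pd.DataFrame(records)
    per_alk = []
    for alk, sub in df.groupby("alkalinity"):
        sub = sub.sort_values("ph")
        low, high = sub.iloc[0], sub.iloc[-1]
        change = np.nan if low.rate == 0 else 100.0 * (high.rate - low.rate) / low.rate
        per_alk.append(
            {
                "alkalinity": alk,
                "rate_low_ph": low.rate,
                "rate_high_ph": high.rate,
                "percent_change": change,
                "mean_rate": sub.rate.mean(),
            }
        )
    table = pd.DataFrame(per_alk)
    low_alk = table.alkalinity.min()
    ref = table[table.alkalinity.isin((0.6, 1.2))]
    if ref.empty:
        ref = table[table.alkalinity != low_alk]
    ratio = np.nan
    if not ref.empty and ref.mean_rate.mean() > 0:
        ratio = float(table.loc[table.alkalinity == low_alk, "mean_rate"].iloc[0] / ref.mean_rate.mean())
    return {"per_alkalinity": table, "low_vs_high_alkalinity_ratio": ratio}


# ---------------------------------------------------------------------------
# published batch observations (validation surface for trends, not targets)
# ---------------------------------------------------------------------------

#: unambiguous published acetate consumption rates (mmol/L/day): two per
#: alkalinity group, for the lower-pH and higher-pH sub-ranges
PRINTED_RATES: dict[float, tuple[float, float]] = {
    0.1: (0.71, 0.54),
    0.6: (0.23, 0.15),
    1.2: (0.23, 0.16),
}

#: published per-condition observations: (alkalinity, initial pH) ->
#: (final pH, headspace CO2 %, headspace CH4 %, incubation days)
PRINTED_BATCH_OBSERVATIONS: dict[tuple[float, float], tuple[float, float, float, int]] = {
    (0.1, 8.40): (8.72, 3.93, 95.91, 23),
    (0.1, 9.01): (8.92, 4.19, 95.63, 23),
    (0.1, 9.15): (9.01, 2.89, 96.96, 23),
    (0.1, 9.40): (9.13, 2.21, 97.62, 23),
    (0.1, 9.87): (9.43, 1.87, 98.97, 30),
    (0.1, 10.35): (9.77, 1.49, 98.26, 30),
    (0.6, 8.41): (8.41, 50.28, 49.63, 76),
    (0.6, 8.64): (8.59, 29.85, 70.03, 64),
    (0.6, 8.99): (8.94, 18.45, 81.41, 64),
    (0.6, 9.17): (9.13, 9.96, 89.89, 64),
    (0.6, 9.45): (9.38, 5.58, 94.26, 64),
    (0.6, 10.00): (9.86, 1.45, 98.38, 103),
    (1.2, 8.26): (8.24, 49.30, 50.62, 68),
    (1.2, 8.63): (8.60, 34.25, 65.64, 75),
    (1.2, 8.81): (8.80, 20.58, 79.28, 75),
    (1.2, 9.10): (9.08, 13.96, 85.89, 92),
    (1.2, 9.68): (9.62, 2.06, 97.76, 114),
}
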