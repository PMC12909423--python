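"""qPCR standard-curve calibration and two-target abundance analysis.

Absolute quantification by qPCR rests on the log-linear relation between
template copy number and the cycle threshold Ct:

    Ct = slope * log10(copies) + intercept,   slope < 0,

fitted to a serial-dilution standard curve. The amplification efficiency
follows from the slope as 10^(-1/slope) - 1 (a perfect doubling per cycle
gives slope -3.3219 and efficiency 1). Sample Ct values are inverted
through the fitted line; the two targets here are the marker organisms of
the competing catabolisms (a hydrogenotrophic and an acetoclastic
methanogen), summarised as relative abundances and fold changes across a
pH series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .carbonate_system import CarbonateError

#: slope of a perfectly efficient (doubling) standard curve
PERFECT_SLOPE = -1.0 / np.log10(2.0)


@dataclass(frozen=True)
class DilutionSeries:
    """Known copy numbers with replicate-averaged Ct values."""

    known_copies: np.ndarray  # copies/reaction, log-spaced
    ct_values: np.ndarray  # cycles

    def __post_init__(self) -> None:
        copies = np.asarray(self.known_copies, dtype=float)
        cts = np.asarray(self.ct_values, dtype=float)
        object.__setattr__(self, "known_copies", copies)
        object.__setattr__(self, "ct_values", cts)
        if copies.shape != cts.shape or copies.size < 3:
            raise CarbonateError("need >= 3 matched (copies, Ct) points")
        if np.any(copies <= 0):
            raise CarbonateError("copy numbers must be > 0")

    @classmethod
    def from_replicates(cls, known_copies: Sequence[float], ct_replicates: Sequence[Sequence[float]]) -> "DilutionSeries":
        """Average duplicate Ct measurements per dilution before fitting."""
        cts = np.asarray([np.mean(rep) for rep in ct_replicates], dtype=float)
        return cls(np.asarray(known_copies, dtype=float), cts)


@dataclass(frozen=True)
class Calibration:
    """Fitted standard curve."""

    slope: float  # cycles per log10(copies)
    intercept: float  # cycles at 1 copy
    r_squared: float
    slope_se: float
    n_points: int

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification factor minus 1: 10^(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def efficiency_ok(self) -> bool:
        return 0.8 <= self.efficiency <= 1.1


def calibrate(series: DilutionSeries) -> Calibration:
    """Least-squares Ct vs log10(copies)."""
    res = stats.linregress(np.log10(series.known_copies), series.ct_values)
    if res.slope >= 0:
        raise CarbonateError(f"calibration failed: non-negative slope {res.slope:.3f}")
    return Calibration(
        slope=res.slope,
        intercept=res.intercept,
        r_squared=res.rvalue**2,
        slope_se=res.stderr,
        n_points=int(series.known_copies.size),
    )


def ct_from_copies(copies: float, cal: Calibration) -> float:
    """Forward evaluation of the standard curve."""
    if copies <= 0:
        raise CarbonateError("copies must be > 0")
    return cal.slope * np.log10(copies) + cal.intercept


def copies_from_ct(ct: float, cal: Calibration) -> float:
    """Invert the standard curve: copies = 10^((intercept - ct) / (-slope))."""
    return 10.0 ** ((cal.intercept - ct) / -cal.slope)


@dataclass(frozen=True)
class AbundancePair:
    """Copy numbers of the two marker organisms in one sample."""

    copies_hydrogenotrophic: float
    copies_acetoclastic: float
    condition: tuple[float, float] | None = None  # (alkalinity, pH)


def relative_abundance(pair: AbundancePair) -> dict[str, float]:
    """Percent of each target among the two; sums to 100."""
    total = pair.copies_hydrogenotrophic + pair.copies_acetoclastic
    if total <= 0:
        raise CarbonateError("undefined abundance: zero total copies")
    return {
        "hydrogenotrophic": 100.0 * pair.copies_hydrogenotrophic / total,
        "acetoclastic": 100.0 * pair.copies_acetoclastic / total,
    }


def fold_change(pairs: Sequence[AbundancePair], target: str = "hydrogenotrophic") -> float:
    """Relative-abundance fold change from the first to the last pair.

    ``pairs`` must be ordered by pH within one alkalinity group; the fold is
    the target's relative abundance at the highest pH over the lowest.
    """
    if len(pairs) < 2:
        raise CarbonateError("need at least two samples for a fold change")
    first = relative_abundance(pairs[0])[target]
    last = relative_abundance(pairs[-1])[target]
    if first <= 0:
        raise CarbonateError("undefined fold change: zero abundance at the lowest pH")
    return last / first
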