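"""Fellow-eye conversion model.

Among patients presenting with unilateral NVAMD, the fellow eye converts
over time.  Years 1-2 come from observed cumulative conversion of the
baseline-unilateral pool (21.2 % and 38.0 % in the base case); years 3
onward extend the series by a last-observation-carried-forward hazard equal
to the mean of the year-1 and year-2 incremental conversions (19.0 %/year),
applied each year to the not-yet-converted remainder.  Bilateral involvement
of the whole cohort is then B = baseline_bilateral + unilateral_share x A,
with A the cumulative incremental conversion percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParameters

__all__ = [
    "ConversionTrajectory",
    "extend_cumulative_conversion",
    "bilateral_involvement",
    "trajectory_from_params",
    "conversion_year_distribution",
]


@dataclass(frozen=True)
class ConversionTrajectory:
    """Year-indexed conversion series (percent scale, year 0 = baseline)."""

    years: np.ndarray
    cumulative_incremental: np.ndarray
    bilateral_involvement: np.ndarray
    annual_hazard_used: float
    baseline_bilateral_pct: float
    unilateral_share: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "cumulative_incremental": self.cumulative_incremental,
                "bilateral_involvement": self.bilateral_involvement,
            }
        )

    def cumulative_at(self, year: int) -> float:
        return float(self.cumulative_incremental[year])

    def bilateral_at(self, year: int) -> float:
        return float(self.bilateral_involvement[year])


def bilateral_involvement(
    cumulative_incremental: float,
    baseline_bilateral_pct: float = 46.4,
    unilateral_share: float = 0.535,
) -> float:
    """Percent of all cases bilateral given cumulative fellow-eye conversion A."""
    if not 0.0 <= cumulative_incremental <= 100.0:
        raise ValueError(f"cumulative conversion {cumulative_incremental} outside [0, 100]")
    return min(100.0, baseline_bilateral_pct + cumulative_incremental * unilateral_share)


def extend_cumulative_conversion(
    year1_cum: float,
    year2_cum: float,
    horizon: int = 12,
    baseline_bilateral_pct: float = 46.4,
    unilateral_share: float = 0.535,
) -> ConversionTrajectory:
    """Extend observed year-1/year-2 cumulative conversion to ``horizon`` years.

    For t >= 3, cumulative(t) = cumulative(t-1) + h x (100 - cumulative(t-1))
    where h is the mean of the two observed incremental conversions expressed
    as a fraction of the baseline-unilateral pool.
    """
    if horizon < 2:
        raise ValueError("horizon must cover at least the two observed years")
    if not (0.0 <= year1_cum <= year2_cum <= 100.0):
        raise ValueError(
            f"observed cumulative conversions ({year1_cum}, {year2_cum}) must be "
            "non-decreasing and within [0, 100]"
        )
    hazard = ((year1_cum - 0.0) + (year2_cum - year1_cum)) / 2.0 / 100.0

    cum = np.empty(horizon + 1)
    cum[0] = 0.0
    cum[1] = year1_cum
    cum[2] = year2_cum
    for t in range(3, horizon + 1):
        cum[t] = cum[t - 1] + hazard * (100.0 - cum[t - 1])

    bil = np.array(
        [bilateral_involvement(a, baseline_bilateral_pct, unilateral_share) for a in cum]
    )
    return ConversionTrajectory(
        years=np.arange(horizon + 1),
        cumulative_incremental=cum,
        bilateral_involvement=bil,
        annual_hazard_used=hazard,
        baseline_bilateral_pct=baseline_bilateral_pct,
        unilateral_share=unilateral_share,
    )


def trajectory_from_params(p: ModelParameters) -> ConversionTrajectory:
    return extend_cumulative_conversion(
        p.conversion_year1_cum_pct,
        p.conversion_year2_cum_pct,
        horizon=p.timeline_years,
        baseline_bilateral_pct=p.baseline_bilateral_pct,
        unilateral_share=p.unilateral_share,
    )


def conversion_year_distribution(traj: ConversionTrajectory) -> np.ndarray:
    """Per-year conversion probabilities for a baseline-unilateral case.

    Returns an array of length horizon+1: entries 1..horizon are the
    incremental conversion fractions for each year, the final implicit
    remainder (no conversion within the horizon) is 1 - sum.  Entry 0 is 0
    (baseline-unilateral by construction).
    """
    inc = np.diff(traj.cumulative_incremental, prepend=0.0) / 100.0
    inc[0] = 0.0
    return inc
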