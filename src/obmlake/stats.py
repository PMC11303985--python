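"""Variability decomposition and seasonal food-web metrics.

Two complementary coefficients of variation separate the character of
multi-year dynamics:

* the *within-year* CV is the CV over the 365 days of the mean annual cycle
  (climatology) -- seasonal amplitude;
* the *between-year* CV is the CV of the annual means -- multiyear cycling
  or drift.

A stable seasonally forced ecosystem shows a large within-year CV and a
between-year CV near zero.

Conventions (frozen by tests): the climatology CV uses the population
standard deviation (n denominator, the 365 days are the whole population of
the average year); the between-year CV uses the sample standard deviation
(n-1).  "August" is days 213-243 of the 365-day year and "summer" is days
121-274 (1 May - 1 Oct).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioResult",
    "within_year_cv",
    "between_year_cv",
    "scenario_metrics",
    "AUGUST_DAYS",
    "SUMMER_DAYS",
]

DAYS_PER_YEAR = 365
AUGUST_DAYS = (213, 243)   # inclusive day-of-year window
SUMMER_DAYS = (121, 274)   # 1 May - 1 Oct


@dataclass
class ScenarioResult:
    """Daily output of one simulation plus the analysis window.

    ``series`` holds one row per day with at least columns ``time`` (days
    since start), ``day_of_year`` and ``year`` plus one column per state
    variable.  ``analysis`` is the slice of whole years used for statistics
    (by default the last half of the run).
    """

    series: pd.DataFrame
    analysis_start_year: int
    meta: dict

    @property
    def analysis(self) -> pd.DataFrame:
        return self.series[self.series["year"] >= self.analysis_start_year]


def _whole_years(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    n_years, rem = divmod(values.size, DAYS_PER_YEAR)
    if n_years < 1 or rem != 0:
        raise ValueError(
            f"series length {values.size} is not a positive multiple of {DAYS_PER_YEAR}"
        )
    return values.reshape(n_years, DAYS_PER_YEAR)


def within_year_cv(values) -> float:
    """CV across the days of the average annual cycle.

    The daily climatology is the mean over years for each of the 365
    day-of-year positions; the result is its population sd over its mean.
    """
    years = _whole_years(values)
    clim = years.mean(axis=0)
    mean = clim.mean()
    if mean == 0.0:
        raise ValueError("zero-mean series: CV undefined")
    return float(clim.std(ddof=0) / mean)


def between_year_cv(values) -> float:
    """CV of the annual means (sample sd, n-1 denominator); needs >= 2 years."""
    years = _whole_years(values)
    if years.shape[0] < 2:
        raise ValueError("between-year CV needs at least 2 whole years")
    annual = years.mean(axis=1)
    mean = annual.mean()
    if mean == 0.0:
        raise ValueError("zero-mean series: CV undefined")
    return float(annual.std(ddof=1) / mean)


def scenario_metrics(
    result: ScenarioResult, chlorophyll_per_biomass: float = 1.0
) -> pd.DataFrame:
    """Seasonal food-web metrics over the analysis window.

    Returns one row per metric:

    * ``august_omnivore_biomass`` -- mean August omnivorous-fish biomass
      (g m^-3); any cross-configuration normalization is the caller's job;
    * ``august_predator_fraction`` -- August-mean predator biomass over
      August-mean total fish biomass (0 when both fish pools are empty);
    * ``summer_zoo_phyto_ratio`` -- summer-mean zooplankton over
      summer-mean phytoplankton biomass (ratios are taken of window means,
      which keeps days when the denominator pool washes out from dominating);
    * ``summer_chlorophyll`` -- mean summer phytoplankton biomass times the
      chlorophyll conversion factor (a pigment proxy, not a pigment model).
    """
    df = result.analysis
    if df.empty:
        raise ValueError("empty analysis window")
    august = df[df["day_of_year"].between(*AUGUST_DAYS)]
    summer = df[df["day_of_year"].between(*SUMMER_DAYS)]
    if august.empty or summer.empty:
        raise ValueError("analysis window does not cover the seasonal metric windows")

    omni = float(august["omnivore"].mean())
    pred = float(august["predator"].mean())
    pred_frac = pred / (omni + pred) if omni + pred > 0.0 else 0.0
    phyto = float(summer["phytoplankton"].mean())
    zp = float(summer["zooplankton"].mean()) / phyto if phyto > 0.0 else np.nan

    rows = [
        ("august_omnivore_biomass", omni),
        ("august_predator_fraction", pred_frac),
        ("summer_zoo_phyto_ratio", zp),
        ("summer_chlorophyll", phyto * chlorophyll_per_biomass),
    ]
    return pd.DataFrame(rows, columns=["metric", "value"])
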