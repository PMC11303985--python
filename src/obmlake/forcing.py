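"""Synthetic seasonal forcing: temperature, light and nutrient load.

A looped, strictly periodic 365-day annual cycle (no leap days, no weather
stochasticity) so that multi-year simulations contain no interannual
environmental variability -- any between-year variation in the ecosystem is
then generated by the food-web dynamics themselves.  Each channel is an
independent sinusoid, optionally floor-clamped at a physical limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ChannelParams", "ForcingParams", "ForcingSample", "seasonal_forcing", "annual_table"]

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class ChannelParams:
    """One sinusoidal channel: mean + amplitude * sin(2*pi*(day - phase)/365)."""

    mean: float
    amplitude: float = 0.0
    phase: float = 0.0
    floor: float | None = None

    def value(self, day: int | float) -> float:
        v = self.mean + self.amplitude * math.sin(
            2.0 * math.pi * (day - self.phase) / DAYS_PER_YEAR
        )
        if self.floor is not None:
            v = max(v, self.floor)
        return v


@dataclass(frozen=True)
class ForcingParams:
    """Annual-cycle parameters for the three forcing channels.

    Defaults emulate a temperate, eutrophic lake: water temperature cycling
    between ~2 and ~20 degC peaking in late July, a light factor in [0, 1]
    peaking at the summer solstice, and a nutrient load peaking in spring.
    """

    temperature: ChannelParams = field(
        default_factory=lambda: ChannelParams(mean=11.0, amplitude=9.0, phase=113.0, floor=0.0)
    )
    light: ChannelParams = field(
        default_factory=lambda: ChannelParams(mean=0.5, amplitude=0.45, phase=81.0, floor=0.0)
    )
    load: ChannelParams = field(
        default_factory=lambda: ChannelParams(mean=2e-4, amplitude=1e-4, phase=20.0, floor=0.0)
    )


@dataclass(frozen=True)
class ForcingSample:
    """Forcing values on one day of the annual cycle."""

    day_of_year: int
    temperature: float
    light_factor: float
    nutrient_load: float


def seasonal_forcing(
    day: int, params: ForcingParams | None = None, load_scale: float = 1.0
) -> ForcingSample:
    """Forcing on ``day`` of the looped year (1-based, in [1, 365]).

    ``load_scale`` multiplies the nutrient-load channel only; the scenario
    ladder uses scales {0.25, 0.5, 1, 2, 4} of the baseline load.
    """
    if not 1 <= day <= DAYS_PER_YEAR:
        raise ValueError(f"day must be in [1, {DAYS_PER_YEAR}], got {day}")
    if load_scale <= 0.0:
        raise ValueError(f"load_scale must be > 0, got {load_scale}")
    p = params or ForcingParams()
    light = min(max(p.light.value(day), 0.0), 1.0)
    return ForcingSample(
        day_of_year=day,
        temperature=p.temperature.value(day),
        light_factor=light,
        nutrient_load=p.load.value(day) * load_scale,
    )


def annual_table(params: ForcingParams | None = None, load_scale: float = 1.0) -> pd.DataFrame:
    """The full 365-day cycle as a DataFrame (used by the simulator loop)."""
    days = np.arange(1, DAYS_PER_YEAR + 1)
    samples = [seasonal_forcing(int(d), params, load_scale) for d in days]
    return pd.DataFrame(
        {
            "day_of_year": days,
            "temperature": [s.temperature for s in samples],
            "light_factor": [s.light_factor for s in samples],
            "nutrient_load": [s.nutrient_load for s in samples],
        }
    )
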