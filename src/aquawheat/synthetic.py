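"""Seeded generators: Beijing-like weather, irrigation scenarios, noisy observations.

The weather generator emulates the continental climate of the reference
site statistically: a sinusoidal annual temperature cycle peaking at a
summer mean Tmax of 26.1 C and bottoming at a winter mean Tmin of
-4.7 C, day-to-day anomalies, seasonally weighted stochastic rain days,
and humidity/wind/sunshine drawn around station-plausible values.  Rain
depths inside the sowing-to-harvest window are rescaled multiplicatively
so the window total hits the configured seasonal target exactly (199,
208, 145 and 168 mm for the four reference seasons), which makes
downstream water-budget arithmetic deterministic in total input.

All generators are pure functions of (spec, seed).  They do not attempt
Markov rain-spell structure or interannual teleconnections; they exist
to exercise the simulator, not to reproduce the station record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import (IRRIGATION_SCHEDULES, PLANTING_DATES, SEASON_RAINFALL_MM,
                       SEASONS, irrigation_schedule)
from .simulate import SeasonResult
from .weather import WeatherDay, WeatherSeries

_PEAK_DOY = 196  # mid-July: warmest day of the climatological cycle


class SyntheticError(ValueError):
    """Infeasible generator specification."""


@dataclass
class ClimateSpec:
    """Statistical targets of the synthetic site climate.

    Latitude/elevation defaults are Beijing-plausible values for the
    Xiaotangshan area and feed the reference-ET computation.
    """

    summer_tmax: float = 26.1       # climatological July mean Tmax, C
    winter_tmin: float = -4.7       # climatological January mean Tmin, C
    diurnal_range: float = 10.0     # mean Tmax - Tmin, C
    temp_noise_sd: float = 2.0      # day-to-day anomaly SD, C
    rain_day_freq: float = 0.15     # base probability of a rain day
    mean_rain_depth: float = 6.0    # mean depth of a rain event, mm
    annual_rain_mm: float = 650.0   # full-year scale (outside the season window)
    season_rain_mm: dict = field(
        default_factory=lambda: dict(SEASON_RAINFALL_MM))
    latitude: float = 40.18
    elevation: float = 36.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.season_rain_mm.values()):
            raise SyntheticError("seasonal rainfall targets must be >= 0")
        if not 0.0 < self.rain_day_freq < 1.0:
            raise SyntheticError("rain_day_freq must lie in (0, 1)")


@dataclass
class ObservationSpec:
    """Sampling plan and noise for pseudo-observations of a simulated season."""

    days: Sequence[int]             # days after sowing
    cc_noise_sd: float = 5.0        # % cover
    biomass_noise_sd: float = 500.0  # kg ha-1

    def __post_init__(self) -> None:
        if self.cc_noise_sd < 0 or self.biomass_noise_sd < 0:
            raise SyntheticError("noise SDs must be >= 0")


def _annual_cycle(doy: np.ndarray, summer: float, winter: float) -> np.ndarray:
    mid = (summer + winter) / 2.0
    amp = (summer - winter) / 2.0
    return mid + amp * np.cos(2.0 * math.pi * (doy - _PEAK_DOY) / 365.25)


def gen_weather(spec: ClimateSpec, season: str, seed: int,
                planting_date: Optional[Date] = None,
                start: Optional[Date] = None,
                end: Optional[Date] = None) -> WeatherSeries:
    """Generate one season of daily weather (default: Sep 1 to Jul 31).

    ``season`` is the sowing year ("2008".."2011"); the sowing-to-harvest
    window (sowing + 250 days) is rescaled to the season's rainfall
    target.  Identical (spec, season, seed) give an identical series.
    """
    if season not in SEASONS:
        raise SyntheticError(f"unknown season {season!r}; choose from {SEASONS}")
    year = int(season)
    start = start or Date(year, 9, 1)
    end = end or Date(year + 1, 7, 31)
    planting = planting_date or PLANTING_DATES[season][0]
    harvest = planting + timedelta(days=250)

    n = (end - start).days + 1
    dates = [start + timedelta(days=i) for i in range(n)]
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    rng = np.random.default_rng(seed)

    # temperature: shared anomaly preserves tmax >= tmin by construction
    tmax_clim = _annual_cycle(doy, spec.summer_tmax,
                              spec.winter_tmin + spec.diurnal_range)
    anomaly = rng.normal(0.0, spec.temp_noise_sd, n)
    rng_jitter = np.clip(spec.diurnal_range * (1.0 + 0.2 * rng.normal(size=n)),
                         2.0, None)
    tmax = tmax_clim + anomaly
    tmin = tmax - rng_jitter

    # humidity, wind, sunshine around station-plausible values
    rh = np.clip(60.0 + 15.0 * np.cos(2 * math.pi * (doy - _PEAK_DOY) / 365.25)
                 + rng.normal(0.0, 8.0, n), 20.0, 95.0)
    wind = np.clip(rng.gamma(2.0, 1.1, n), 0.3, 9.0)
    sunshine = np.clip(rng.normal(7.2, 2.5, n), 0.0, 13.0)

    # seasonally weighted rain occurrence, exponential depths
    summer_weight = 0.6 + 0.8 * (1.0 + np.cos(2 * math.pi * (doy - _PEAK_DOY) / 365.25)) / 2.0
    p_rain = np.clip(spec.rain_day_freq * summer_weight, 0.0, 0.95)
    is_rain = rng.random(n) < p_rain
    rain = np.where(is_rain, rng.exponential(spec.mean_rain_depth, n), 0.0)

    # rescale the sowing-to-harvest window to the configured seasonal total
    target = spec.season_rain_mm.get(season)
    if target is not None:
        window = np.array([planting <= d <= harvest for d in dates])
        current = float(rain[window].sum())
        if current == 0.0 and target > 0:
            raise SyntheticError(
                f"no rain days fell in the {season} season window; "
                "cannot rescale to a positive target")
        if current > 0:
            rain[window] *= target / current

    days = [WeatherDay(date=d, tmax=float(tmax[i]), tmin=float(tmin[i]),
                       rh_mean=float(rh[i]), wind2=float(wind[i]),
                       sunshine=float(sunshine[i]), rain=float(rain[i]))
            for i, d in enumerate(dates)]
    return WeatherSeries(days, spec.latitude, spec.elevation)


def gen_irrigation(template: str = "custom",
                   events: Optional[Sequence[tuple[Date, float]]] = None
                   ) -> list[tuple[Date, float]]:
    """Return an irrigation schedule: a published season template or a custom list.

    Templates "2008".."2011" reproduce the applied schedules of the
    reference trials exactly (e.g. "2008": 75 + 68 + 68 + 68 = 279 mm);
    "custom" returns ``events`` as given (empty = rainfed).
    """
    if template == "custom":
        return list(events or [])
    if template in IRRIGATION_SCHEDULES:
        return irrigation_schedule(template)
    raise SyntheticError(
        f"unknown irrigation template {template!r}; choose from "
        f"{SEASONS + ('custom',)}")


def gen_observations(truth: SeasonResult, spec: ObservationSpec,
                     seed: int) -> pd.DataFrame:
    """Noisy pseudo-observations of canopy cover and biomass from a simulated season.

    Gaussian noise is added independently per sampling day; cover
    observations are truncated to [0, 100] %.  With zero noise SDs the
    truth is returned exactly.
    """
    n_days = len(truth.daily)
    days = np.asarray(spec.days, dtype=int)
    if days.size and (days.min() < 0 or days.max() >= n_days):
        raise SyntheticError(
            f"sampling days outside the simulated season [0, {n_days - 1}]")
    rng = np.random.default_rng(seed)
    cc_true = truth.daily["cc"].to_numpy()[days] * 100.0
    b_true = truth.daily["biomass_kg_ha"].to_numpy()[days]
    cc_obs = np.clip(cc_true + rng.normal(0.0, spec.cc_noise_sd, days.size)
                     if spec.cc_noise_sd > 0 else cc_true, 0.0, 100.0)
    b_obs = np.maximum(b_true + rng.normal(0.0, spec.biomass_noise_sd, days.size)
                       if spec.biomass_noise_sd > 0 else b_true, 0.0)
    dates = [truth.daily["date"].iloc[int(d)] for d in days]
    return pd.DataFrame({"day": days, "date": dates,
                         "cc_pct": cc_obs, "biomass_kg_ha": b_obs})
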