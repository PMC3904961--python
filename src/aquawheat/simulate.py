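"""Season driver: couple weather, soil water, canopy and production; calibrate.

:func:`run_season` advances one sowing-to-maturity season a day at a
time.  Each day it (1) looks up weather and reference ET, (2) updates the
root zone and the depletion fraction p = Dr/TAW, (3) evaluates the three
water-stress coefficients (leaf expansion, stomatal closure, early
senescence), (4) advances the canopy, (5) computes transpiration demand
and runs the soil water balance, and (6) accumulates biomass and harvest
index.  The run is deterministic: identical configuration gives a
bit-identical result.

:func:`calibrate` fits selected crop parameters to observed canopy-cover
(and optionally biomass) series by bounded derivative-free minimisation
of the aggregate RMSE.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from datetime import date as Date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import canopy as cn
from . import production as pr
from . import soil_water as sw
from .params import CropParams, ParameterError
from .weather import WeatherSeries, WeatherError

log = logging.getLogger(__name__)

CALIBRATABLE = ("cgc", "cdc", "p_sen", "p_exp_upper", "cc0", "hi0")


class SimulationError(ValueError):
    """Invalid scenario configuration."""


@dataclass
class ScenarioConfig:
    """Everything one season needs: weather, soil, crop, schedule, options.

    The initial soil water condition defaults to field capacity through
    the whole profile (the reference trials sowed into a profile at
    maximum field capacity).  ``hold_at_field_capacity`` reruns the
    season with the soil reset to FC after every day — a no-stress mode
    used for analytic cross-checks.
    """

    planting_date: Date
    weather: WeatherSeries
    soil: sw.SoilProfile
    crop: CropParams = field(default_factory=CropParams)
    irrigation: Sequence[tuple[Date, float]] = ()
    initial_water: float = 1.0        # initial plant-available water fraction (1 = FC)
    hold_at_field_capacity: bool = False
    name: str = "season"

    def __post_init__(self) -> None:
        end = self.planting_date + timedelta(days=self.crop.maturity_day)
        for d, mm in self.irrigation:
            if mm <= 0:
                raise SimulationError(f"irrigation amount must be positive on {d}")
            if not self.planting_date <= d <= end:
                raise SimulationError(f"irrigation date {d} outside the season")
        if self.soil.depth + 1e-9 < self.crop.zr_max:
            raise SimulationError("soil profile shallower than maximum root depth")


@dataclass
class SeasonTotals:
    """Season-aggregate water fluxes and production."""

    transpiration_mm: float
    evaporation_mm: float
    runoff_mm: float
    percolation_mm: float
    rain_mm: float
    irrigation_mm: float
    biomass_kg_ha: float
    grain_yield_kg_ha: float
    hi: float
    tr_eto_sum: float
    closure_error_mm: float


@dataclass
class SeasonResult:
    """Daily trajectories plus seasonal totals of one simulated season."""

    daily: pd.DataFrame
    totals: SeasonTotals
    config: ScenarioConfig

    def cc_on_day(self, day: int) -> float:
        return float(self.daily["cc"].iloc[day])


def run_season(config: ScenarioConfig) -> SeasonResult:
    """Simulate one season from sowing to maturity (inclusive).

    Raises before the first step if the weather series does not cover
    the whole season.  Emits a debug-level log line per simulated day.
    """
    crop, profile = config.crop, config.soil
    start = config.planting_date
    end = start + timedelta(days=crop.maturity_day)
    if not config.weather.covers(start, end):
        raise WeatherError(
            f"weather covers {config.weather.start}..{config.weather.end}, "
            f"season needs {start}..{end}")
    weather = config.weather.ensure_eto()
    irrigation = {d: float(mm) for d, mm in config.irrigation}

    state = sw.WaterState.at_fraction(profile, config.initial_water)
    can = cn.CanopyState()
    prod = pr.ProductionState()

    n_days = crop.maturity_day + 1
    cols = {k: np.zeros(n_days) for k in (
        "eto", "rain", "irrigation", "runoff", "percolation", "evaporation",
        "transpiration", "cc", "root_depth", "taw", "dr", "ks_exp", "ks_sto",
        "ks_sen", "biomass_kg_ha", "hi")}
    dates = []

    water_in = water_out = 0.0
    storage0 = state.storage_mm(profile)

    for day in range(n_days):
        today = start + timedelta(days=day)
        w = weather.day(today)
        eto = float(w.eto)
        rain, irr = w.rain, irrigation.get(today, 0.0)

        zr = sw.root_deepening(day, crop)
        taw, dr = sw.update_root_zone(state, zr, profile)
        p = dr / taw if taw > 0 else 0.0
        ks_exp = cn.ks_stress(p, crop.p_exp_upper, crop.p_exp_lower, crop.shape_exp)
        ks_sto = cn.ks_stress(p, crop.p_sto, 1.0, crop.shape_sto)
        ks_sen = cn.ks_stress(p, crop.p_sen, 1.0, crop.shape_sen)

        # canopy development (calendar-day phenology)
        if day < crop.emergence_day:
            pass  # pre-emergence: bare soil
        elif day == crop.emergence_day:
            can = cn.CanopyState(cc=crop.cc0, phase="growth")
        elif day < crop.senescence_day:
            can = cn.cc_growth_step(can, crop, ks_exp)
            can = replace(can, cc=cn.stress_senescence_decay(can.cc, crop, ks_sen))
        else:
            can = cn.cc_senescence_step(can, crop)

        demand = pr.daily_transpiration(can.cc, eto, ks_sto, crop.kctr,
                                        adjust=crop.cc_adjustment)
        fluxes = sw.step_water_balance(state, profile, rain, irr, can.cc, eto,
                                       demand, zr)
        prod.add_growth(fluxes.transpiration, eto, crop)
        prod.update_hi(day, w.tmin, w.tmax, crop)

        water_in += rain + irr
        water_out += (fluxes.runoff + fluxes.percolation + fluxes.evaporation
                      + fluxes.transpiration)

        if config.hold_at_field_capacity:
            state = sw.WaterState.at_field_capacity(profile)

        dates.append(today)
        for k, v in (("eto", eto), ("rain", rain), ("irrigation", irr),
                     ("runoff", fluxes.runoff), ("percolation", fluxes.percolation),
                     ("evaporation", fluxes.evaporation),
                     ("transpiration", fluxes.transpiration), ("cc", can.cc),
                     ("root_depth", zr), ("taw", taw), ("dr", dr),
                     ("ks_exp", ks_exp), ("ks_sto", ks_sto), ("ks_sen", ks_sen),
                     ("biomass_kg_ha", prod.biomass_kg_ha), ("hi", prod.hi)):
            cols[k][day] = v
        log.debug("%s day %d cc=%.3f Dr=%.1f T=%.2f B=%.0f",
                  config.name, day, can.cc, dr, fluxes.transpiration,
                  prod.biomass_kg_ha)

    storage1 = state.storage_mm(profile)
    if config.hold_at_field_capacity:
        closure = float("nan")  # storage is externally reset; no budget to close
    else:
        closure = water_in - water_out - (storage1 - storage0)

    by = prod.biomass_kg_ha
    gy = pr.grain_yield(by, prod.hi)
    daily = pd.DataFrame(cols)
    daily.insert(0, "date", dates)
    daily.insert(0, "day", np.arange(n_days))
    totals = SeasonTotals(
        transpiration_mm=float(cols["transpiration"].sum()),
        evaporation_mm=float(cols["evaporation"].sum()),
        runoff_mm=float(cols["runoff"].sum()),
        percolation_mm=float(cols["percolation"].sum()),
        rain_mm=float(cols["rain"].sum()),
        irrigation_mm=float(cols["irrigation"].sum()),
        biomass_kg_ha=by, grain_yield_kg_ha=gy, hi=prod.hi,
        tr_eto_sum=prod.tr_eto_sum, closure_error_mm=float(closure))
    return SeasonResult(daily=daily, totals=totals, config=config)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Fitted parameters and achieved fit of a calibration run."""

    crop: CropParams
    fitted: dict[str, float]
    rmse: float
    n_evals: int


def _objective(values, names, cases) -> float:
    total_sq, total_n = 0.0, 0
    for config, obs in cases:
        crop = config.crop.replace(**dict(zip(names, values)))
        try:
            result = run_season(replace(config, crop=crop))
        except ParameterError:
            return 1e6
        sim_cc = result.daily["cc"].to_numpy() * 100.0
        days = obs["day"].to_numpy(dtype=int)
        resid = sim_cc[days] - obs["cc_pct"].to_numpy(dtype=float)
        total_sq += float(np.sum(resid ** 2))
        total_n += resid.size
        if "biomass_kg_ha" in obs.columns:
            sim_b = result.daily["biomass_kg_ha"].to_numpy()
            resid_b = (sim_b[days] - obs["biomass_kg_ha"].to_numpy(dtype=float)) / 100.0
            total_sq += float(np.sum(resid_b ** 2))
            total_n += resid_b.size
    return math.sqrt(total_sq / total_n)


def calibrate(cases: Sequence[tuple[ScenarioConfig, pd.DataFrame]],
              free_params: dict[str, tuple[float, float]],
              xtol: float = 1e-4) -> CalibrationResult:
    """Fit crop parameters to observed canopy cover by derivative-free search.

    ``cases`` pairs each scenario with an observation frame holding
    columns ``day`` (days after sowing) and ``cc_pct`` (% cover), plus
    optionally ``biomass_kg_ha``.  ``free_params`` maps parameter names
    (subset of cgc, cdc, p_sen, p_exp_upper, cc0, hi0) to (lo, hi)
    bounds.  One free parameter uses bounded scalar minimisation; more
    use Nelder-Mead started at the current values.
    """
    cases = [(c, pd.DataFrame(o)) for c, o in cases]
    if not cases or any(o.empty for _, o in cases):
        raise SimulationError("calibration needs at least one non-empty observation set")
    if not free_params:
        raise SimulationError("no free parameters requested")
    for name, bounds in free_params.items():
        if name not in CALIBRATABLE:
            raise SimulationError(f"parameter {name!r} is not calibratable")
        if bounds is None or len(bounds) != 2 or not bounds[0] < bounds[1]:
            raise SimulationError(f"parameter {name!r} needs finite (lo, hi) bounds")

    names = list(free_params)
    base = cases[0][0].crop

    if len(names) == 1:
        lo, hi = free_params[names[0]]
        res = optimize.minimize_scalar(
            lambda v: _objective([v], names, cases), bounds=(lo, hi),
            method="bounded", options={"xatol": xtol})
        best = [float(res.x)]
        n_evals = int(res.nfev)
        fun = float(res.fun)
    else:
        x0 = np.array([getattr(base, n) for n in names], dtype=float)
        lob = np.array([free_params[n][0] for n in names])
        hib = np.array([free_params[n][1] for n in names])
        x0 = np.clip(x0, lob, hib)

        def clipped(v):
            return _objective(np.clip(v, lob, hib), names, cases)

        res = optimize.minimize(clipped, x0, method="Nelder-Mead",
                                options={"xatol": xtol, "fatol": 1e-6})
        best = list(np.clip(res.x, lob, hib).astype(float))
        n_evals = int(res.nfev)
        fun = float(res.fun)

    fitted = dict(zip(names, best))
    return CalibrationResult(crop=base.replace(**fitted), fitted=fitted,
                             rmse=fun, n_evals=n_evals)
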