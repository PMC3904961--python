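"""Transpiration, normalized-water-productivity biomass, harvest index, yield.

Biomass accumulates as the normalized crop water productivity (NCWP,
g m-2) times the daily ratio of crop transpiration to reference
evapotranspiration:

    dB = NCWP * (Tr / ETo)        [g m-2 d-1]
    BY = 10 * B                    [kg ha-1]
    GY = HI * BY

Transpiration scales with canopy cover through a micro-advection
adjustment and the full-canopy crop coefficient, and shuts down with the
stomatal stress coefficient.  The harvest index builds linearly from
flowering to maturity; cold (<5 C) or hot (>35 C) days within the
flowering window fail a proportional share of pollination and scale the
achievable HI down.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import CropParams

G_M2_TO_KG_HA = 10.0


class ProductionError(ValueError):
    """Inconsistent production forcing."""


def cc_adjusted(cc: float) -> float:
    """Micro-advection adjustment of cover: min(1, 1.72 cc - cc^2 + 0.30 cc^3).

    A sparse canopy transpires more than its shaded area suggests because
    of advection from the bare interrows; the cubic lifts small covers
    and is capped at 1 so full cover never exceeds the crop coefficient.
    """
    return min(1.0, 1.72 * cc - cc ** 2 + 0.30 * cc ** 3)


def daily_transpiration(cc: float, eto: float, ks_stomatal: float,
                        kctr: float, adjust: bool = True) -> float:
    """Potential crop transpiration, mm d-1: ks * kctr * cc* * ETo."""
    if not 0.0 <= cc <= 1.0:
        raise ProductionError(f"canopy cover {cc} outside [0, 1]")
    if eto < 0:
        raise ProductionError("eto must be non-negative")
    cover = cc_adjusted(cc) if adjust else cc
    return ks_stomatal * kctr * cover * eto


def biomass_increment(biomass_g_m2: float, tr: float, eto: float,
                      ncwp: float) -> float:
    """Add one day's growth NCWP*(Tr/ETo) to the running biomass (g m-2)."""
    if tr > 0 and eto <= 0:
        raise ProductionError("transpiration with zero reference ET is inconsistent")
    if tr <= 0:
        return biomass_g_m2
    return biomass_g_m2 + ncwp * (tr / eto)


def grain_yield(by: float, hi: float) -> float:
    """Grain yield = harvest index * aboveground biomass, both kg ha-1."""
    if by < 0 or not 0.0 <= hi <= 1.0:
        raise ProductionError("need by >= 0 and hi in [0, 1]")
    return hi * by


@dataclass
class ProductionState:
    """Running biomass, transpiration ratio sum, harvest index, pollination record."""

    biomass_g_m2: float = 0.0
    tr_eto_sum: float = 0.0
    hi: float = 0.0
    flowering_ok: int = 0      # flowering days with successful pollination
    flowering_seen: int = 0

    @property
    def biomass_kg_ha(self) -> float:
        return self.biomass_g_m2 * G_M2_TO_KG_HA

    def add_growth(self, tr: float, eto: float, crop: CropParams) -> None:
        self.biomass_g_m2 = biomass_increment(self.biomass_g_m2, tr, eto, crop.ncwp)
        if tr > 0 and eto > 0:
            self.tr_eto_sum += tr / eto

    def update_hi(self, day: int, tmin: float, tmax: float, crop: CropParams) -> None:
        """Harvest-index buildup for one day (``day`` counted from sowing)."""
        if day < crop.flowering_day:
            return
        if day < crop.flowering_day + crop.flowering_length:
            self.flowering_seen += 1
            if crop.t_pol_min <= tmin and tmax <= crop.t_pol_max:
                self.flowering_ok += 1
        self.hi = hi_buildup(day, crop, self.pollination_fraction)

    @property
    def pollination_fraction(self) -> float:
        if self.flowering_seen == 0:
            return 1.0
        return self.flowering_ok / self.flowering_seen


def hi_buildup(day: int, crop: CropParams, pollination_fraction: float = 1.0) -> float:
    """Harvest index on ``day`` (days after sowing).

    Zero before flowering; rises linearly to the reference hi0 at
    maturity.  Failed pollination days scale the achievable ceiling by
    the successful fraction; any upward adjustment is capped at
    hi0 * (1 + hi_increase_max).
    """
    if day < crop.flowering_day:
        return 0.0
    span = max(crop.maturity_day - crop.flowering_day, 1)
    ramp = min((day - crop.flowering_day) / span, 1.0)
    ceiling = min(crop.hi0 * pollination_fraction,
                  crop.hi0 * (1.0 + crop.hi_increase_max))
    return ramp * ceiling
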