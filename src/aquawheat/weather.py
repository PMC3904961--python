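"""Daily weather records and FAO-56 Penman-Monteith reference evapotranspiration.

The reference evapotranspiration (ETo) of a well-watered grass surface is
computed from daily Tmax/Tmin, mean relative humidity, 2-m wind speed and
sunshine hours (or measured solar radiation) with the standard FAO-56
combination equation:

    ETo = [0.408 D (Rn - G) + g 900/(T+273) u2 (es - ea)] / [D + g (1 + 0.34 u2)]

with D the slope of the saturation vapour pressure curve, g the
psychrometric constant from station elevation, Rn the net radiation
derived from sunshine via the Angstrom relation (a=0.25, b=0.50), and
soil heat flux G = 0 at the daily step.

Latitude and elevation are required arguments everywhere: no station
default is baked in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date as Date, timedelta
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

SOLAR_CONSTANT = 0.0820       # MJ m-2 min-1
STEFAN_BOLTZMANN = 4.903e-9   # MJ K-4 m-2 day-1
ANGSTROM_A = 0.25
ANGSTROM_B = 0.50
ALBEDO = 0.23

CSV_COLUMNS = ["date", "tmax", "tmin", "rh_mean", "wind2", "sunshine", "rain"]


class WeatherError(ValueError):
    """Invalid weather record or weather file."""


@dataclass(frozen=True)
class WeatherDay:
    """One day of station meteorology.

    ``sunshine`` is bright sunshine duration in hours unless
    ``sunshine_is_radiation`` is set, in which case it is measured solar
    radiation in MJ m-2 d-1.  ``eto`` may be supplied pre-computed (mm d-1);
    when present it takes precedence over the Penman-Monteith computation.
    """

    date: Date
    tmax: float
    tmin: float
    rh_mean: float
    wind2: float
    sunshine: float
    rain: float
    eto: Optional[float] = None
    sunshine_is_radiation: bool = False

    def __post_init__(self) -> None:
        for name in ("tmax", "tmin", "rh_mean", "wind2", "sunshine", "rain"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise WeatherError(f"missing required weather field {name!r} on {self.date}")
        if self.tmax < self.tmin:
            raise WeatherError(f"tmax < tmin on {self.date}")
        if not 0.0 <= self.rh_mean <= 100.0:
            raise WeatherError(f"rh_mean outside [0, 100] on {self.date}")
        if self.wind2 < 0 or self.rain < 0 or self.sunshine < 0:
            raise WeatherError(f"negative wind/rain/sunshine on {self.date}")
        if self.eto is not None and self.eto < 0:
            raise WeatherError(f"negative eto on {self.date}")


# ---------------------------------------------------------------------------
# FAO-56 component relations
# ---------------------------------------------------------------------------

def saturation_vapour_pressure(t: float) -> float:
    """e0(T), kPa, from air temperature in deg C."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def svp_slope(t: float) -> float:
    """Slope of the saturation vapour pressure curve at T, kPa degC-1."""
    return 4098.0 * saturation_vapour_pressure(t) / (t + 237.3) ** 2


def atmospheric_pressure(elevation: float) -> float:
    """Barometric pressure, kPa, from elevation in m."""
    return 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26


def psychrometric_constant(elevation: float) -> float:
    """g = 0.665e-3 * P, kPa degC-1."""
    return 0.665e-3 * atmospheric_pressure(elevation)


def extraterrestrial_radiation(doy: int, latitude: float) -> tuple[float, float]:
    """Daily extraterrestrial radiation Ra (MJ m-2 d-1) and daylight hours N."""
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))  # clamp for polar day/night
    ra = (24.0 * 60.0 / math.pi) * SOLAR_CONSTANT * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws))
    n_hours = 24.0 / math.pi * ws
    return ra, n_hours


def penman_monteith(tmean: float, u2: float, es: float, ea: float,
                    rn: float, gamma: float, g: float = 0.0) -> float:
    """FAO-56 combination equation, mm d-1, clipped at zero.

    This is the low-level form taking already-assembled components; use
    :func:`eto_fao56` for the full daily chain.
    """
    delta = svp_slope(tmean)
    num = 0.408 * delta * (rn - g) + gamma * (900.0 / (tmean + 273.0)) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    return max(0.0, num / den)


def eto_fao56(day: WeatherDay, latitude: float, elevation: float) -> float:
    """Daily grass reference evapotranspiration, mm d-1.

    Net radiation comes from sunshine hours through the Angstrom relation
    (a=0.25, b=0.50) unless the record carries measured solar radiation.
    """
    if not -90.0 <= latitude <= 90.0:
        raise WeatherError(f"latitude {latitude} outside [-90, 90]")
    tmean = (day.tmax + day.tmin) / 2.0
    gamma = psychrometric_constant(elevation)
    es = (saturation_vapour_pressure(day.tmax) + saturation_vapour_pressure(day.tmin)) / 2.0
    ea = day.rh_mean / 100.0 * es

    doy = day.date.timetuple().tm_yday
    ra, n_hours = extraterrestrial_radiation(doy, latitude)
    if day.sunshine_is_radiation:
        rs = day.sunshine
    else:
        rel = min(day.sunshine / n_hours, 1.0) if n_hours > 0 else 0.0
        rs = (ANGSTROM_A + ANGSTROM_B * rel) * ra
    rso = (0.75 + 2e-5 * elevation) * ra
    rns = (1.0 - ALBEDO) * rs
    rel_rs = min(rs / rso, 1.0) if rso > 0 else 0.0
    rnl = STEFAN_BOLTZMANN * (((day.tmax + 273.16) ** 4 + (day.tmin + 273.16) ** 4) / 2.0) \
        * (0.34 - 0.14 * math.sqrt(max(ea, 0.0))) * (1.35 * rel_rs - 0.35)
    rn = rns - rnl
    return penman_monteith(tmean, day.wind2, es, ea, rn, gamma)


# ---------------------------------------------------------------------------
# Weather series and CSV I/O
# ---------------------------------------------------------------------------

@dataclass
class WeatherSeries:
    """An ordered, gap-free run of daily weather for one station."""

    days: list[WeatherDay]
    latitude: float
    elevation: float
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.days:
            raise WeatherError("empty weather series")
        for prev, cur in zip(self.days, self.days[1:]):
            if cur.date != prev.date + timedelta(days=1):
                raise WeatherError(
                    f"dates must be consecutive: gap between {prev.date} and {cur.date}")
        self._index = {d.date: i for i, d in enumerate(self.days)}

    def __len__(self) -> int:
        return len(self.days)

    def __iter__(self) -> Iterator[WeatherDay]:
        return iter(self.days)

    @property
    def start(self) -> Date:
        return self.days[0].date

    @property
    def end(self) -> Date:
        return self.days[-1].date

    def __contains__(self, d: Date) -> bool:
        return d in self._index

    def day(self, d: Date) -> WeatherDay:
        try:
            return self.days[self._index[d]]
        except KeyError:
            raise WeatherError(f"no weather record for {d}") from None

    def covers(self, start: Date, end: Date) -> bool:
        return self.start <= start and end <= self.end

    def ensure_eto(self) -> "WeatherSeries":
        """Return a series in which every record has eto, computing where absent."""
        out = [d if d.eto is not None
               else replace(d, eto=eto_fao56(d, self.latitude, self.elevation))
               for d in self.days]
        return WeatherSeries(out, self.latitude, self.elevation)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "date": d.date.isoformat(), "tmax": d.tmax, "tmin": d.tmin,
            "rh_mean": d.rh_mean, "wind2": d.wind2, "sunshine": d.sunshine,
            "rain": d.rain, "eto": np.nan if d.eto is None else d.eto,
        } for d in self.days]
        return pd.DataFrame(rows)


def read_weather_csv(path, latitude: float, elevation: float) -> WeatherSeries:
    """Read a weather CSV (columns date,tmax,tmin,rh_mean,wind2,sunshine,rain[,eto]).

    Malformed rows are reported with their file line number; a gap in the
    date sequence is an error.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str)
    if raw.empty:
        raise WeatherError(f"{path}: no weather rows")
    missing = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise WeatherError(f"{path}: missing column(s) {missing}")
    has_eto = "eto" in raw.columns
    days = []
    for i, row in raw.iterrows():
        lineno = i + 2  # header is line 1
        try:
            eto = None
            if has_eto and isinstance(row["eto"], str) and row["eto"].strip():
                eto = float(row["eto"])
            days.append(WeatherDay(
                date=Date.fromisoformat(row["date"].strip()),
                tmax=float(row["tmax"]), tmin=float(row["tmin"]),
                rh_mean=float(row["rh_mean"]), wind2=float(row["wind2"]),
                sunshine=float(row["sunshine"]), rain=float(row["rain"]),
                eto=eto))
        except (WeatherError, ValueError, TypeError, AttributeError) as exc:
            raise WeatherError(f"{path}:{lineno}: malformed weather row ({exc})") from exc
    return WeatherSeries(days, latitude, elevation)


def write_weather_csv(series: WeatherSeries, path) -> None:
    """Write the series with a fixed 6-decimal format so round-trips are bitwise stable."""
    def fmt(v: Optional[float]) -> str:
        return "" if v is None else f"{v:.6f}"

    lines = [",".join(CSV_COLUMNS + ["eto"])]
    for d in series.days:
        lines.append(",".join([
            d.date.isoformat(), fmt(d.tmax), fmt(d.tmin), fmt(d.rh_mean),
            fmt(d.wind2), fmt(d.sunshine), fmt(d.rain), fmt(d.eto)]))
    Path(path).write_text("\n".join(lines) + "\n")
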