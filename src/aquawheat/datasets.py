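"""Published field-trial inputs for the Xiaotangshan (Beijing) winter wheat experiments.

The 2008/2009-2011/2012 trials report planting dates, the irrigation
schedule actually applied each season, the measured hydraulic properties
of the top 0.3 m of soil, and a seasonal summary of aboveground biomass,
grain yield and model-derived seasonal transpiration for ten planting-date
x season combinations.  These printed values are inputs to the analysis
layer (water-use efficiency, yield-transpiration regressions) and the
reference scenarios of the simulator.

Seasons are keyed by sowing year: "2008" is the 2008/2009 season.

Note on units: the seasonal transpiration column is tabulated under an
m3 ha-1 header in the source, but the reported WUE values are only
consistent with the column being transpiration depth in mm (1 mm =
10 m3 ha-1).  It is stored here as mm and converted where needed.
"""

from __future__ import annotations

from datetime import date as Date

import pandas as pd

SEASONS = ("2008", "2009", "2010", "2011")

#: Planting dates trialled each season (first entry = earliest/normal sowing).
PLANTING_DATES: dict[str, list[Date]] = {
    "2008": [Date(2008, 9, 28), Date(2008, 10, 7), Date(2008, 10, 20)],
    "2009": [Date(2009, 9, 25), Date(2009, 10, 5), Date(2009, 10, 15)],
    "2010": [Date(2010, 9, 25), Date(2010, 10, 5), Date(2010, 10, 15)],
    "2011": [Date(2011, 9, 25)],
}

#: Seasonal rainfall from sowing to harvest, mm.
SEASON_RAINFALL_MM: dict[str, float] = {
    "2008": 199.0, "2009": 208.0, "2010": 145.0, "2011": 168.0,
}

#: Applied irrigation events, (date, mm), per season.
IRRIGATION_SCHEDULES: dict[str, list[tuple[Date, float]]] = {
    "2008": [
        (Date(2008, 11, 16), 75.0),
        (Date(2009, 4, 10), 68.0),
        (Date(2009, 4, 28), 68.0),
        (Date(2009, 5, 26), 68.0),
    ],
    "2009": [
        (Date(2009, 11, 15), 75.0),
        (Date(2010, 4, 5), 68.0),
        (Date(2010, 5, 4), 68.0),
        (Date(2010, 5, 26), 68.0),
    ],
    "2010": [
        (Date(2010, 11, 13), 75.0),
        (Date(2011, 3, 24), 30.0),
        (Date(2011, 3, 26), 30.0),
        (Date(2011, 4, 7), 90.0),
        (Date(2011, 4, 29), 36.0),
        (Date(2011, 4, 30), 30.0),
        (Date(2011, 5, 2), 30.0),
        (Date(2011, 5, 23), 34.0),
        (Date(2011, 5, 24), 30.0),
        (Date(2011, 5, 25), 30.0),
        (Date(2011, 5, 26), 54.0),
    ],
    "2011": [
        (Date(2011, 11, 16), 75.0),
        (Date(2012, 3, 30), 27.0),
        (Date(2012, 4, 7), 54.0),
        (Date(2012, 5, 19), 27.0),
        (Date(2012, 5, 24), 30.0),
        (Date(2012, 5, 26), 30.0),
        (Date(2012, 5, 28), 30.0),
    ],
}

# Seasonal summary: measured biomass and grain (kg ha-1), model-derived
# seasonal transpiration (mm), and the reported WUE values (kg m-3).
_FIELD_ROWS = [
    # season, planting_date, biomass, grain, transp_mm, bwue_rep, gwue_rep
    ("2008", Date(2008, 9, 28), 13072.0, 5808.0, 341.2, 3.83, 1.70),
    ("2008", Date(2008, 10, 7), 11612.0, 5227.0, 259.1, 4.48, 2.02),
    ("2008", Date(2008, 10, 20), 11144.0, 5146.0, 255.7, 4.36, 2.01),
    ("2009", Date(2009, 9, 25), 12666.0, 5909.0, 322.3, 3.93, 1.83),
    ("2009", Date(2009, 10, 5), 10212.0, 5106.0, 296.3, 3.45, 1.72),
    ("2009", Date(2009, 10, 15), 9861.0, 4852.0, 207.0, 4.76, 2.34),
    ("2010", Date(2010, 9, 25), 11812.0, 6103.0, 292.9, 4.03, 2.08),
    ("2010", Date(2010, 10, 5), 11024.0, 5512.0, 251.1, 4.39, 2.20),
    ("2010", Date(2010, 10, 15), 10062.0, 5013.0, 220.2, 4.57, 2.28),
    ("2011", Date(2011, 9, 25), 12514.0, 6257.0, 306.0, 4.09, 2.04),
]


def field_results() -> pd.DataFrame:
    """Seasonal biomass/grain/transpiration summary of the ten trial rows.

    Columns: season, planting_date, biomass_kg_ha, grain_kg_ha,
    transpiration_mm, biomass_wue_reported, grain_wue_reported.
    """
    return pd.DataFrame(_FIELD_ROWS, columns=[
        "season", "planting_date", "biomass_kg_ha", "grain_kg_ha",
        "transpiration_mm", "biomass_wue_reported", "grain_wue_reported"])


def irrigation_schedule(season: str) -> list[tuple[Date, float]]:
    """The applied (date, mm) irrigation events of one season."""
    try:
        return list(IRRIGATION_SCHEDULES[season])
    except KeyError:
        raise KeyError(
            f"unknown season {season!r}; choose from {SEASONS} or build a "
            "custom schedule") from None
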