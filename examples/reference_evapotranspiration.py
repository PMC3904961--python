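"""Compute FAO-56 reference evapotranspiration for a single station day.

ETo is the evaporative demand of a standardized well-watered grass
surface; every transpiration and biomass number downstream is scaled by
it, so this is the first quantity to sanity-check at a new site.
"""

from datetime import date

from aquawheat import WeatherDay, eto_fao56

LATITUDE, ELEVATION = 40.18, 36.0  # Beijing-plausible station geometry

summer = WeatherDay(date=date(2009, 6, 15), tmax=30.0, tmin=15.0,
                    rh_mean=40.0, wind2=2.0, sunshine=9.0, rain=0.0)
winter = WeatherDay(date=date(2009, 1, 20), tmax=4.0, tmin=-6.0,
                    rh_mean=55.0, wind2=3.0, sunshine=6.0, rain=0.0)

for label, day in [("summer", summer), ("winter", winter)]:
    eto = eto_fao56(day, LATITUDE, ELEVATION)
    print(f"{label} day {day.date}: ETo = {eto:.2f} mm/day")

print("\nA dry, sunny summer day evaporates several mm of water; a cold")
print("winter day well under 1 mm — the ratio drives the seasonal shape of")
print("crop water demand.")
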