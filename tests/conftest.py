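"""Shared fixtures: synthetic weather seasons and reference scenarios.

Weather generation and full-season runs are session-scoped so the suite
reuses them instead of regenerating per test.
"""

import dataclasses

import pytest

import aquawheat as aw


@pytest.fixture(scope="session")
def climate():
    return aw.ClimateSpec()


@pytest.fixture(scope="session")
def weather_2008(climate):
    """Seeded Beijing-like season for sowing year 2008 (199 mm window rain)."""
    return aw.gen_weather(climate, "2008", seed=42)


@pytest.fixture(scope="session")
def weather_2008_eto(weather_2008):
    return weather_2008.ensure_eto()


@pytest.fixture(scope="session")
def dry_weather_2008(climate):
    """Same climate but every rain depth zeroed: a rainless scenario family."""
    base = aw.gen_weather(climate, "2008", seed=11)
    days = [dataclasses.replace(d, rain=0.0) for d in base.days]
    return aw.WeatherSeries(days, climate.latitude, climate.elevation)


@pytest.fixture(scope="session")
def soil():
    return aw.SoilProfile.xiaotangshan()


@pytest.fixture(scope="session")
def crop():
    return aw.CropParams()


@pytest.fixture(scope="session")
def scenario_2008(weather_2008, soil, crop):
    """Reference 2008/2009 scenario: first planting date, applied schedule."""
    return aw.ScenarioConfig(
        planting_date=aw.datasets.PLANTING_DATES["2008"][0],
        weather=weather_2008, soil=soil, crop=crop,
        irrigation=aw.datasets.irrigation_schedule("2008"), name="2008-ref")


@pytest.fixture(scope="session")
def season_2008(scenario_2008):
    return aw.run_season(scenario_2008)
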