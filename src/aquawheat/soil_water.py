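"""Layered soil water balance.

The profile is a stack of thin compartments (0.1 m by default), each with
its own saturation, field capacity, wilting point (volumetric %) and
saturated conductivity (mm d-1).  The daily step partitions rain into
runoff (SCS curve number), infiltrates the remainder plus irrigation,
drains water above field capacity downward at a rate bounded by Ksat,
evaporates from the uncovered surface layer in two stages, and extracts
transpiration from the rooted compartments.

Unit convention: 1 %vol of water over 0.1 m of soil = 1 mm; every flux is
expressed in mm of water.  The daily budget closes exactly:

    rain + irrigation = runoff + percolation + E + T + dStorage
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .params import CropParams, ParameterError

MM_PER_PCTVOL_M = 10.0   # mm of water per (%vol * m of soil)
KE_MAX = 1.1             # maximum soil evaporation coefficient, stage 1
REW_DEFAULT = 9.0        # readily evaporable water, mm
AIR_DRY_FACTOR = 0.5     # air-dry floor of the surface layer, fraction of WP


class SoilError(ValueError):
    """Invalid soil configuration or state."""


@dataclass(frozen=True)
class SoilLayer:
    """One compartment: thickness (m), water contents (%vol), Ksat (mm d-1)."""

    thickness: float
    theta_sat: float
    theta_fc: float
    theta_wp: float
    ksat: float

    def __post_init__(self) -> None:
        if not self.theta_sat > self.theta_fc > self.theta_wp > 0:
            raise SoilError(
                f"need sat > fc > wp > 0, got {self.theta_sat}/{self.theta_fc}/{self.theta_wp}")
        if self.ksat <= 0 or self.thickness <= 0:
            raise SoilError("ksat and thickness must be positive")


# Measured hydraulic properties of the Xiaotangshan fine-loamy profile
# (0-0.3 m); deeper compartments reuse the 0.2-0.3 m values.
XIAOTANGSHAN_LAYERS = (
    SoilLayer(0.1, 51.1, 27.3, 8.8, 240.0),
    SoilLayer(0.1, 51.3, 27.3, 8.7, 240.0),
    SoilLayer(0.1, 54.7, 34.8, 13.2, 224.0),
)


@dataclass
class SoilProfile:
    """Compartment stack plus runoff curve number and groundwater depth.

    The water table (3.5 m at the reference site) lies well below the
    root zone and is treated as free drainage; percolation past the
    bottom compartment leaves the system.
    """

    layers: Sequence[SoilLayer]
    curve_number: float = 75.0
    groundwater_depth: float = 3.5

    def __post_init__(self) -> None:
        if not self.layers:
            raise SoilError("profile needs at least one layer")
        if not 0.0 < self.curve_number <= 100.0:
            raise ParameterError(f"curve number {self.curve_number} outside (0, 100]")
        self.thick = np.array([l.thickness for l in self.layers])
        self.sat = np.array([l.theta_sat for l in self.layers])
        self.fc = np.array([l.theta_fc for l in self.layers])
        self.wp = np.array([l.theta_wp for l in self.layers])
        self.ksat = np.array([l.ksat for l in self.layers])
        self.bottoms = np.cumsum(self.thick)

    @property
    def depth(self) -> float:
        return float(self.bottoms[-1])

    @classmethod
    def xiaotangshan(cls, total_depth: float = 1.3, curve_number: float = 75.0,
                     groundwater_depth: float = 3.5) -> "SoilProfile":
        """Reference-site profile extended to ``total_depth`` in 0.1 m steps.

        Only the top 0.3 m was characterised in the field; the 0.2-0.3 m
        layer's properties are extended downward so the 1.2 m maximum
        rooting depth fits inside the profile.
        """
        layers = list(XIAOTANGSHAN_LAYERS)
        deep = XIAOTANGSHAN_LAYERS[-1]
        n_extra = int(round((total_depth - 0.3) / 0.1))
        layers.extend([deep] * n_extra)
        return cls(layers, curve_number, groundwater_depth)


@dataclass
class WaterState:
    """Evolving water content (%vol per compartment) plus surface-evaporation stage.

    ``surface_depletion`` is the cumulative evaporation (mm) from the
    surface layer since it was last wetted; it selects between the
    energy-limited and falling-rate evaporation stages.
    """

    theta: np.ndarray
    surface_depletion: float = 0.0

    @classmethod
    def at_field_capacity(cls, profile: SoilProfile) -> "WaterState":
        return cls(theta=profile.fc.copy().astype(float))

    @classmethod
    def at_fraction(cls, profile: SoilProfile, fraction: float) -> "WaterState":
        """Profile uniformly at WP + fraction*(FC - WP); fraction=1 is field capacity."""
        if not 0.0 <= fraction <= 1.0:
            raise SoilError(f"water fraction {fraction} outside [0, 1]")
        theta = profile.wp + fraction * (profile.fc - profile.wp)
        return cls(theta=theta.astype(float))

    def storage_mm(self, profile: SoilProfile) -> float:
        return float(np.sum(self.theta * profile.thick) * MM_PER_PCTVOL_M)

    def copy(self) -> "WaterState":
        return WaterState(self.theta.copy(), self.surface_depletion)


@dataclass(frozen=True)
class DayFluxes:
    """Water fluxes of one daily step, all in mm."""

    runoff: float
    percolation: float
    evaporation: float
    transpiration: float
    delta_storage: float
    infiltration: float


# ---------------------------------------------------------------------------
# Component operations
# ---------------------------------------------------------------------------

def curve_number_runoff(rain: float, curve_number: float) -> float:
    """SCS curve-number runoff with initial abstraction Ia = 0.2 S.

    S = 25400/CN - 254 (mm); runoff is zero until rain exceeds Ia and
    approaches rain - Ia - S asymptotically.
    """
    if not 0.0 < curve_number <= 100.0:
        raise ParameterError(f"curve number {curve_number} outside (0, 100]")
    if rain < 0:
        raise SoilError("rain must be non-negative")
    s = 25400.0 / curve_number - 254.0
    ia = 0.2 * s
    if rain <= ia:
        return 0.0
    return (rain - ia) ** 2 / (rain - ia + s)


def infiltrate(state: WaterState, profile: SoilProfile, amount: float) -> float:
    """Push ``amount`` mm into the profile from the top, filling toward saturation.

    Returns the part that could not be stored anywhere (saturation excess).
    """
    remaining = amount
    for i in range(len(profile.thick)):
        if remaining <= 0:
            break
        room = (profile.sat[i] - state.theta[i]) * profile.thick[i] * MM_PER_PCTVOL_M
        take = min(remaining, max(room, 0.0))
        state.theta[i] += take / (profile.thick[i] * MM_PER_PCTVOL_M)
        remaining -= take
    return remaining


def drain_profile(state: WaterState, profile: SoilProfile) -> float:
    """Move water above field capacity downward, bounded by Ksat per day.

    Processes compartments top-down so water cascades within the step;
    a full receiving compartment pushes the surplus back up.  Returns
    deep percolation (mm) past the bottom compartment.
    """
    n = len(profile.thick)
    perc = 0.0
    for i in range(n):
        cap = profile.thick[i] * MM_PER_PCTVOL_M
        excess = max(0.0, (state.theta[i] - profile.fc[i])) * cap
        flow = min(excess, profile.ksat[i])
        if flow <= 0:
            continue
        state.theta[i] -= flow / cap
        if i + 1 < n:
            cap_next = profile.thick[i + 1] * MM_PER_PCTVOL_M
            room = max(0.0, (profile.sat[i + 1] - state.theta[i + 1])) * cap_next
            into = min(flow, room)
            state.theta[i + 1] += into / cap_next
            state.theta[i] += (flow - into) / cap  # no room below: stays put
        else:
            perc += flow
    return perc


def soil_evaporation(state: WaterState, profile: SoilProfile, cc: float,
                     eto: float, ke_max: float = KE_MAX,
                     rew: float = REW_DEFAULT) -> float:
    """Two-stage evaporation from the uncovered fraction of the surface layer.

    Stage 1 (surface recently wetted, depletion < REW) proceeds at the
    energy limit (1-cc)*ke_max*eto; stage 2 falls off linearly with the
    remaining evaporable water down to the air-dry floor (0.5 WP).
    """
    if not 0.0 <= cc <= 1.0:
        raise SoilError(f"canopy cover {cc} outside [0, 1]")
    cap = profile.thick[0] * MM_PER_PCTVOL_M
    air_dry = AIR_DRY_FACTOR * profile.wp[0]
    tew = (profile.fc[0] - air_dry) * cap          # totally evaporable water
    rew = min(rew, tew)
    e_pot = (1.0 - cc) * ke_max * eto
    de = state.surface_depletion
    if de <= rew:
        kr = 1.0
    elif de >= tew:
        kr = 0.0
    else:
        kr = (tew - de) / (tew - rew)
    available = max(0.0, (state.theta[0] - air_dry)) * cap
    e = min(e_pot * kr, available)
    state.theta[0] -= e / cap
    state.surface_depletion = min(de + e, tew)
    return e


def update_root_zone(state: WaterState, root_depth: float,
                     profile: SoilProfile) -> tuple[float, float]:
    """Total available water (TAW) and current depletion (Dr) of the root zone, mm.

    Partially rooted compartments contribute pro rata.  Depletion is
    referenced to field capacity and floored at zero per compartment.
    """
    if root_depth > profile.depth + 1e-9:
        raise SoilError(
            f"root depth {root_depth} m exceeds profile depth {profile.depth} m")
    tops = profile.bottoms - profile.thick
    rooted = np.clip((root_depth - tops) / profile.thick, 0.0, 1.0)
    cap = profile.thick * MM_PER_PCTVOL_M * rooted
    taw = float(np.sum((profile.fc - profile.wp) * cap))
    dr = float(np.sum(np.maximum(profile.fc - state.theta, 0.0) * cap))
    return taw, dr


def root_deepening(days_after_planting: float, crop: CropParams) -> float:
    """Effective rooting depth (m): power-law expansion from zr_min to zr_max.

    Depth follows zr_min + (zr_max - zr_min) * t_rel**(1/shape) with
    t_rel the fraction of the emergence-to-max-root period elapsed.
    """
    if days_after_planting < 0:
        raise SoilError("days_after_planting must be >= 0")
    t0, t1 = crop.emergence_day, crop.max_root_day
    t_rel = (days_after_planting - t0) / (t1 - t0)
    t_rel = min(max(t_rel, 0.0), 1.0)
    return crop.zr_min + (crop.zr_max - crop.zr_min) * t_rel ** (1.0 / crop.root_shape)


def extract_transpiration(state: WaterState, profile: SoilProfile,
                          demand: float, root_depth: float) -> float:
    """Withdraw up to ``demand`` mm from rooted compartments, floor at wilting point.

    Extraction is distributed proportionally to each compartment's
    available water above WP (weighted by rooted fraction).
    """
    if demand <= 0:
        return 0.0
    tops = profile.bottoms - profile.thick
    rooted = np.clip((root_depth - tops) / profile.thick, 0.0, 1.0)
    cap = profile.thick * MM_PER_PCTVOL_M
    avail = np.maximum(state.theta - profile.wp, 0.0) * cap * rooted
    total = float(avail.sum())
    if total <= 0:
        return 0.0
    t = min(demand, total)
    state.theta -= (avail / total) * t / cap
    return t


def step_water_balance(state: WaterState, profile: SoilProfile, rain: float,
                       irrigation: float, cc: float, eto: float,
                       transp_demand: float, root_depth: float,
                       ke_max: float = KE_MAX, rew: float = REW_DEFAULT) -> DayFluxes:
    """Advance the profile by one day; returns the closing flux set.

    Order of operations: runoff partition, infiltration (irrigation does
    not run off), drainage, surface evaporation, root extraction.  A
    saturation excess that cannot infiltrate joins the runoff term.
    """
    if rain < 0 or irrigation < 0:
        raise SoilError("rain and irrigation must be non-negative")
    storage0 = state.storage_mm(profile)
    runoff = curve_number_runoff(rain, profile.curve_number)
    supply = rain - runoff + irrigation
    excess = infiltrate(state, profile, supply)
    runoff += excess
    infiltrated = supply - excess
    # a real wetting pulse rewets the evaporating surface layer
    state.surface_depletion = max(0.0, state.surface_depletion - infiltrated)
    perc = drain_profile(state, profile)
    e = soil_evaporation(state, profile, cc, eto, ke_max=ke_max, rew=rew)
    t = extract_transpiration(state, profile, transp_demand, root_depth)
    delta = state.storage_mm(profile) - storage0
    return DayFluxes(runoff=runoff, percolation=perc, evaporation=e,
                     transpiration=t, delta_storage=delta, infiltration=infiltrated)
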