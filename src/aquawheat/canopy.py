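"""Canopy cover dynamics, LAI conversion, and water-stress coefficients.

Canopy cover (CC, fraction of shaded ground) replaces LAI as the state
variable of the crop.  Growth is exponential in the establishment phase
(cc <= ccx/2) and decays exponentially toward the maximum cover ccx
thereafter; senescence follows a convex exponential decline.  Water
stress enters through dimensionless coefficients Ks in [0, 1] driven by
the root-zone depletion fraction p = Dr/TAW between an upper threshold
(stress onset) and a lower threshold (full stress).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .params import CropParams, ParameterError


class CanopyError(ValueError):
    """Invalid canopy input."""


# Hsiao-form LAI -> CC conversion constants for wheat.
_CC_SCALE = 1.005
_CC_K = 0.6
_CC_POW = 1.2

# Fractional senescence offset in the decline curve (see cc_senescence).
_SEN_OFFSET = 0.05

PHASES = ("pre-emergence", "growth", "full", "senescence")


@dataclass
class CanopyState:
    """Current cover, developmental phase and days spent in that phase."""

    cc: float = 0.0
    phase: str = "pre-emergence"
    days_in_phase: int = 0
    cc_at_senescence: float = 0.0   # reference cover when decline started

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise CanopyError(f"unknown phase {self.phase!r}")


def ks_stress(p: float, p_upper: float, p_lower: float, shape: float) -> float:
    """Water-stress coefficient from the depletion fraction p = Dr/TAW.

    Ks = 1 below the upper threshold, 0 beyond the lower threshold, and a
    convex exponential transition in between:

        Ks = 1 - (exp(s_rel*shape) - 1) / (exp(shape) - 1),
        s_rel = (p - p_upper) / (p_lower - p_upper).
    """
    if not 0.0 <= p_upper <= p_lower <= 1.0:
        raise ParameterError(
            f"stress thresholds out of order: upper={p_upper}, lower={p_lower}")
    if shape <= 0:
        raise ParameterError("stress curve shape must be positive")
    if p <= p_upper:
        return 1.0
    if p >= p_lower:
        return 0.0
    s_rel = (p - p_upper) / (p_lower - p_upper)
    return 1.0 - (math.exp(s_rel * shape) - 1.0) / (math.exp(shape) - 1.0)


def cc_growth_step(state: CanopyState, crop: CropParams,
                   ks_expansion: float, dt: float = 1.0) -> CanopyState:
    """One day of canopy expansion at effective rate ks * cgc.

    Exponential growth cc*exp(ks*cgc*dt) up to half the maximum cover,
    then exponential approach ccx - (ccx - cc)*exp(-ks*cgc*dt); a fully
    stressed day (ks = 0) freezes the canopy.
    """
    cc = state.cc
    if ks_expansion > 0 and cc > 0:
        rate = ks_expansion * crop.cgc * dt
        if cc <= crop.ccx / 2.0:
            cc = cc * math.exp(rate)
        else:
            cc = crop.ccx - (crop.ccx - cc) * math.exp(-rate)
        cc = min(cc, crop.ccx)
    phase = "full" if crop.ccx - cc < 1e-9 else "growth"
    return replace(state, cc=cc, phase=phase, days_in_phase=state.days_in_phase + 1)


def cc_senescence(cc_ref: float, cdc: float, t: float) -> float:
    """Cover after ``t`` days of senescence starting from ``cc_ref``.

    cc(t) = cc_ref * [1 - 0.05*(exp((cdc/cc_ref)*t) - 1)], floored at 0;
    the decline accelerates so the canopy reaches zero in finite time.
    """
    if cc_ref <= 1e-6:
        return 0.0
    exponent = min((cdc / cc_ref) * t, 700.0)  # guard exp overflow for tiny covers
    cc = cc_ref * (1.0 - _SEN_OFFSET * (math.exp(exponent) - 1.0))
    return max(0.0, cc)


def cc_senescence_step(state: CanopyState, crop: CropParams) -> CanopyState:
    """Advance one day of the senescence phase.

    The decline curve is anchored at the cover held when senescence began
    (ccx for an unstressed season).
    """
    if state.phase != "senescence":
        ref = state.cc
        new = replace(state, phase="senescence", days_in_phase=1, cc_at_senescence=ref,
                      cc=cc_senescence(ref, crop.cdc, 1.0))
        return new
    t = state.days_in_phase + 1
    cc = cc_senescence(state.cc_at_senescence, crop.cdc, t)
    return replace(state, cc=cc, days_in_phase=t)


def stress_senescence_decay(cc: float, crop: CropParams, ks_senescence: float) -> float:
    """Early canopy loss under severe water shortage during the growth phase.

    When the senescence stress coefficient drops below 1 the cover decays
    at the decline rate scaled by (1 - Ks): cc * exp(-(1-Ks)*cdc).
    """
    if ks_senescence >= 1.0:
        return cc
    return cc * math.exp(-(1.0 - ks_senescence) * crop.cdc)


# ---------------------------------------------------------------------------
# LAI <-> CC conversions and manual LAI
# ---------------------------------------------------------------------------

def cc_from_lai(lai: float) -> float:
    """Hsiao-form conversion cc = min(1, 1.005*(1 - exp(-0.6*lai))**1.2)."""
    if lai < 0:
        raise CanopyError(f"negative LAI: {lai}")
    return min(1.0, _CC_SCALE * (1.0 - math.exp(-_CC_K * lai)) ** _CC_POW)


def lai_from_cc(cc: float) -> float:
    """Inverse of :func:`cc_from_lai` on [0, 1)."""
    if not 0.0 <= cc < 1.0:
        raise CanopyError(f"cc must lie in [0, 1) for inversion, got {cc}")
    inner = (cc / _CC_SCALE) ** (1.0 / _CC_POW)
    if inner >= 1.0:
        raise CanopyError(f"cc={cc} is in the capped region; LAI undefined")
    return -math.log(1.0 - inner) / _CC_K


def manual_lai(leaf_lengths, leaf_widths, plant_density: float,
               shape_factor: float = 0.83) -> float:
    """LAI from straightedge leaf measurements.

    ``leaf_lengths``/``leaf_widths`` are per-plant sequences (m) of leaf
    length and maximum width; LAI = density * mean over plants of
    sum(shape_factor * L * B), in m2 leaf per m2 ground.
    """
    if plant_density <= 0:
        raise CanopyError("plant density must be positive")
    if len(leaf_lengths) != len(leaf_widths):
        raise CanopyError("per-plant leaf arrays differ in length")
    if not leaf_lengths:
        return 0.0
    per_plant = []
    for ls, bs in zip(leaf_lengths, leaf_widths):
        ls, bs = np.asarray(ls, dtype=float), np.asarray(bs, dtype=float)
        if ls.shape != bs.shape:
            raise CanopyError("leaf length/width arrays differ in shape")
        per_plant.append(float(np.sum(shape_factor * ls * bs)))
    return plant_density * float(np.mean(per_plant))
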