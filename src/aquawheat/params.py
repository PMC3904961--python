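"""Crop parameter set for winter wheat.

One flat dataclass carries the canopy, root, production and phenology
parameters of the water-driven crop model.  Defaults are the calibrated
winter wheat values for the Xiaotangshan (Beijing) field trials; every
field is overridable, so other cultivars or sites are a matter of
constructing a different instance (or loading one from YAML).

Units and conventions
---------------------
* Canopy cover (CC) is a fraction of ground area in [0, 1].
* CGC and CDC are fractional rates per calendar day.  The source trials
  report them as "%/day" (0.03 and 0.09); a literal 0.0003 d-1 cannot
  reach full cover within a wheat season, so they are interpreted as
  fractional daily rates 0.03 d-1 and 0.09 d-1.
* Depletion thresholds p_* are fractions of total available water (TAW).
* Phenology is expressed in calendar days after sowing.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields


class ParameterError(ValueError):
    """Raised when a crop or soil parameter violates its constraints."""


@dataclass
class CropParams:
    # -- canopy development --------------------------------------------------
    cc0: float = 0.045          # initial cover at emergence (fraction)
    ccx: float = 0.90           # maximum canopy cover (fraction)
    cgc: float = 0.03           # canopy growth coefficient (d-1)
    cdc: float = 0.09           # canopy decline coefficient at senescence (d-1)

    # -- water-stress response ----------------------------------------------
    p_exp_upper: float = 0.20   # leaf expansion: stress starts (fraction of TAW)
    p_exp_lower: float = 0.65   # leaf expansion: full stress
    shape_exp: float = 3.0      # expansion stress curve shape
    p_sto: float = 0.65         # stomatal closure: stress starts
    shape_sto: float = 3.0
    p_sen: float = 0.70         # early senescence: stress starts
    shape_sen: float = 3.0

    # -- roots ----------------------------------------------------------------
    zr_min: float = 0.3         # minimum effective rooting depth (m)
    zr_max: float = 1.2         # maximum effective rooting depth (m)
    root_shape: float = 1.5     # shape factor of root-zone expansion
    max_root_day: int = 150     # days after sowing at which zr_max is reached

    # -- production ----------------------------------------------------------
    ncwp: float = 15.0          # normalized crop water productivity (g m-2)
    kctr: float = 1.1           # transpiration coefficient at full canopy
    hi0: float = 0.46           # reference harvest index (fraction)
    hi_increase_max: float = 0.15  # allowable upward HI adjustment (fraction of hi0)
    t_pol_min: float = 5.0      # deg C below which pollination starts to fail
    t_pol_max: float = 35.0     # deg C above which pollination starts to fail

    # -- phenology (calendar days after sowing) -------------------------------
    emergence_day: int = 7
    flowering_day: int = 232
    flowering_length: int = 10
    senescence_day: int = 236
    maturity_day: int = 250

    # -- temperature limits (carried for completeness; calendar-day mode) -----
    base_temp: float = 0.0
    upper_temp: float = 26.0

    # -- switches --------------------------------------------------------------
    cc_adjustment: bool = True  # micro-advection adjustment of cover in Tr

    def __post_init__(self) -> None:
        if not 0.0 < self.cc0 < self.ccx <= 1.0:
            raise ParameterError(
                f"need 0 < cc0 < ccx <= 1, got cc0={self.cc0}, ccx={self.ccx}")
        if not 0.0 <= self.p_exp_upper < self.p_exp_lower <= 1.0:
            raise ParameterError("expansion thresholds out of order")
        for name in ("p_sto", "p_sen"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {p}")
        if not 0.0 < self.hi0 < 1.0:
            raise ParameterError(f"hi0 must lie in (0, 1), got {self.hi0}")
        if not 13.0 <= self.ncwp <= 20.0:
            raise ParameterError(
                f"ncwp={self.ncwp} outside the C3 default range [13, 20] g m-2")
        if self.zr_min <= 0 or self.zr_max < self.zr_min:
            raise ParameterError("rooting depths out of order")
        if not (0 <= self.emergence_day < self.senescence_day <= self.maturity_day):
            raise ParameterError("phenology days out of order")

    def replace(self, **changes) -> "CropParams":
        d = asdict(self)
        d.update(changes)
        return CropParams(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CropParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown crop parameter(s): {sorted(unknown)}")
        return cls(**d)
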