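"""Model evaluation statistics and water-use efficiency.

Goodness of fit between simulated and observed series is summarised by
the Nash-Sutcliffe model efficiency E = 1 - SSE/SST, the root mean
square error, and an ordinary least-squares line whose R-squared is the
squared Pearson correlation of the pairs (matching how the regression
panels of crop-model evaluations are read).

Water-use efficiency converts seasonal transpiration depth (mm) to a
water volume (1 mm = 10 m3 ha-1) and divides biomass and grain yield by
it:

    Biomass-WUE = BY / (10 T)   [kg m-3]
    Grain-WUE   = GY / (10 T)   [kg m-3]
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MM_TO_M3_PER_HA = 10.0


class EvaluationError(ValueError):
    """Undefined statistic for the given series."""


@dataclass(frozen=True)
class EvalStats:
    """Fit summary for one simulated-vs-observed comparison."""

    slope: float
    intercept: float
    r2: float
    rmse: float
    e: float
    n: int


@dataclass(frozen=True)
class WueResult:
    """Biomass and grain water-use efficiency, kg per m3 of transpired water."""

    biomass_wue: float
    grain_wue: float
    transpiration_m3_per_ha: float


def _pair(sim, obs) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(sim, dtype=float)
    o = np.asarray(obs, dtype=float)
    if s.shape != o.shape:
        raise EvaluationError(f"length mismatch: {s.shape} vs {o.shape}")
    return s, o


def nash_sutcliffe(sim, obs) -> float:
    """Nash-Sutcliffe model efficiency E = 1 - sum(S-O)^2 / sum(O-Obar)^2."""
    s, o = _pair(sim, obs)
    if s.size < 2:
        raise EvaluationError("need at least 2 points for E")
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        raise EvaluationError("observations are constant; E undefined")
    return 1.0 - float(np.sum((s - o) ** 2)) / sst


def rmse(sim, obs) -> float:
    """Root mean square error, in the units of the data."""
    s, o = _pair(sim, obs)
    if s.size == 0:
        raise EvaluationError("empty series")
    return float(np.sqrt(np.mean((s - o) ** 2)))


def linear_fit(x, y) -> EvalStats:
    """OLS line y ~ x with R2 = squared Pearson correlation.

    The returned EvalStats carries the regression slope/intercept/R2
    together with RMSE and E of y against x treated as paired series.
    """
    xa, ya = _pair(x, y)
    if xa.size < 2:
        raise EvaluationError("need at least 2 points for a line")
    if np.ptp(xa) == 0:
        raise EvaluationError("x is constant; slope undefined")
    res = stats.linregress(xa, ya)
    return EvalStats(slope=float(res.slope), intercept=float(res.intercept),
                     r2=float(res.rvalue) ** 2, rmse=rmse(xa, ya),
                     e=nash_sutcliffe(xa, ya) if np.ptp(ya) > 0 else float("nan"),
                     n=int(xa.size))


def fit_stats(sim, obs) -> EvalStats:
    """Full simulated-vs-observed summary (obs regressed on sim)."""
    s, o = _pair(sim, obs)
    ls = linear_fit(s, o)
    return EvalStats(slope=ls.slope, intercept=ls.intercept, r2=ls.r2,
                     rmse=rmse(s, o), e=nash_sutcliffe(s, o), n=int(s.size))


def wue(biomass_kg_ha: float, grain_kg_ha: float,
        transpiration_mm: float) -> WueResult:
    """Water-use efficiency from seasonal totals.

    Transpiration depth in mm is converted to m3 ha-1 (x10); efficiencies
    come out in kg of dry matter per m3 of transpired water.
    """
    if transpiration_mm <= 0:
        raise EvaluationError("seasonal transpiration must be positive")
    if biomass_kg_ha < 0 or grain_kg_ha < 0:
        raise EvaluationError("yields must be non-negative")
    vol = transpiration_mm * MM_TO_M3_PER_HA
    return WueResult(biomass_wue=biomass_kg_ha / vol,
                     grain_wue=grain_kg_ha / vol,
                     transpiration_m3_per_ha=vol)


def evaluation_table(groups: Iterable[tuple[str, Sequence, Sequence]]) -> pd.DataFrame:
    """Per-group and pooled fit statistics.

    ``groups`` yields (name, sim, obs) triples (e.g. one per planting
    date); the result has one row per group plus a ``pooled`` row over
    all pairs weighted equally.
    """
    groups = list(groups)
    if not groups:
        raise EvaluationError("no groups to evaluate")
    rows, all_sim, all_obs = [], [], []
    for name, sim, obs in groups:
        st = fit_stats(sim, obs)
        rows.append({"group": name, "slope": st.slope, "intercept": st.intercept,
                     "r2": st.r2, "rmse": st.rmse, "e": st.e, "n": st.n})
        all_sim.extend(np.asarray(sim, dtype=float))
        all_obs.extend(np.asarray(obs, dtype=float))
    if len(groups) > 1:
        st = fit_stats(all_sim, all_obs)
        rows.append({"group": "pooled", "slope": st.slope, "intercept": st.intercept,
                     "r2": st.r2, "rmse": st.rmse, "e": st.e, "n": st.n})
    else:
        pooled = dict(rows[0])
        pooled["group"] = "pooled"
        rows.append(pooled)
    return pd.DataFrame(rows)
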