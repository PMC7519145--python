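"""Ecophysiological wheat phenology: thermal time, vernalization, photoperiod,
and growth-stage (Zadoks GS00–GS92) simulation from daily weather.

Development is driven by daily accumulation of thermal time computed from a
piece-wise linear response with cardinal temperatures (base, optimum, maximum).
Between emergence (GS10) and the beginning of stem elongation (GS30) the daily
increment is reduced by photoperiod and vernalization factors; between GS30 and
heading (GS55) by photoperiod only (with a higher base temperature); after
heading only temperature matters. Flag-leaf (GS39) is back-calculated from
heading using the phyllotherm (the thermal interval between successive leaves).

All stage positions are tracked on a common axis of unmodified base-0 °C-days
since sowing; thresholds for GS30/GS55 apply to the modified accumulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weather import WeatherSeries

__all__ = [
    "CultivarPhenologyParams",
    "GrowthStageSchedule",
    "thermal_time_daily",
    "vernalizing_day",
    "photoperiod_factor",
    "vernalization_factor",
    "phyllotherm",
    "simulate_growth_stages",
    "STAGES",
]

STAGES = ("GS00", "GS10", "GS30", "GS39", "GS55", "GS65", "GS75", "GS92")

#: Cardinal temperatures (°C) of the development response before GS30.
T_BASE, T_OPT, T_MAX = 0.0, 24.0, 35.0
#: Base temperature from GS30 to GS55.
T_BASE_GS30 = 3.5
#: Vernalizing-day cardinal temperatures (°C).
V_TMIN, V_TOPT, V_TMAX = -1.0, 6.0, 17.0
#: Photoperiod response (hours): before GS30 and after GS30.
P_BASE, P_OPT = 6.3, 20.0
P_BASE_GS30 = 7.7
#: Vernalization requirement (vernalizing days).
V_BASE, V_SAT = 0.0, 45.0
#: Thermal time from sowing to emergence (°C-days), unmodified.
EMERGENCE_TT = 150.0
#: Phyllotherm bounds (°C-days per leaf).
PHYLL_MIN, PHYLL_MAX = 66.0, 120.0


def thermal_time_daily(
    tmean: float | np.ndarray,
    base: float = T_BASE,
    opt: float = T_OPT,
    tmax: float = T_MAX,
) -> float | np.ndarray:
    """Daily thermal-time increment (°C-days), piece-wise linear in Tmean.

    Zero at or below ``base`` and at or above ``tmax``; rises linearly to a
    peak of ``opt - base`` at the optimum; falls linearly back to zero at the
    maximum.
    """
    t = np.asarray(tmean, dtype=float)
    peak = opt - base
    rising = (t - base) * (t > base) * (t <= opt)
    falling = peak * (tmax - t) / (tmax - opt) * (t > opt) * (t < tmax)
    out = rising + falling
    return float(out) if np.ndim(tmean) == 0 else out


def vernalizing_day(tmean: float | np.ndarray) -> float | np.ndarray:
    """Vernalizing-day increment in [0, 1], piece-wise linear in Tmean.

    Zero at ≤ −1 °C or ≥ 17 °C, equal to 1 at 6 °C, linear between.
    """
    t = np.asarray(tmean, dtype=float)
    rising = (t - V_TMIN) / (V_TOPT - V_TMIN) * (t > V_TMIN) * (t <= V_TOPT)
    falling = (V_TMAX - t) / (V_TMAX - V_TOPT) * (t > V_TOPT) * (t < V_TMAX)
    out = rising + falling
    return float(out) if np.ndim(tmean) == 0 else out


def photoperiod_factor(
    p_h: float | np.ndarray, p_base: float = P_BASE, p_opt: float = P_OPT
) -> float | np.ndarray:
    """PF = (P_H − P_base)/(P_opt − P_base), clamped to [0, 1]."""
    if p_opt <= p_base:
        raise ValueError("p_opt must exceed p_base")
    out = np.clip((np.asarray(p_h, dtype=float) - p_base) / (p_opt - p_base), 0.0, 1.0)
    return float(out) if np.ndim(p_h) == 0 else out


def vernalization_factor(
    vdd_cum: float | np.ndarray, v_base: float = V_BASE, v_sat: float = V_SAT
) -> float | np.ndarray:
    """VF = (VDD − V_base)/(V_sat − V_base), clamped to [0, 1]."""
    if vdd_cum is None or np.any(np.asarray(vdd_cum) < 0):
        raise ValueError("cumulative vernalizing days must be >= 0")
    out = np.clip((np.asarray(vdd_cum, dtype=float) - v_base) / (v_sat - v_base), 0.0, 1.0)
    return float(out) if np.ndim(vdd_cum) == 0 else out


def phyllotherm(
    p_gs10: float,
    p_gs00: float,
    gdd_00_10: float,
    rg_00_10: float,
    d_gs10: float,
) -> float:
    """Phyllotherm (°C-days per leaf), bounded to [66, 120].

    Parameters: photoperiods (hours) at emergence and sowing, thermal time
    (°C-days) and mean daily global radiation (joules·cm⁻²) between sowing and
    emergence, and plant density at emergence (plants·m⁻²).
    """
    if rg_00_10 <= 0:
        raise ValueError("mean global radiation over GS00-GS10 must be positive")
    dp = 2.54 * (p_gs10 - p_gs00)
    denom = gdd_00_10 + 14.396 / rg_00_10 + 1.0104
    if dp == 0:
        return PHYLL_MAX  # 100/(dp/denom) -> +inf
    raw = (100.0 / (dp / denom)) * 0.9393 + 0.000379 * d_gs10
    return float(np.clip(raw, PHYLL_MIN, PHYLL_MAX))


@dataclass
class CultivarPhenologyParams:
    """Cultivar-dependent development requirements.

    ``gdd_pv``: modified °C-days (photoperiod- and vernalization-reduced)
    from emergence to GS30. ``gdd_p``: modified °C-days (photoperiod-reduced,
    base 3.5 °C) from GS30 to GS55. ``density_gs10``: plants/m² at emergence.
    """

    gdd_pv: float = 220.0
    gdd_p: float = 280.0
    density_gs10: float = 250.0
    name: str = "default"

    def __post_init__(self) -> None:
        if self.gdd_pv <= 0 or self.gdd_p <= 0:
            raise ValueError("GDD parameters must be positive")


@dataclass
class GrowthStageSchedule:
    """Dates and cumulative °C-days since sowing of the eight growth stages."""

    dates: dict[str, pd.Timestamp]
    tt_cum: dict[str, float]  # base-0 unmodified °C-days since sowing
    phyll: float

    def phase_bounds(self, start: str, end: str) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.dates[start], self.dates[end]

    def validate(self) -> None:
        order = [self.tt_cum[s] for s in STAGES]
        for a, b in zip(order, order[1:]):
            if b < a - 1e-9:
                raise ValueError("growth stages out of order")
        if not (PHYLL_MIN <= self.phyll <= PHYLL_MAX):
            raise ValueError("phyllotherm out of bounds")


class SeasonTooShortError(RuntimeError):
    def __init__(self, last_stage: str):
        self.last_stage = last_stage
        super().__init__(
            f"weather series ends before crop maturity; last stage reached: {last_stage}"
        )


def simulate_growth_stages(
    w: WeatherSeries,
    cp: CultivarPhenologyParams,
    sowing_date,
) -> GrowthStageSchedule:
    """Simulate GS00–GS92 dates from daily weather and cultivar parameters.

    Sowing is GS00. Emergence (GS10) occurs at 150 unmodified °C-days from
    sowing. Emergence→GS30 accumulates base-0 thermal time multiplied by
    min(PF, VF); GS30→GS55 accumulates base-3.5 °C thermal time multiplied by
    PF (P_base 7.7 h). GS39 is back-calculated as GS55 − 1.2·Phyll °C-days.
    After GS55 development depends on temperature only: GS65 from the heading-
    anthesis relation, GS75/GS92 at +430/+770 °C-days from heading.
    """
    sow = pd.Timestamp(sowing_date)
    df = w.data
    idx0 = df.index[df["date"] == sow]
    if len(idx0) == 0:
        raise ValueError(f"sowing date {sow.date()} not covered by weather series")
    i0 = int(idx0[0])

    tmean = df["tmean"].to_numpy()[i0:]
    photo = df["photoperiod"].to_numpy()[i0:]
    dates = df["date"].to_numpy()[i0:]
    n = len(tmean)

    tt0 = thermal_time_daily(tmean)  # unmodified base-0 increments
    tt0[0] = 0.0  # development starts the day after sowing
    cum0 = np.cumsum(tt0)  # cum0[d] = °C-days through end of day d
    vdd = vernalizing_day(tmean)
    vdd[0] = 0.0
    vdd_cum = np.cumsum(vdd)

    def first_at(arr: np.ndarray, threshold: float, start: int) -> int | None:
        hits = np.nonzero(arr[start:] >= threshold - 1e-9)[0]
        return int(hits[0]) + start if len(hits) else None

    # --- emergence ---
    d10 = first_at(cum0, EMERGENCE_TT, 0)
    if d10 is None:
        raise SeasonTooShortError("GS00")

    # --- GS10 -> GS30: min(PF, VF)-modified accumulation ---
    pf1 = photoperiod_factor(photo, P_BASE, P_OPT)
    vf = vernalization_factor(vdd_cum)
    mod1 = tt0 * np.minimum(pf1, vf)
    mod1[: d10 + 1] = 0.0
    d30 = first_at(np.cumsum(mod1), cp.gdd_pv, d10 + 1)
    if d30 is None:
        raise SeasonTooShortError("GS10")

    # --- GS30 -> GS55: PF-modified, base 3.5 °C ---
    pf2 = photoperiod_factor(photo, P_BASE_GS30, P_OPT)
    mod2 = thermal_time_daily(tmean, T_BASE_GS30, T_OPT, T_MAX) * pf2
    mod2[: d30 + 1] = 0.0
    d55 = first_at(np.cumsum(mod2), cp.gdd_p, d30 + 1)
    if d55 is None:
        raise SeasonTooShortError("GS30")

    # --- phyllotherm and GS39 (back-calculated, °C-days since sowing) ---
    rg_mean = float(df["radiation"].to_numpy()[i0 : i0 + d10 + 1].mean())
    phyll = phyllotherm(photo[d10], photo[0], float(cum0[d10]), rg_mean, cp.density_gs10)
    gs55_tt = float(cum0[d55])
    gs39_tt = gs55_tt - 1.2 * phyll
    d39 = first_at(cum0, gs39_tt, 0)
    if d39 is None:  # pragma: no cover - gs39_tt <= gs55_tt always reachable
        d39 = d55

    # --- post-heading: temperature only ---
    gs65_tt = gs55_tt + 0.05899 * (1.596 * gs55_tt - 93.61)
    gs75_tt = gs55_tt + 430.0
    gs92_tt = gs55_tt + 770.0
    d65 = first_at(cum0, gs65_tt, d55)
    d75 = first_at(cum0, gs75_tt, d55)
    d92 = first_at(cum0, gs92_tt, d55)
    if d65 is None:
        raise SeasonTooShortError("GS55")
    if d75 is None:
        raise SeasonTooShortError("GS65")
    if d92 is None:
        raise SeasonTooShortError("GS75")

    day = {
        "GS00": 0, "GS10": d10, "GS30": d30, "GS39": d39,
        "GS55": d55, "GS65": d65, "GS75": d75, "GS92": d92,
    }
    tt = {
        "GS00": 0.0, "GS10": float(cum0[d10]), "GS30": float(cum0[d30]),
        "GS39": gs39_tt, "GS55": gs55_tt, "GS65": gs65_tt,
        "GS75": gs75_tt, "GS92": gs92_tt,
    }
    sched = GrowthStageSchedule(
        dates={s: pd.Timestamp(dates[day[s]]) for s in STAGES},
        tt_cum=tt,
        phyll=phyll,
    )
    return sched
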