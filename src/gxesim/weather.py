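"""Daily weather series: container, astronomical daylength, and a stochastic
weather generator.

The generator stands in for historical weather-station records: seasonal
sinusoids for temperature and global radiation with AR(1) daily anomalies,
and rainfall as a two-state Markov occurrence chain with gamma-distributed
wet-day amounts. It is meant to produce series with realistic seasonal
structure for a temperate (French) wheat-growing climate, not to emulate any
particular station.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream

__all__ = ["WeatherSeries", "ClimateParams", "daylength", "generate_weather", "read_weather_csv"]


def daylength(latitude: float, day_of_year: int | np.ndarray) -> float | np.ndarray:
    """Astronomical daylength (hours) from the solar-declination formula.

    Parameters
    ----------
    latitude : degrees, must satisfy ``|latitude| < 66.5`` (no polar day/night)
    day_of_year : 1..366
    """
    if abs(latitude) >= 66.5:
        raise ValueError(f"latitude {latitude} outside modeled range (|lat| < 66.5)")
    doy = np.asarray(day_of_year, dtype=float)
    decl = np.deg2rad(23.45) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    lat = np.deg2rad(latitude)
    cos_h0 = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    hours = 2.0 * np.rad2deg(np.arccos(cos_h0)) / 15.0
    if np.ndim(day_of_year) == 0:
        return float(hours)
    return hours


@dataclass
class WeatherSeries:
    """Daily weather at one location.

    ``data`` columns: date (datetime64), tmin, tmax (°C), radiation
    (joules·cm⁻², daily global), rain (mm). ``tmean`` and the daily
    photoperiod ``photoperiod`` (hours) are derived on construction.
    """

    data: pd.DataFrame
    latitude: float
    location: str = ""

    def __post_init__(self) -> None:
        df = self.data.copy()
        df["date"] = pd.to_datetime(df["date"])
        df = df.sort_values("date").reset_index(drop=True)
        deltas = df["date"].diff().dropna()
        if len(deltas) and not (deltas == pd.Timedelta(days=1)).all():
            raise ValueError("weather dates must be contiguous daily records")
        if (df["tmin"] > df["tmax"]).any():
            bad = df.loc[df["tmin"] > df["tmax"], "date"].iloc[0]
            raise ValueError(f"tmin > tmax on {bad.date()}")
        if (df["radiation"] < 0).any():
            raise ValueError("negative global radiation")
        if (df["rain"] < 0).any():
            raise ValueError("negative rainfall")
        df["tmean"] = 0.5 * (df["tmin"] + df["tmax"])
        doy = df["date"].dt.dayofyear.to_numpy()
        df["photoperiod"] = daylength(self.latitude, doy)
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def slice(self, start: pd.Timestamp, end: pd.Timestamp) -> pd.DataFrame:
        """Rows with start <= date < end."""
        m = (self.data["date"] >= start) & (self.data["date"] < end)
        return self.data.loc[m]

    def to_csv(self, path) -> None:
        cols = ["date", "tmin", "tmax", "radiation", "rain"]
        out = self.data[cols].copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


def read_weather_csv(path, latitude: float, location: str = "") -> WeatherSeries:
    """Read a daily weather CSV (columns date, tmin, tmax, radiation, rain)."""
    df = pd.read_csv(path, parse_dates=["date"])
    return WeatherSeries(df[["date", "tmin", "tmax", "radiation", "rain"]], latitude, location)


@dataclass
class ClimateParams:
    """Seasonal climate for the weather generator (temperate defaults).

    Temperatures in °C, radiation in joules·cm⁻²·day⁻¹, rain in mm.
    The seasonal cycle peaks in mid-July (day-of-year ``doy_peak``).
    """

    tmean_annual: float = 11.0
    t_amplitude: float = 7.5
    diurnal_range: float = 8.0
    t_anom_sd: float = 2.2
    t_ar1: float = 0.7
    rg_mean: float = 1400.0
    rg_amplitude: float = 1050.0
    rg_anom_sd: float = 180.0
    rain_p_wet_after_dry: float = 0.28
    rain_p_wet_after_wet: float = 0.58
    rain_gamma_shape: float = 0.75
    rain_gamma_scale: float = 7.0
    doy_peak: int = 197
    # regional structure: southern locations are persistently warmer, and a
    # season-wide anomaly is shared by all locations in the same harvest year
    # (a hot/dry year is hot/dry across the whole network)
    lat_ref: float = 46.5
    t_lat_gradient: float = 0.6  # °C per degree latitude, south warmer
    t_year_anom_sd: float = 1.0
    rg_year_anom_sd: float = 110.0
    rain_year_log_sd: float = 0.35  # drought/wet years scale rain occurrence


def generate_weather(
    latitude: float,
    year: int,
    params: ClimateParams | None = None,
    seed: int = 0,
    location: str = "",
    start: str | None = None,
    end: str | None = None,
) -> WeatherSeries:
    """Generate one harvest-year of daily weather ending in ``year``.

    The series runs from 1 September of ``year - 1`` through 30 September of
    ``year`` (configurable via ``start``/``end``), covering sowing through
    maturity of a winter-wheat crop with margin for cold northern seasons. With ``t_anom_sd = rg_anom_sd = 0`` and
    both rain probabilities 0 the series is exactly the seasonal sinusoid.
    """
    p = params or ClimateParams()
    rng = stream(seed, f"weather:{location}:{year}")
    rng_year = stream(seed, f"year-anomaly:{year}")  # shared across locations
    t0 = pd.Timestamp(start) if start else pd.Timestamp(year=year - 1, month=9, day=1)
    t1 = pd.Timestamp(end) if end else pd.Timestamp(year=year, month=9, day=30)
    dates = pd.date_range(t0, t1, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    n = len(dates)

    t_year = rng_year.normal(0.0, p.t_year_anom_sd) if p.t_year_anom_sd > 0 else 0.0
    rg_year = rng_year.normal(0.0, p.rg_year_anom_sd) if p.rg_year_anom_sd > 0 else 0.0
    rain_year = (
        float(np.clip(np.exp(rng_year.normal(0.0, p.rain_year_log_sd)), 0.4, 1.8))
        if p.rain_year_log_sd > 0
        else 1.0
    )
    t_loc = p.t_lat_gradient * (p.lat_ref - latitude)
    season = -np.cos(2.0 * np.pi * (doy - p.doy_peak + 182.625) / 365.25)
    tmean_clim = p.tmean_annual + t_loc + t_year + p.t_amplitude * season
    rg_clim = np.maximum(p.rg_mean + rg_year + p.rg_amplitude * season, 50.0)

    def _ar1(sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros(n)
        innov_sd = sd * np.sqrt(1.0 - p.t_ar1**2)
        e = rng.normal(0.0, innov_sd, size=n)
        out = np.empty(n)
        out[0] = rng.normal(0.0, sd)
        for t in range(1, n):
            out[t] = p.t_ar1 * out[t - 1] + e[t]
        return out

    tmean = tmean_clim + _ar1(p.t_anom_sd)
    half = 0.5 * p.diurnal_range
    tmin = tmean - half
    tmax = tmean + half
    rg = np.maximum(rg_clim + _ar1(p.rg_anom_sd), 0.0)

    rain = np.zeros(n)
    if p.rain_p_wet_after_dry > 0 or p.rain_p_wet_after_wet > 0:
        u = rng.random(n)
        amounts = rng.gamma(p.rain_gamma_shape, p.rain_gamma_scale, size=n)
        wet = False
        for t in range(n):
            p_wet = p.rain_p_wet_after_wet if wet else p.rain_p_wet_after_dry
            wet = u[t] < min(p_wet * rain_year, 0.95)
            if wet:
                rain[t] = max(amounts[t], 0.1)

    df = pd.DataFrame(
        {"date": dates, "tmin": tmin, "tmax": tmax, "radiation": rg, "rain": rain}
    )
    return WeatherSeries(df, latitude=latitude, location=location)
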