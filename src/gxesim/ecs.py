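"""Environmental covariates (ECs): per-phase weather summaries.

The crop cycle is divided into phases bounded by the simulated growth stages;
within each phase a catalogue of summary statistics describes temperature,
radiation and water availability. The default schema uses the seven intervals
between the eight growth stages plus the whole cycle (8 phases) × 13 statistics
≈ 104 covariates — the same structure (phases × temperature/radiation/water
summaries) as operational wheat EC catalogues, with configurable definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .phenology import STAGES, GrowthStageSchedule, thermal_time_daily
from .weather import WeatherSeries

__all__ = ["ECSchema", "ECMatrix", "compute_ecs", "build_ec_matrix", "STATISTICS"]


def _max_dry_spell(rain: np.ndarray) -> float:
    dry = rain < 0.1
    best = run = 0
    for d in dry:
        run = run + 1 if d else 0
        best = max(best, run)
    return float(best)


#: Statistic id -> function of a phase slice of daily weather.
STATISTICS: dict[str, callable] = {
    "tmin_mean": lambda d: float(d["tmin"].mean()),
    "tmax_mean": lambda d: float(d["tmax"].mean()),
    "tmean_mean": lambda d: float(d["tmean"].mean()),
    "gdd_sum": lambda d: float(np.sum(thermal_time_daily(d["tmean"].to_numpy()))),
    "days_tmax_gt25": lambda d: float((d["tmax"] > 25.0).sum()),
    "days_tmax_gt30": lambda d: float((d["tmax"] > 30.0).sum()),
    "days_tmin_lt0": lambda d: float((d["tmin"] < 0.0).sum()),
    "rg_sum": lambda d: float(d["radiation"].sum()),
    "rg_mean": lambda d: float(d["radiation"].mean()),
    "rain_sum": lambda d: float(d["rain"].sum()),
    "rain_days": lambda d: float((d["rain"] >= 0.1).sum()),
    # simple climatic water balance: rain minus a radiation-scaled
    # evapotranspiration proxy (0.4 mm per 1000 J·cm⁻² of global radiation)
    "water_balance": lambda d: float(d["rain"].sum() - 0.4 * d["radiation"].sum() / 1000.0),
    "max_dry_spell": lambda d: _max_dry_spell(d["rain"].to_numpy()),
}

_DEFAULT_PHASES: tuple[tuple[str, str, str], ...] = tuple(
    (f"{a}_{b}", a, b) for a, b in zip(STAGES, STAGES[1:])
) + (("cycle", "GS00", "GS92"),)


@dataclass
class ECSchema:
    """Ordered catalogue of (phase, statistic) pairs.

    ``phases``: list of (name, start stage, end stage); ``statistics``: list
    of statistic ids from :data:`STATISTICS`.
    """

    phases: tuple[tuple[str, str, str], ...] = _DEFAULT_PHASES
    statistics: tuple[str, ...] = tuple(STATISTICS)

    def __post_init__(self) -> None:
        unknown = set(self.statistics) - set(STATISTICS)
        if unknown:
            raise ValueError(f"unknown statistics: {sorted(unknown)}")

    @property
    def columns(self) -> list[str]:
        return [f"{ph}:{st}" for ph, _, _ in self.phases for st in self.statistics]

    def __len__(self) -> int:
        return len(self.phases) * len(self.statistics)

    def to_yaml(self, path) -> None:
        payload = {
            "phases": [list(p) for p in self.phases],
            "statistics": list(self.statistics),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "ECSchema":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            phases=tuple(tuple(p) for p in payload["phases"]),
            statistics=tuple(payload["statistics"]),
        )


def compute_ecs(
    w: WeatherSeries, gs: GrowthStageSchedule, schema: ECSchema | None = None
) -> pd.Series:
    """EC row for one environment: schema statistics over each phenological phase.

    Phase windows are [start-stage date, end-stage date); a zero-length phase
    yields zeros for its statistics, with a warning.
    """
    schema = schema or ECSchema()
    values: list[float] = []
    for name, a, b in schema.phases:
        t0, t1 = gs.dates[a], gs.dates[b]
        sl = w.slice(t0, t1)
        if len(sl) == 0:
            warnings.warn(f"phase {name} has zero length; its ECs set to 0")
            values.extend(0.0 for _ in schema.statistics)
            continue
        values.extend(STATISTICS[st](sl) for st in schema.statistics)
    return pd.Series(values, index=schema.columns, dtype=float)


@dataclass
class ECMatrix:
    """Environment × EC matrix, centered and scaled.

    ``raw`` holds the unstandardized values; ``W`` the centered/scaled matrix
    used in Ω = WW′/q. Zero-variance columns are dropped (with a warning).
    Rows are keyed by environment id (``year:location`` by default).
    """

    raw: pd.DataFrame
    W: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if self.raw.index.duplicated().any():
            raise ValueError("duplicate environment keys in EC matrix")
        sd = self.raw.std(ddof=1)
        dead = sd.index[(sd == 0) | sd.isna()]
        if len(dead):
            warnings.warn(f"dropping {len(dead)} zero-variance EC columns")
        kept = self.raw.drop(columns=dead)
        self.W = (kept - kept.mean()) / kept.std(ddof=1)

    @property
    def q(self) -> int:
        return self.W.shape[1]

    def to_csv(self, path) -> None:
        self.raw.to_csv(path, index_label="environment")

    @classmethod
    def from_csv(cls, path) -> "ECMatrix":
        return cls(pd.read_csv(path, index_col="environment"))


def build_ec_matrix(
    env_weather: dict[str, tuple[WeatherSeries, GrowthStageSchedule]],
    schema: ECSchema | None = None,
) -> ECMatrix:
    """Assemble and standardize the EC matrix for a set of environments."""
    schema = schema or ECSchema()
    rows = {key: compute_ecs(w, gs, schema) for key, (w, gs) in env_weather.items()}
    raw = pd.DataFrame(rows).T
    raw.index.name = "environment"
    return ECMatrix(raw)
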