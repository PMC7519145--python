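"""Monte Carlo simulation of cultivar performance at target locations.

Given a model fitted with the target grid carried as missing-response rows,
the platform evaluates, for every year i, location j, cultivar k and posterior
sample s, the prediction function

    f(i, j, k, θ_s) = μ(s) + L_j(s) + V_k(s) + w_ijk(s) + VW_ijk(s)

— only the terms learnable from past data or predictable from SNPs and ECs;
year and year–location effects are excluded because future years' effects
cannot be predicted. Averaging f over historical weather years and posterior
samples yields forecasts that smooth out year-to-year variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gibbs import PosteriorSamples, predict_terms

__all__ = ["SimulationGrid", "SimulatedPhenotypes", "simulate_performance", "summarize_simulation"]

#: terms entering the prediction function (year and year-location excluded)
PREDICTION_TERMS = ("L", "V", "W", "VW")


@dataclass
class SimulationGrid:
    """Target locations × historical weather years × candidate cultivars."""

    years: list
    locations: list
    cultivars: list

    def __post_init__(self) -> None:
        for name in ("years", "locations", "cultivars"):
            vals = getattr(self, name)
            if len(set(vals)) != len(vals) or not vals:
                raise ValueError(f"{name} must be non-empty and unique")

    @property
    def n_cells(self) -> int:
        return len(self.years) * len(self.locations) * len(self.cultivars)

    def n_values(self, n_samples: int) -> int:
        """Planned simulated-value count: |years|·|locations|·|cultivars|·B."""
        return self.n_cells * int(n_samples)

    def cell_keys(self) -> list[tuple]:
        return [
            (y, l, c) for y in self.years for l in self.locations for c in self.cultivars
        ]

    def grid_records(self) -> pd.DataFrame:
        """Missing-response rows to append to the training records before
        fitting (the design-augmentation prediction mechanism)."""
        rows = self.cell_keys()
        df = pd.DataFrame(rows, columns=["year", "location", "cultivar"])
        df["yield"] = np.nan
        return df

    def row_indices(self, ps: PosteriorSamples) -> np.ndarray:
        """Index of each grid cell among the stored posterior rows."""
        pos = {k: i for i, k in enumerate(ps.row_keys)}
        idx = []
        missing = []
        for key in self.cell_keys():
            if key in pos:
                idx.append(pos[key])
            else:
                missing.append(key)
        if missing:
            raise KeyError(
                f"{len(missing)} grid cells absent from the fitted design "
                f"(e.g. {missing[0]}); re-fit the model with grid_records() "
                "appended as missing-response rows"
            )
        return np.array(idx, dtype=int)


@dataclass
class SimulatedPhenotypes:
    """f(i,j,k,θ_s) values on the grid (tons/ha); residual and year/year-
    location draws are never included."""

    grid: SimulationGrid
    values: np.ndarray  # (n_years, n_locations, n_cultivars, B)

    def __post_init__(self) -> None:
        expect = (
            len(self.grid.years), len(self.grid.locations), len(self.grid.cultivars),
        )
        if self.values.shape[:3] != expect:
            raise ValueError("values shape does not match grid")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite simulated values")

    @property
    def n_values(self) -> int:
        return int(self.values.size)

    @property
    def B(self) -> int:
        return self.values.shape[3]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            for dim in ("years", "locations", "cultivars"):
                f.create_dataset(dim, data=np.array([str(v) for v in getattr(self.grid, dim)], dtype="S"))


def simulate_performance(
    ps: PosteriorSamples, grid: SimulationGrid, chunk_samples: int = 2000
) -> SimulatedPhenotypes:
    """Evaluate the prediction function over the full grid × sample space.

    The grid cells must have been carried as missing-response rows in the
    fitted design. Evaluation streams over posterior-sample chunks; the
    returned object holds the (years, locations, cultivars, B) array.
    """
    idx = grid.row_indices(ps)
    terms = [t for t in PREDICTION_TERMS if t in ps.effects]
    shape = (len(grid.years), len(grid.locations), len(grid.cultivars), ps.B)
    out = np.empty(shape, dtype=float)
    flat = out.reshape(-1, ps.B)
    for s0 in range(0, ps.B, chunk_samples):
        s1 = min(s0 + chunk_samples, ps.B)
        sub = _predict_sample_slice(ps, idx, terms, s0, s1)
        flat[:, s0:s1] = sub.T
    return SimulatedPhenotypes(grid=grid, values=out)


def _predict_sample_slice(ps, idx, terms, s0, s1) -> np.ndarray:
    out = np.repeat(ps.mu[s0:s1, None], len(idx), axis=1)
    for t in terms:
        out += ps.effects[t][s0:s1][:, idx]
    return out


def summarize_simulation(
    sp: SimulatedPhenotypes,
    by: str = "cultivar-location",
    quantiles: tuple[float, ...] = (0.25, 0.75),
) -> pd.DataFrame:
    """Summary table of simulated yields.

    ``by="cultivar-location"``: one row per cultivar × location (mean, median
    and quantiles across years × samples). ``by="cultivar-location-year"``:
    one row per cell (across samples only).
    """
    g = sp.grid
    rows = []
    if by == "cultivar-location":
        for j, loc in enumerate(g.locations):
            for k, cult in enumerate(g.cultivars):
                vals = sp.values[:, j, k, :].ravel()
                rows.append(_stats_row({"cultivar": cult, "location": loc}, vals, quantiles))
    elif by == "cultivar-location-year":
        for i, yr in enumerate(g.years):
            for j, loc in enumerate(g.locations):
                for k, cult in enumerate(g.cultivars):
                    vals = sp.values[i, j, k, :]
                    rows.append(
                        _stats_row(
                            {"cultivar": cult, "location": loc, "year": yr}, vals, quantiles
                        )
                    )
    else:
        raise ValueError(f"unknown grouping {by!r}")
    return pd.DataFrame(rows)


def _stats_row(keys: dict, vals: np.ndarray, quantiles) -> dict:
    row = dict(keys)
    row["mean"] = float(np.mean(vals))
    row["median"] = float(np.median(vals))
    for q in quantiles:
        row[f"q{int(round(q * 100)):02d}"] = float(np.quantile(vals, q))
    return row


def means_matrix(sp: SimulatedPhenotypes) -> pd.DataFrame:
    """Cultivar × location matrix of simulated-average yields (mean over
    years × samples) — the input to means-stability analyses."""
    m = sp.values.mean(axis=(0, 3))  # (locations, cultivars)
    return pd.DataFrame(m.T, index=sp.grid.cultivars, columns=sp.grid.locations)
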