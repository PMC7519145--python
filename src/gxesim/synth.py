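"""Synthetic multi-environment trial networks.

The generator emulates the structure of a national post-registration wheat
trial network: un-replicated trials (one record per year–location–cultivar),
a common check present everywhere plus a random subset of the cultivar roster
per trial (partial connectivity), SNP genotypes, per-location daily weather,
phenology-derived ECs, and phenotypes assembled from the full reaction-norm
model

    y_ijk = μ + Y_i + L_j + YL_ij + V_k + w_ijk + VW_ijk + ε_ijk

with V = Xa (a ~ N(0, σ²_V/p)), w = Wβ/√q (β ~ N(0, σ²_EC I)), and VW drawn
from the Hadamard interaction kernel. Default generating variances are the
full-model posterior means estimated on the real network (Y 0.175, L 0.525,
YL 0.916, V 0.184, EC 0.140, V×EC 0.054, ε 0.170) around a grand mean of
9.49 t/ha, so synthetic phenotypes live on the scale of French wheat yields.

All randomness flows from one master seed through named child streams
(weather, genotypes, effects, ...), so each component is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_seed, stream
from .ecs import ECMatrix, ECSchema, build_ec_matrix
from .kernels import CovarianceStructure, environmental_relationship, genomic_relationship
from .phenology import CultivarPhenologyParams, GrowthStageSchedule, simulate_growth_stages
from .trialdata import GenotypeMatrix, TrialDataset, impute_and_standardize, qc_filter_snps
from .weather import ClimateParams, WeatherSeries, generate_weather

__all__ = ["GeneratorConfig", "TrueEffects", "SyntheticData", "generate_dataset"]

#: Full-model generating variances (Y, L, YL, V, EC, V×EC, eps).
DEFAULT_VARIANCES = {
    "Y": 0.175,
    "L": 0.525,
    "YL": 0.916,
    "V": 0.184,
    "W": 0.140,
    "VW": 0.054,
    "eps": 0.170,
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic network."""

    years: int = 10
    locations: int = 30
    cultivars: int = 100
    snps: int = 1000
    presence_prob: float = 0.09  # non-check cultivar presence per trial
    mu: float = 9.49
    variances: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VARIANCES))
    seed: int = 0
    missing_rate: float = 0.02  # missing SNP calls before imputation
    het_rate: float = 0.03  # residual heterozygosity of inbred lines
    base_year: int = 2000
    latitude_range: tuple[float, float] = (43.5, 49.5)
    sowing_month: int = 10
    sowing_day: int = 15
    climate: ClimateParams = field(default_factory=ClimateParams)
    ec_schema: ECSchema = field(default_factory=ECSchema)

    def __post_init__(self) -> None:
        for c in (self.years, self.locations, self.cultivars, self.snps):
            if c < 1:
                raise ValueError("counts must be >= 1")
        if any(v < 0 for v in self.variances.values()):
            raise ValueError("variances must be non-negative")
        missing = set(DEFAULT_VARIANCES) - set(self.variances)
        if missing:
            raise ValueError(f"missing variance components: {sorted(missing)}")


@dataclass
class TrueEffects:
    """Generating effect values and variances, for recovery experiments."""

    mu: float
    variances: dict[str, float]
    Y: pd.Series
    L: pd.Series
    YL: pd.Series  # indexed by (year, location)
    V: pd.Series  # cultivar genetic values Xa
    snp_effects: np.ndarray
    w_env: pd.Series  # environment-level EC effect, indexed by (year, location)
    VW: np.ndarray  # record-level interaction values
    eps: np.ndarray  # record-level noise
    fw_slopes: pd.Series | None = None


@dataclass
class SyntheticData:
    """One generated trial network with everything downstream steps need."""

    dataset: TrialDataset
    genotypes: GenotypeMatrix  # QC'd, imputed, standardized (X populated)
    ecs: ECMatrix
    truth: TrueEffects
    weather: dict[tuple, WeatherSeries]  # (year, location) -> series
    schedules: dict[tuple, GrowthStageSchedule]
    latitudes: dict[str, float]
    phenology_params: dict[str, CultivarPhenologyParams]
    config: GeneratorConfig

    @property
    def G(self) -> CovarianceStructure:
        return genomic_relationship(self.genotypes.X)

    @property
    def Om(self) -> CovarianceStructure:
        W = self.ecs.W.copy()
        W.index = [_env_key(i) for i in W.index]
        return environmental_relationship(W)


def _env_key(label: str) -> tuple:
    year, loc = label.split(":")
    return int(year), loc


def _generate_genotypes(cfg: GeneratorConfig) -> GenotypeMatrix:
    rng = stream(cfg.seed, "genotypes")
    freqs = rng.uniform(0.1, 0.9, size=cfg.snps)
    # inbred wheat lines: essentially homozygous (0/2) with a small residual
    # heterozygosity, so synthetic SNPs pass the het < 10% QC filter
    dos = 2.0 * rng.binomial(1, freqs, size=(cfg.cultivars, cfg.snps)).astype(float)
    het = rng.random(dos.shape) < cfg.het_rate
    dos[het] = 1.0
    if cfg.missing_rate > 0:
        mask = rng.random(dos.shape) < cfg.missing_rate
        dos[mask] = np.nan
    names = [f"C{i:03d}" for i in range(cfg.cultivars)]
    snp_ids = [f"snp{j:05d}" for j in range(cfg.snps)]
    gm = GenotypeMatrix(pd.DataFrame(dos, index=names, columns=snp_ids))
    return impute_and_standardize(qc_filter_snps(gm))


def generate_dataset(cfg: GeneratorConfig | None = None) -> SyntheticData:
    """Generate a full synthetic trial network under ``cfg``.

    Weather → growth stages → ECs are produced by the phenology machinery;
    phenotypes are assembled from the full reaction-norm model with the
    configured generating variances. Bit-reproducible under ``cfg.seed``.
    """
    cfg = cfg or GeneratorConfig()
    v = cfg.variances

    genotypes = _generate_genotypes(cfg)
    cults = genotypes.cultivars
    X = genotypes.X.to_numpy()
    p = X.shape[1]

    years = [cfg.base_year + i for i in range(cfg.years)]
    locs = [f"L{j:02d}" for j in range(cfg.locations)]
    rng_geo = stream(cfg.seed, "geography")
    latitudes = {loc: float(rng_geo.uniform(*cfg.latitude_range)) for loc in locs}

    # cultivar phenology parameters (used for the reference EC schedules and
    # available to pipeline consumers)
    rng_ph = stream(cfg.seed, "phenology")
    phen_params = {
        c: CultivarPhenologyParams(
            gdd_pv=float(rng_ph.uniform(180.0, 260.0)),
            gdd_p=float(rng_ph.uniform(240.0, 320.0)),
            name=c,
        )
        for c in cults
    }
    ref_params = CultivarPhenologyParams(name="reference")

    # --- weather, growth stages, ECs (trial-level) ----------------------
    weather: dict[tuple, WeatherSeries] = {}
    schedules: dict[tuple, GrowthStageSchedule] = {}
    env_inputs = {}
    for y in years:
        for loc in locs:
            w = generate_weather(
                latitudes[loc], y, cfg.climate,
                seed=child_seed(cfg.seed, "weather"), location=loc,
            )
            sowing = pd.Timestamp(year=y - 1, month=cfg.sowing_month, day=cfg.sowing_day)
            gs = simulate_growth_stages(w, ref_params, sowing)
            weather[(y, loc)] = w
            schedules[(y, loc)] = gs
            env_inputs[f"{y}:{loc}"] = (w, gs)
    ecs = build_ec_matrix(env_inputs, cfg.ec_schema)
    bad = ecs.W.columns[~np.isfinite(ecs.W.to_numpy()).all(axis=0)].tolist()
    if bad:
        raise ValueError(f"degenerate EC columns (non-finite after scaling): {bad[:5]}")
    env_keys = [_env_key(i) for i in ecs.W.index]

    # --- trial rosters: common check + random subsets -------------------
    rng_net = stream(cfg.seed, "network")
    check = cults[0]
    rows = []
    for y, loc in env_keys:
        present = [check] + [c for c in cults[1:] if rng_net.random() < cfg.presence_prob]
        rows.extend((y, loc, c) for c in present)
    # every cultivar appears somewhere: place absentees in random trials
    seen = {c for _, _, c in rows}
    for c in cults:
        if c not in seen:
            y, loc = env_keys[int(rng_net.integers(len(env_keys)))]
            rows.append((y, loc, c))
    rec = pd.DataFrame(rows, columns=["year", "location", "cultivar"])
    n = len(rec)

    # --- effects --------------------------------------------------------
    rng_eff = stream(cfg.seed, "effects")
    a = rng_eff.normal(0.0, np.sqrt(v["V"] / p), size=p) if v["V"] > 0 else np.zeros(p)
    V = pd.Series(X @ a, index=cults)
    Y_eff = pd.Series(rng_eff.normal(0.0, np.sqrt(v["Y"]), size=len(years)), index=years)
    L_eff = pd.Series(rng_eff.normal(0.0, np.sqrt(v["L"]), size=len(locs)), index=locs)
    YL_eff = pd.Series(
        rng_eff.normal(0.0, np.sqrt(v["YL"]), size=len(env_keys)),
        index=pd.MultiIndex.from_tuples(env_keys),
    )
    Wmat = ecs.W.to_numpy()
    q = Wmat.shape[1]
    beta = rng_eff.normal(0.0, np.sqrt(v["W"]), size=q) if v["W"] > 0 else np.zeros(q)
    w_env = pd.Series(Wmat @ beta / np.sqrt(q), index=pd.MultiIndex.from_tuples(env_keys))

    env_pos = {k: i for i, k in enumerate(env_keys)}
    cult_pos = {c: i for i, c in enumerate(cults)}
    ei = rec.apply(lambda r: env_pos[(r["year"], r["location"])], axis=1).to_numpy()
    ci = rec["cultivar"].map(cult_pos).to_numpy()

    if v["VW"] > 0:
        # exact draw from the Hadamard kernel via its Khatri-Rao factorization:
        # Cov = (Fg Fg') # (Fo Fo') with row factors Fg[k] ⊗ Fo[env], so
        # VW_i = Fg[k_i]' H Fo[env_i] with H ~ N(0, σ² I) gives the right law
        Fg = genomic_relationship(genotypes.X).factor
        Fo = environmental_relationship(ecs.W).factor
        H = rng_eff.normal(0.0, np.sqrt(v["VW"]), size=(Fg.shape[1], Fo.shape[1]))
        VW = np.einsum("ij,jk,ik->i", Fg[ci], H, Fo[ei])
    else:
        VW = np.zeros(n)
    eps = rng_eff.normal(0.0, np.sqrt(v["eps"]), size=n) if v["eps"] > 0 else np.zeros(n)

    y_vals = (
        cfg.mu
        + Y_eff[rec["year"]].to_numpy()
        + L_eff[rec["location"]].to_numpy()
        + YL_eff.to_numpy()[ei]
        + V.to_numpy()[ci]
        + w_env.to_numpy()[ei]
        + VW
        + eps
    )
    rec["yield"] = y_vals
    dataset = TrialDataset(rec)

    truth = TrueEffects(
        mu=cfg.mu, variances=dict(v), Y=Y_eff, L=L_eff, YL=YL_eff, V=V,
        snp_effects=a, w_env=w_env, VW=VW, eps=eps,
    )
    return SyntheticData(
        dataset=dataset, genotypes=genotypes, ecs=ecs, truth=truth,
        weather=weather, schedules=schedules, latitudes=latitudes,
        phenology_params=phen_params, config=cfg,
    )
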