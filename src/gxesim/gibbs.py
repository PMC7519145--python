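"""Bayesian variance-component fitting of reaction-norm G×E models.

The model family (all with intercept μ and Gaussian noise ε ~ N(0, σ²_ε)):

- ``TL``       y = μ + Y_i + L_j + YL_ij + V_k + ε            (identity kernels)
- ``GW``       y = μ + V_k + w_ijk + ε                        (V ~ G, w ~ Ω)
- ``GW-GxW``   adds VW_ijk with the Hadamard kernel (Z_g G Z_g′)#Ω
- ``TGW``      y = μ + Y_i + L_j + YL_ij + V_k + w_ijk + ε
- ``TGW-GxW``  the full model: TGW + VW_ijk

Every random term is Gaussian with covariance K σ²_t and is carried in the
sampler through a factor B with K = BB′ (from the truncated eigendecomposition
of K, or an incidence matrix for IID terms), so the effect is u = Bδ with
δ ~ N(0, I σ²_t). A one-time SVD of the observed-row block of B rotates δ into
coordinates whose full conditional is diagonal, giving an exact blocked Gibbs
update at matrix-vector cost per iteration. Variances get scaled-inverse-χ²
updates; μ has a flat prior.

Scaled-inverse-χ² convention: a draw is σ² = (S0 + SS)/χ²_{df0 + n}, so S0 is
scale × df and the prior mode is S0/(df0 + 2). The default priors follow the
same rule mainstream Bayesian genomic-prediction software (e.g. BGLR) uses:
the prior modes split var(y) between signal and noise according to an R²
parameter.

Rows whose response is missing contribute no likelihood; their effect values
are drawn from the conditional distribution given all observed data (the
identified directions) plus the prior (unidentified directions). Carrying
prediction targets as missing-response rows is the mechanism by which new
year–location–cultivar combinations are predicted and simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream
from .kernels import CovarianceStructure

__all__ = [
    "RandomTerm",
    "ModelDesign",
    "PriorSpec",
    "PosteriorSamples",
    "MODEL_TERMS",
    "build_model",
    "default_priors",
    "gibbs_fit",
    "variance_components",
    "predict_terms",
]

MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "TL": ("Y", "L", "YL", "V"),
    "GW": ("V", "W"),
    "GW-GxW": ("V", "W", "VW"),
    "TGW": ("Y", "L", "YL", "V", "W"),
    "TGW-GxW": ("Y", "L", "YL", "V", "W", "VW"),
}


@dataclass
class RandomTerm:
    """One Gaussian random term: effect = B δ, δ ~ N(0, I σ²)."""

    name: str
    B: np.ndarray  # n_rows × r factor
    kernel: str = "identity"  # identity | G | Omega | Hadamard

    @property
    def r(self) -> int:
        return self.B.shape[1]


@dataclass
class ModelDesign:
    """Response, random terms and observed/missing row flags for one model."""

    name: str
    y: np.ndarray  # NaN marks missing-response (prediction) rows
    terms: list[RandomTerm]
    row_keys: list  # (year, location, cultivar) per row

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.y)
        for t in self.terms:
            if t.B.shape[0] != n:
                raise ValueError(f"term {t.name}: factor rows != design rows")
        if len(self.row_keys) != n:
            raise ValueError("row_keys length mismatch")

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.y)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    def term(self, name: str) -> RandomTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"term {name!r} not in model {self.name}")


def _indicator(values, levels: list) -> np.ndarray:
    pos = {v: i for i, v in enumerate(levels)}
    values = list(values)
    Z = np.zeros((len(values), len(levels)))
    Z[np.arange(len(values)), [pos[v] for v in values]] = 1.0
    return Z


def build_model(
    name: str,
    records: pd.DataFrame,
    G: CovarianceStructure | None = None,
    Om: CovarianceStructure | None = None,
) -> ModelDesign:
    """Assemble a ModelDesign for one of the five named models.

    ``records`` is long format with columns year, location, cultivar, yield;
    NaN yields flag prediction rows. ``G`` is the genomic kernel over
    cultivars; ``Om`` the environmental kernel over environment keys
    ``(year, location)`` (trial-level ECs, expanded to record level here).
    """
    key = name.replace("×", "x").replace("G×W", "GxW")
    if key not in MODEL_TERMS:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(MODEL_TERMS)}")
    needed = MODEL_TERMS[key]
    df = records.reset_index(drop=True)
    years = sorted(df["year"].unique().tolist())
    locs = sorted(df["location"].unique().tolist())
    trials = sorted(set(zip(df["year"], df["location"])))
    cults = sorted(df["cultivar"].unique().tolist())
    env_of_row = list(zip(df["year"], df["location"]))

    if ("W" in needed or "VW" in needed) and Om is None:
        raise ValueError(f"model {key} requires an EC-derived environmental kernel")
    if key != "TL" and G is None:
        raise ValueError(f"model {key} requires a genomic kernel")

    Zc = _indicator(df["cultivar"].to_numpy(), cults)
    terms: list[RandomTerm] = []
    if "Y" in needed:
        terms.append(RandomTerm("Y", _indicator(df["year"].to_numpy(), years)))
    if "L" in needed:
        terms.append(RandomTerm("L", _indicator(df["location"].to_numpy(), locs)))
    if "YL" in needed:
        terms.append(RandomTerm("YL", _indicator(env_of_row, trials)))
    if key == "TL":
        terms.append(RandomTerm("V", Zc))
    else:
        missing_c = set(cults) - set(G.row_keys)
        if missing_c:
            raise ValueError(f"cultivars missing from genomic kernel: {sorted(missing_c)[:5]}")
        Bg = G.factor[G.row_index(cults)]
        terms.append(RandomTerm("V", Zc @ Bg, kernel="G"))
    if "W" in needed:
        missing_e = set(env_of_row) - set(map(tuple, Om.row_keys))
        if missing_e:
            raise ValueError(f"environments missing from EC kernel: {sorted(missing_e)[:5]}")
        Ze = _indicator(env_of_row, list(map(tuple, Om.row_keys)))
        terms.append(RandomTerm("W", Ze @ Om.factor, kernel="Omega"))
    if "VW" in needed:
        ZGZ = (Zc @ G.K[np.ix_(G.row_index(cults), G.row_index(cults))]) @ Zc.T
        ZOZ = Ze @ Om.K @ Ze.T
        Kvw = CovarianceStructure(ZGZ * ZOZ, row_keys=list(range(len(df))), tag="Hadamard")
        terms.append(RandomTerm("VW", Kvw.factor, kernel="Hadamard"))

    row_keys = list(zip(df["year"], df["location"], df["cultivar"]))
    return ModelDesign(name=key, y=df["yield"].to_numpy(dtype=float), terms=terms, row_keys=row_keys)


@dataclass
class PriorSpec:
    """Scaled-inverse-χ² hyperparameters per variance (S0 = scale × df)."""

    df0: dict[str, float]
    S0: dict[str, float]

    def __post_init__(self) -> None:
        for name in self.S0:
            if self.df0[name] <= 0 or self.S0[name] <= 0:
                raise ValueError(f"prior for {name}: df0 and S0 must be positive")


def default_priors(design: ModelDesign, r2: float = 0.5, df0: float = 5.0) -> PriorSpec:
    """BGLR-style default priors: split var(y) between terms and noise by R².

    Residual: S0 = var(y)(1−R²)(df0+2). Each of the m terms: S0 =
    var(y)·R²/m·(df0+2)/mean-diag(K), where mean-diag(K) is the average
    implied prior variance of the term at the observed rows.
    """
    y = design.y[design.observed]
    if len(y) < 2:
        raise ValueError("need at least 2 observed responses")
    vy = float(np.var(y, ddof=1))
    if vy == 0:
        raise ValueError("response has zero variance")
    if not (0 < r2 < 1):
        raise ValueError("R² must be in (0, 1)")
    m = len(design.terms)
    S0 = {"eps": vy * (1.0 - r2) * (df0 + 2.0)}
    dfs = {"eps": df0}
    for t in design.terms:
        mean_diag = float(np.mean(np.sum(t.B[design.observed] ** 2, axis=1)))
        if mean_diag <= 0:
            raise ValueError(f"term {t.name}: degenerate kernel (zero mean diagonal)")
        S0[t.name] = vy * r2 / m * (df0 + 2.0) / mean_diag
        dfs[t.name] = df0
    return PriorSpec(df0=dfs, S0=S0)


@dataclass
class PosteriorSamples:
    """Thinned posterior draws of μ, all variances and (optionally) all
    effect vectors at the stored rows."""

    model: str
    mu: np.ndarray  # (B,)
    variances: dict[str, np.ndarray]  # term name (and "eps") -> (B,)
    effects: dict[str, np.ndarray]  # term name -> (B, n_stored)
    row_keys: list
    observed: np.ndarray
    n_iter: int
    burn_in: int
    thin: int
    seed: int

    @property
    def B(self) -> int:
        return len(self.mu)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs.update(
                model=self.model, n_iter=self.n_iter, burn_in=self.burn_in,
                thin=self.thin, seed=self.seed,
            )
            f.create_dataset("mu", data=self.mu)
            f.create_dataset("observed", data=self.observed)
            f.create_dataset(
                "row_keys", data=np.array([repr(k) for k in self.row_keys], dtype="S")
            )
            gv = f.create_group("variances")
            for k, v in self.variances.items():
                gv.create_dataset(k, data=v)
            ge = f.create_group("effects")
            for k, v in self.effects.items():
                ge.create_dataset(k, data=v)

    @classmethod
    def from_hdf5(cls, path) -> "PosteriorSamples":
        import ast
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                model=str(f.attrs["model"]),
                mu=f["mu"][:],
                variances={k: f["variances"][k][:] for k in f["variances"]},
                effects={k: f["effects"][k][:] for k in f["effects"]},
                row_keys=[ast.literal_eval(s.decode()) for s in f["row_keys"][:]],
                observed=f["observed"][:].astype(bool),
                n_iter=int(f.attrs["n_iter"]),
                burn_in=int(f.attrs["burn_in"]),
                thin=int(f.attrs["thin"]),
                seed=int(f.attrs["seed"]),
            )


def expected_samples(n_iter: int, burn_in: int, thin: int) -> int:
    """Number of stored samples for a chain: (n_iter − burn_in) // thin."""
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    return (n_iter - burn_in) // thin


def gibbs_fit(
    design: ModelDesign,
    priors: PriorSpec | None = None,
    n_iter: int = 6000,
    burn_in: int = 1000,
    thin: int = 5,
    seed: int = 0,
    store_effects: bool = True,
    store_rows: np.ndarray | None = None,
    fix_variances: dict[str, float] | None = None,
    fix_mu: float | None = None,
    verbose: bool = False,
) -> PosteriorSamples:
    """Blocked Gibbs sampler for a ModelDesign.

    ``store_rows``: indices of rows whose effect draws are kept (default all).
    ``fix_variances``/``fix_mu`` hold parameters at known values (used by the
    conjugate closed-form checks). Fully reproducible under ``seed``.
    """
    priors = priors or default_priors(design)
    B_count = expected_samples(n_iter, burn_in, thin)
    rng = stream(seed, "gibbs")
    obs = design.observed
    y_obs = design.y[obs]
    n_obs = len(y_obs)
    if store_rows is None:
        store_rows = np.arange(len(design.y))
    store_rows = np.asarray(store_rows, dtype=int)
    fix_variances = fix_variances or {}

    # --- one-time per-term factorizations -------------------------------
    class _TermState:
        __slots__ = ("name", "P", "s", "Q", "r_full", "B_store", "gamma", "sigma2", "f_obs", "fixed")

    states: list[_TermState] = []
    for t in design.terms:
        st = _TermState()
        st.name = t.name
        B_obs = t.B[obs]
        P, s, Qt = np.linalg.svd(B_obs, full_matrices=False)
        keep = s > (s[0] * 1e-12 if len(s) and s[0] > 0 else 0)
        st.P, st.s, st.Q = P[:, keep], s[keep], Qt[keep].T
        st.r_full = t.r
        st.B_store = t.B[store_rows] if store_effects else None
        st.gamma = np.zeros(len(st.s))
        st.sigma2 = fix_variances.get(t.name, priors.S0[t.name] / (priors.df0[t.name] + 2.0))
        st.f_obs = np.zeros(n_obs)
        st.fixed = t.name in fix_variances
        if len(st.s) == 0:
            raise ValueError(f"term {t.name}: factor has no signal at observed rows")
        states.append(st)

    mu = float(np.mean(y_obs)) if fix_mu is None else float(fix_mu)
    sigma2_eps = fix_variances.get("eps", priors.S0["eps"] / (priors.df0["eps"] + 2.0))
    e = y_obs - mu  # residual at observed rows

    out_mu = np.empty(B_count)
    out_var: dict[str, np.ndarray] = {st.name: np.empty(B_count) for st in states}
    out_var["eps"] = np.empty(B_count)
    out_eff: dict[str, np.ndarray] = (
        {st.name: np.empty((B_count, len(store_rows))) for st in states} if store_effects else {}
    )

    kept = 0
    for it in range(1, n_iter + 1):
        # intercept (flat prior)
        if fix_mu is None:
            e += mu
            mu = float(np.mean(e)) + rng.normal() * np.sqrt(sigma2_eps / n_obs)
            e -= mu

        for st in states:
            e += st.f_obs
            c = st.P.T @ e
            prec = st.s**2 / sigma2_eps + 1.0 / st.sigma2
            mean = (st.s * c / sigma2_eps) / prec
            st.gamma = mean + rng.standard_normal(len(st.s)) / np.sqrt(prec)
            st.f_obs = st.P @ (st.s * st.gamma)
            e -= st.f_obs
            if not st.fixed:
                ss = float(st.gamma @ st.gamma)
                df = priors.df0[st.name] + len(st.gamma)
                st.sigma2 = (priors.S0[st.name] + ss) / rng.chisquare(df)
                if not np.isfinite(st.sigma2) or st.sigma2 <= 0:
                    raise FloatingPointError(
                        f"non-finite variance for term {st.name} at iteration {it}"
                    )

        if "eps" not in fix_variances:
            sigma2_eps = (priors.S0["eps"] + float(e @ e)) / rng.chisquare(
                priors.df0["eps"] + n_obs
            )

        if it > burn_in and (it - burn_in) % thin == 0 and kept < B_count:
            out_mu[kept] = mu
            out_var["eps"][kept] = sigma2_eps
            for st in states:
                out_var[st.name][kept] = st.sigma2
                if store_effects:
                    delta = st.Q @ st.gamma
                    if st.r_full > st.Q.shape[1]:
                        # unidentified directions: prior draw, projected off
                        # the identified subspace
                        eta = rng.standard_normal(st.r_full) * np.sqrt(st.sigma2)
                        delta = delta + eta - st.Q @ (st.Q.T @ eta)
                    out_eff[st.name][kept] = st.B_store @ delta
            kept += 1

    return PosteriorSamples(
        model=design.name,
        mu=out_mu,
        variances=out_var,
        effects=out_eff,
        row_keys=[design.row_keys[i] for i in store_rows],
        observed=obs[store_rows],
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
    )


def variance_components(ps: PosteriorSamples, ci: float = 0.95) -> pd.DataFrame:
    """Posterior mean and credible interval per variance component."""
    lo, hi = (1.0 - ci) / 2.0, 1.0 - (1.0 - ci) / 2.0
    rows = {}
    for name, draws in ps.variances.items():
        rows[name] = {
            "mean": float(np.mean(draws)),
            "lower": float(np.quantile(draws, lo)),
            "upper": float(np.quantile(draws, hi)),
        }
    return pd.DataFrame(rows).T[["mean", "lower", "upper"]]


def predict_terms(
    ps: PosteriorSamples,
    rows: np.ndarray | list,
    terms: list[str] | None = None,
    include_mu: bool = True,
) -> np.ndarray:
    """Per-sample sum of the requested terms' effects at the given rows.

    ``rows``: indices into the stored rows. Returns an array (B, len(rows)).
    """
    rows = np.asarray(rows, dtype=int)
    if terms is None:
        terms = list(ps.effects)
    out = np.zeros((ps.B, len(rows)))
    if include_mu:
        out += ps.mu[:, None]
    for name in terms:
        if name not in ps.effects:
            raise KeyError(f"term {name!r} not stored in posterior (model {ps.model})")
        out += ps.effects[name][:, rows]
    return out
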