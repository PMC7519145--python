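"""Post-simulation analytics: Finlay–Wilkinson mean-stability regression,
slope-stability cross-validation, the site-regression (SREG) biplot and
means-matrix clustering.

The FW regression models the mean of cultivar k at location j as

    M_jk = b_0k + E_j + E_j·b_1k + δ_jk

fitted in two steps: (i) a random-effects additive fit estimates environment
means Ẽ_j; (ii) a Bayesian regression with genomic covariance G on both the
cultivar intercepts b_0 and slope deviations b_1, with E_j fixed at Ẽ_j.
In this parameterization b_1k is the deviation from the common regression on
E_j; the total FW slope is 1 + b_1k (reported both ways).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.stats

from ._rng import stream
from .gibbs import ModelDesign, RandomTerm, default_priors, gibbs_fit
from .kernels import CovarianceStructure
from .validate import ChainConfig

__all__ = [
    "FWResult",
    "SREGResult",
    "fw_two_step",
    "fw_stability_cv",
    "sreg_biplot",
    "cluster_means",
]

# A means matrix M is a DataFrame with rows = cultivars, columns = locations;
# NaN cells are allowed for raw/BLUE provenance (a cultivar not tested at a
# location) but not for simulated averages.


@dataclass
class FWResult:
    """Per-cultivar FW coefficients and environment means."""

    coefficients: pd.DataFrame  # intercept, slope_dev, slope_total, sds, identifiable
    env_means: pd.Series  # step-1 Ẽ_j per location
    cultivar_means: pd.Series  # step-1 Ṽ_k
    mu: float
    residuals: pd.DataFrame  # δ_jk at posterior means (cultivar × location)
    fitted: pd.DataFrame

    def to_csv(self, path) -> None:
        self.coefficients.to_csv(path, index_label="cultivar")


def _melt(M: pd.DataFrame) -> pd.DataFrame:
    long = M.stack().rename("value").reset_index()
    long.columns = ["cultivar", "location", "value"]
    return long


def _step1_additive(
    long: pd.DataFrame, chain: ChainConfig, seed: int
) -> tuple[pd.Series, pd.Series, float]:
    """Random-effects additive fit M_jk = μ + Ṽ_k + Ẽ_j + δ̃ via the Gibbs
    machinery (IID cultivar and location effects, flat μ)."""
    cults = sorted(long["cultivar"].unique())
    locs = sorted(long["location"].unique())
    n = len(long)
    Zc = np.zeros((n + len(cults) + len(locs), len(cults)))
    Ze = np.zeros((n + len(cults) + len(locs), len(locs)))
    cpos = {c: i for i, c in enumerate(cults)}
    epos = {l: i for i, l in enumerate(locs)}
    for i, (c, l) in enumerate(zip(long["cultivar"], long["location"])):
        Zc[i, cpos[c]] = 1.0
        Ze[i, epos[l]] = 1.0
    # pseudo-rows expose the level-space draws directly
    for i, c in enumerate(cults):
        Zc[n + i, cpos[c]] = 1.0
    for i, l in enumerate(locs):
        Ze[n + len(cults) + i, epos[l]] = 1.0
    y = np.concatenate([long["value"].to_numpy(), np.full(len(cults) + len(locs), np.nan)])
    keys = (
        list(zip(long["cultivar"], long["location"]))
        + [("__V__", c) for c in cults]
        + [("__E__", l) for l in locs]
    )
    design = ModelDesign(
        name="FW-step1", y=y, terms=[RandomTerm("Vt", Zc), RandomTerm("Et", Ze)], row_keys=keys
    )
    ps = gibbs_fit(
        design, default_priors(design, r2=chain.r2, df0=chain.df0),
        n_iter=chain.n_iter, burn_in=chain.burn_in, thin=chain.thin, seed=seed,
    )
    v_rows = np.arange(n, n + len(cults))
    e_rows = np.arange(n + len(cults), n + len(cults) + len(locs))
    V_t = pd.Series(ps.effects["Vt"][:, v_rows].mean(axis=0), index=cults)
    E_t = pd.Series(ps.effects["Et"][:, e_rows].mean(axis=0), index=locs)
    return V_t, E_t, float(ps.mu.mean())


def fw_two_step(
    M: pd.DataFrame,
    G: CovarianceStructure | None = None,
    chain: ChainConfig | None = None,
    seed: int = 0,
) -> FWResult:
    """Two-step Finlay–Wilkinson regression on a cultivar × location means
    matrix, with genomic covariance on intercepts and slopes when ``G`` is
    given (identity otherwise)."""
    chain = chain or ChainConfig(n_iter=3000, burn_in=500)
    if M.shape[0] < 3 or M.shape[1] < 3:
        raise ValueError("need at least 3 cultivars and 3 locations")
    long = _melt(M)
    cults = sorted(long["cultivar"].unique())
    locs_per_cult = long.groupby("cultivar")["location"].nunique()
    unident = set(locs_per_cult.index[locs_per_cult < 2])
    if unident:
        warnings.warn(f"{len(unident)} cultivar(s) in a single location: slope unidentifiable")

    V_t, E_t, mu1 = _step1_additive(long, chain, seed)

    # ---- step 2: y = μ + b0_k + Ẽ_j (1 + b1_k) + δ, Ẽ fixed ------------
    n = len(long)
    e_vals = E_t[long["location"]].to_numpy()
    y2 = long["value"].to_numpy() - e_vals
    if G is not None:
        missing = set(cults) - set(G.row_keys)
        if missing:
            raise ValueError(f"cultivars missing from G: {sorted(missing)[:5]}")
        Fg = G.factor[G.row_index(cults)]
    else:
        Fg = np.eye(len(cults))
    cpos = {c: i for i, c in enumerate(cults)}
    Zc = np.zeros((n + len(cults), len(cults)))
    for i, c in enumerate(long["cultivar"]):
        Zc[i, cpos[c]] = 1.0
    for i in range(len(cults)):
        Zc[n + i, i] = 1.0  # pseudo-rows: unit "environment" exposes b0, b1
    scale = np.concatenate([e_vals, np.ones(len(cults))])
    B0 = Zc @ Fg
    B1 = scale[:, None] * B0
    y_full = np.concatenate([y2, np.full(len(cults), np.nan)])
    keys = list(zip(long["cultivar"], long["location"])) + [("__coef__", c) for c in cults]
    design = ModelDesign(
        name="FW-step2",
        y=y_full,
        terms=[RandomTerm("b0", B0, kernel="G"), RandomTerm("b1", B1, kernel="G")],
        row_keys=keys,
    )
    ps = gibbs_fit(
        design, default_priors(design, r2=chain.r2, df0=chain.df0),
        n_iter=chain.n_iter, burn_in=chain.burn_in, thin=chain.thin, seed=seed + 1,
    )
    coef_rows = np.arange(n, n + len(cults))
    b0_draws = ps.effects["b0"][:, coef_rows] + ps.mu[:, None]
    b1_draws = ps.effects["b1"][:, coef_rows]
    coefficients = pd.DataFrame(
        {
            "intercept": b0_draws.mean(axis=0),
            "sd_intercept": b0_draws.std(axis=0, ddof=1),
            "slope_dev": b1_draws.mean(axis=0),
            "slope_total": 1.0 + b1_draws.mean(axis=0),
            "sd_slope": b1_draws.std(axis=0, ddof=1),
            "identifiable": [c not in unident for c in cults],
        },
        index=pd.Index(cults, name="cultivar"),
    )
    fitted = pd.DataFrame(index=pd.Index(cults), columns=M.columns, dtype=float)
    for c in cults:
        fitted.loc[c] = (
            coefficients.loc[c, "intercept"]
            + E_t[M.columns].to_numpy() * coefficients.loc[c, "slope_total"]
        )
    residuals = M.loc[cults] - fitted
    return FWResult(
        coefficients=coefficients, env_means=E_t, cultivar_means=V_t, mu=mu1,
        residuals=residuals, fitted=fitted,
    )


def fw_stability_cv(
    means: dict[str, pd.DataFrame],
    G: CovarianceStructure | None = None,
    repeats: int = 100,
    chain: ChainConfig | None = None,
    seed: int = 0,
    max_retries: int = 20,
) -> dict:
    """Twofold slope-stability CV, repeated, for one or more means matrices.

    For every repeat each cultivar's location cells are split into two folds
    (both keeping ≥ 2 cells; bounded resplits, else the cultivar is dropped);
    FW regressions run per fold and the correlation between fold-1 and fold-2
    slopes measures slope stability. Inputs (e.g. raw vs BLUE vs simulated
    means) are compared with paired t-tests and Holm-adjusted p-values.
    """
    from statsmodels.stats.multitest import multipletests

    chain = chain or ChainConfig(n_iter=1500, burn_in=300)
    rng = stream(seed, "fw-cv")
    names = list(means)
    corr = {name: [] for name in names}
    for rep in range(repeats):
        split_seed = int(rng.integers(2**31))
        for name in names:
            M = means[name]
            f1, f2 = _split_cells(M, split_seed, max_retries)
            res1 = fw_two_step(f1, G=G, chain=chain, seed=split_seed)
            res2 = fw_two_step(f2, G=G, chain=chain, seed=split_seed + 7)
            common = res1.coefficients.index.intersection(res2.coefficients.index)
            s1 = res1.coefficients.loc[common, "slope_dev"]
            s2 = res2.coefficients.loc[common, "slope_dev"]
            corr[name].append(float(np.corrcoef(s1, s2)[0, 1]))
    table = pd.DataFrame(corr)
    summary = pd.DataFrame(
        {"mean_r": table.mean(), "se": table.std(ddof=1) / np.sqrt(repeats)}
    )
    pvals, pairs = [], []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pairs.append((a, b))
            pvals.append(float(scipy.stats.ttest_rel(table[a], table[b]).pvalue))
    if pvals:
        adj = multipletests(pvals, method="holm")[1]
    else:
        adj = []
    tests = pd.DataFrame(
        {"pair": [f"{a} vs {b}" for a, b in pairs], "p": pvals, "p_holm": list(adj)}
    )
    return {"correlations": table, "summary": summary, "tests": tests}


def _split_cells(M: pd.DataFrame, seed: int, max_retries: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split each cultivar's non-missing cells into two folds, both ≥ 2."""
    rng = np.random.default_rng(seed)
    A = M.copy()
    B = M.copy()
    dropped = []
    for c in M.index:
        cells = M.columns[M.loc[c].notna()]
        if len(cells) < 4:
            dropped.append(c)
            continue
        for _ in range(max_retries):
            mask = rng.random(len(cells)) < 0.5
            if 2 <= mask.sum() <= len(cells) - 2:
                break
        else:  # deterministic fallback split
            mask = np.arange(len(cells)) % 2 == 0
        A.loc[c, cells[~mask]] = np.nan
        B.loc[c, cells[mask]] = np.nan
    if dropped:
        warnings.warn(f"{len(dropped)} cultivar(s) with <4 cells dropped from FW CV")
        A = A.drop(index=dropped)
        B = B.drop(index=dropped)
    return A, B


@dataclass
class SREGResult:
    """Site-regression (SREG) decomposition of an environment-centered means
    matrix: the first two components give the biplot."""

    singular_values: np.ndarray
    scores: pd.DataFrame  # cultivar scores (PC1, PC2, ...)
    loadings: pd.DataFrame  # location loadings
    variance_explained: np.ndarray

    @property
    def first_two_fraction(self) -> float:
        return float(self.variance_explained[:2].sum())


def sreg_biplot(M: pd.DataFrame) -> SREGResult:
    """SVD of the location-centered cultivar × location means matrix."""
    if M.isna().any().any():
        raise ValueError("SREG requires a complete means matrix")
    centered = M - M.mean(axis=0)  # remove environment (location) means
    U, s, Vt = np.linalg.svd(centered.to_numpy(), full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s[0] > 0 else 0
    if rank < 2:
        raise ValueError("centered means matrix has rank < 2")
    frac = s**2 / np.sum(s**2)
    cols = [f"PC{i+1}" for i in range(len(s))]
    scores = pd.DataFrame(U * s, index=M.index, columns=cols)
    loadings = pd.DataFrame(Vt.T, index=M.columns, columns=cols)
    return SREGResult(
        singular_values=s, scores=scores, loadings=loadings, variance_explained=frac
    )


def cluster_means(M: pd.DataFrame) -> dict:
    """Hierarchical clustering (Euclidean, average linkage) of cultivars and
    locations; returns leaf orders and linkage matrices for heatmap display."""
    if M.isna().any().any():
        raise ValueError("clustering requires a complete means matrix")
    out = {}
    for axis, labels in (("cultivars", M.index), ("locations", M.columns)):
        data = M.to_numpy() if axis == "cultivars" else M.to_numpy().T
        if data.shape[0] < 2:
            out[axis] = {"order": list(labels), "linkage": None}
            continue
        link = scipy.cluster.hierarchy.linkage(data, method="average", metric="euclidean")
        order = scipy.cluster.hierarchy.leaves_list(link)
        out[axis] = {"order": [labels[i] for i in order], "linkage": link}
    return out
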