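"""Prediction-accuracy assessment: leave-trial-out (and leave-cultivar-out)
cross-validation, within-trial correlations, Fisher-z paired model comparison
with letter grouping, and EC-predictiveness validation.

The accuracy metric is the within-year-location Pearson correlation between
posterior-mean predictions and observed yield: within a trial the environment
main effects are constant, so the correlation isolates how well the model
ranks cultivars inside an environment.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from ._rng import stream
from .gibbs import build_model, default_priors, gibbs_fit, predict_terms
from .kernels import CovarianceStructure
from .trialdata import FoldAssignment, TrialDataset

__all__ = [
    "CVResult",
    "ModelComparison",
    "ChainConfig",
    "leave_trial_out_cv",
    "fisher_z",
    "compare_models",
    "validate_ec_predictiveness",
    "trial_blues",
]

MIN_RECORDS_PER_TRIAL = 3  # below this a within-trial correlation is unstable


@dataclass
class ChainConfig:
    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    r2: float = 0.5
    df0: float = 5.0


@dataclass
class CVResult:
    """Per-trial correlation between predictions and observations."""

    model: str
    scheme: str
    table: pd.DataFrame  # columns: year, location, r, n

    def __post_init__(self) -> None:
        if ((self.table["r"] < -1) | (self.table["r"] > 1)).any():
            raise ValueError("correlation outside [-1, 1]")
        if (self.table["n"] < MIN_RECORDS_PER_TRIAL).any():
            raise ValueError("trials with too few records must be dropped")

    @property
    def mean_r(self) -> float:
        return float(self.table["r"].mean())


def leave_trial_out_cv(
    model_name: str,
    data: TrialDataset,
    folds: FoldAssignment,
    G: CovarianceStructure | None = None,
    Om: CovarianceStructure | None = None,
    chain: ChainConfig | None = None,
    seed: int = 0,
) -> CVResult:
    """K-fold CV with trials (or cultivars) assigned to folds.

    For each fold the model is re-fitted on the remaining folds with the
    left-out rows carried as missing responses; predictions are posterior
    means of all model terms at those rows. Terms at levels unseen in
    training (e.g. Y/YL of a left-out year-location) revert to their prior
    and are constant within a trial, so they do not affect the within-trial
    correlation. Returns one Pearson r per trial with ≥ 3 test records.
    """
    chain = chain or ChainConfig()
    rec = data.records.reset_index(drop=True)
    preds = np.full(len(rec), np.nan)

    for fold in range(folds.k):
        units = set(folds.units_in_fold(fold))
        if folds.scheme == "by-trial":
            test_mask = rec.apply(lambda r: (r["year"], r["location"]) in units, axis=1).to_numpy()
        else:
            test_mask = rec["cultivar"].isin(units).to_numpy()
        assert test_mask.any(), "empty fold"
        masked = rec.copy()
        masked.loc[test_mask, "yield"] = np.nan
        # leakage guard: no test unit contributes a training response
        assert not masked.loc[test_mask, "yield"].notna().any()
        design = build_model(model_name, masked, G=G, Om=Om)
        priors = default_priors(design, r2=chain.r2, df0=chain.df0)
        test_idx = np.nonzero(test_mask)[0]
        ps = gibbs_fit(
            design, priors, n_iter=chain.n_iter, burn_in=chain.burn_in, thin=chain.thin,
            seed=seed + fold, store_rows=test_idx,
        )
        draws = predict_terms(ps, np.arange(len(test_idx)))
        preds[test_idx] = draws.mean(axis=0)

    out_rows = []
    for (y, l), grp in rec.groupby(["year", "location"], sort=False):
        obs = grp["yield"].to_numpy()
        pr = preds[grp.index.to_numpy()]
        ok = np.isfinite(pr)
        if folds.scheme == "by-cultivar" and not ok.all():
            obs, pr = obs[ok], pr[ok]  # trials mixing train/test cultivars
        if len(obs) < MIN_RECORDS_PER_TRIAL or not np.isfinite(pr).all():
            warnings.warn(f"trial ({y},{l}) dropped: fewer than 3 usable test records")
            continue
        if np.std(pr) == 0 or np.std(obs) == 0:
            warnings.warn(f"trial ({y},{l}) dropped: constant predictions or observations")
            continue
        r = float(np.corrcoef(obs, pr)[0, 1])
        out_rows.append({"year": y, "location": l, "r": r, "n": len(obs)})
    table = pd.DataFrame(out_rows)
    return CVResult(model=design.name, scheme=folds.scheme, table=table)


def fisher_z(r: float, n: int) -> float:
    """z = (√(n−3)/2)·log((1+r)/(1−r)) — the variance-stabilized correlation."""
    if abs(r) >= 1:
        raise ValueError("Fisher z is infinite at |r| = 1")
    if n < 3:
        raise ValueError("Fisher z requires n >= 3")
    return float(np.sqrt(n - 3.0) / 2.0 * np.log((1.0 + r) / (1.0 - r)))


@dataclass
class ModelComparison:
    """Mean correlations, pairwise paired-t p-values on Fisher z, and a
    compact letter display (models sharing a letter: p > α)."""

    means: pd.Series  # model -> mean r, descending
    pvalues: pd.DataFrame
    letters: pd.Series
    alpha: float


def compare_models(results: dict[str, CVResult], alpha: float = 0.05) -> ModelComparison:
    """Paired comparison of models on their per-trial Fisher-z values."""
    names = list(results)
    tables = {}
    for name, res in results.items():
        t = res.table.set_index(["year", "location"])
        tables[name] = t
    common = None
    for t in tables.values():
        idx = set(t.index)
        common = idx if common is None else common & idx
    if not common:
        raise ValueError("no common trials across models; results are unpaired")
    common = sorted(common)
    z = pd.DataFrame(
        {
            name: [
                fisher_z(tables[name].loc[k, "r"], int(tables[name].loc[k, "n"]))
                for k in common
            ]
            for name in names
        }
    )
    means = pd.Series({n: results[n].mean_r for n in names}).sort_values(ascending=False)
    order = list(means.index)
    p = pd.DataFrame(np.ones((len(order), len(order))), index=order, columns=order)
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            if i < j:
                diff = z[a] - z[b]
                if np.allclose(diff, 0):
                    pv = 1.0
                else:
                    pv = float(scipy.stats.ttest_rel(z[a], z[b]).pvalue)
                p.loc[a, b] = p.loc[b, a] = pv

    letters = _letter_groups(order, p, alpha)
    return ModelComparison(means=means, pvalues=p, letters=letters, alpha=alpha)


def _letter_groups(order: list[str], p: pd.DataFrame, alpha: float) -> pd.Series:
    """Compact letter display over models sorted by descending mean."""
    m = len(order)
    spans = []
    for i in range(m):
        j = i
        while j + 1 < m and all(
            p.loc[order[a], order[b]] > alpha
            for a in range(i, j + 2)
            for b in range(a + 1, j + 2)
        ):
            j += 1
        spans.append((i, j))
    # drop spans nested in an earlier span
    maximal = [s for s in spans if not any(o[0] <= s[0] and s[1] <= o[1] and o != s for o in spans)]
    labels = {name: "" for name in order}
    for letter, (i, j) in zip(string.ascii_lowercase, maximal):
        for k in range(i, j + 1):
            labels[order[k]] += letter
    return pd.Series(labels)


def trial_blues(data: TrialDataset) -> pd.Series:
    """Trial means adjusted for cultivar composition: BLUEs from the two-way
    fixed-effects model yield ~ trial + cultivar (OLS, first cultivar as
    reference), shifted to the scale of the raw trial means."""
    rec = data.records
    trials = sorted(set(zip(rec["year"], rec["location"])))
    cults = sorted(rec["cultivar"].unique())
    t_pos = {t: i for i, t in enumerate(trials)}
    c_pos = {c: i for i, c in enumerate(cults)}
    n = len(rec)
    Xt = np.zeros((n, len(trials)))
    Xc = np.zeros((n, len(cults) - 1))
    for i, (y, l, c) in enumerate(zip(rec["year"], rec["location"], rec["cultivar"])):
        Xt[i, t_pos[(y, l)]] = 1.0
        if c_pos[c] > 0:
            Xc[i, c_pos[c] - 1] = 1.0
    A = np.hstack([Xt, Xc])
    coef, *_ = np.linalg.lstsq(A, rec["yield"].to_numpy(), rcond=None)
    mu_shift = float(coef[len(trials):].mean()) * (len(cults) - 1) / len(cults)
    blues = coef[: len(trials)] + mu_shift
    return pd.Series(blues, index=pd.MultiIndex.from_tuples(trials, names=["year", "location"]))


def validate_ec_predictiveness(
    data: TrialDataset,
    Om: CovarianceStructure,
    repeats: int = 100,
    holdout: float = 0.2,
    seed: int = 0,
    ridge: float = 0.5,
) -> tuple[float, float]:
    """How well do the ECs predict trial means in cross-validation?

    Trial means are BLUEs from a two-way (trial + cultivar) linear model;
    a kernel ridge regression on Ω predicts held-out trial means over
    ``repeats`` random holdout partitions. Returns (mean r, sd of r).
    """
    blues = trial_blues(data)
    keys = [tuple(k) for k in blues.index]
    if len(keys) < 20:
        raise ValueError("need at least 20 trials to validate EC predictiveness")
    idx = Om.row_index(keys)
    K = Om.K[np.ix_(idx, idx)]
    m = blues.to_numpy()
    n = len(m)
    n_test = int(round(holdout * n))
    if n_test < 3:
        raise ValueError("holdout leaves fewer than 3 test trials")
    rng = stream(seed, "ec-validation")
    rs = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        te, tr = perm[:n_test], perm[n_test:]
        mc = m[tr] - m[tr].mean()
        alpha_hat = np.linalg.solve(K[np.ix_(tr, tr)] + ridge * np.eye(len(tr)), mc)
        pred = K[np.ix_(te, tr)] @ alpha_hat + m[tr].mean()
        rs.append(float(np.corrcoef(pred, m[te])[0, 1]))
    return float(np.mean(rs)), float(np.std(rs, ddof=1))
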