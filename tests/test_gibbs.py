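"""Gibbs sampler: model assembly, priors, conjugate closed-form agreement,
missing-row prediction, posterior summaries."""

import numpy as np
import pandas as pd
import pytest

from gxesim.gibbs import (
    ModelDesign,
    PriorSpec,
    RandomTerm,
    build_model,
    default_priors,
    expected_samples,
    gibbs_fit,
    predict_terms,
    variance_components,
)


@pytest.fixture(scope="module")
def toy_design():
    rng = np.random.default_rng(1)
    n, m1, m2 = 80, 8, 12
    Z1 = np.zeros((n, m1))
    Z1[np.arange(n), rng.integers(0, m1, n)] = 1
    B2 = rng.normal(size=(n, m2)) * 0.5
    y = (
        Z1 @ rng.normal(0, np.sqrt(0.8), m1)
        + B2 @ rng.normal(0, np.sqrt(0.4), m2)
        + rng.normal(0, np.sqrt(0.3), n)
    )
    design = ModelDesign(
        "toy", y, [RandomTerm("t1", Z1), RandomTerm("t2", B2)], row_keys=list(range(n))
    )
    return design, Z1, B2


class TestBuildModel:
    def test_term_sets(self, tiny_network):
        rec = tiny_network.dataset.records
        G, Om = tiny_network.G, tiny_network.Om
        tl = build_model("TL", rec)
        assert [t.name for t in tl.terms] == ["Y", "L", "YL", "V"]
        full = build_model("TGW-GxW", rec, G=G, Om=Om)
        assert [t.name for t in full.terms] == ["Y", "L", "YL", "V", "W", "VW"]
        gw = build_model("GW", rec, G=G, Om=Om)
        assert [t.name for t in gw.terms] == ["V", "W"]
        assert build_model("TGW", rec, G=G, Om=Om).terms[-1].name == "W"

    def test_unknown_model_errors(self, tiny_network):
        with pytest.raises(ValueError, match="unknown model"):
            build_model("XYZ", tiny_network.dataset.records)

    def test_gw_without_ecs_errors(self, tiny_network):
        with pytest.raises(ValueError, match="EC"):
            build_model("GW", tiny_network.dataset.records, G=tiny_network.G, Om=None)


class TestPriors:
    def test_formula_values(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=200)
        y = (y - y.mean()) / y.std(ddof=1)  # var exactly 1
        Z = np.ones((200, 1))  # mean-diag of implied kernel = 1
        d = ModelDesign("m", y, [RandomTerm("u", Z)], row_keys=list(range(200)))
        pr = default_priors(d, r2=0.5, df0=5.0)
        assert pr.S0["u"] == pytest.approx(0.5 * 7.0)  # = 3.5
        assert pr.S0["eps"] == pytest.approx(0.5 * 7.0)

    def test_degenerate_r2_rejected(self, toy_design):
        design, *_ = toy_design
        with pytest.raises(ValueError):
            default_priors(design, r2=0.0)

    def test_identical_kernels_identical_scales(self):
        rng = np.random.default_rng(2)
        Z = np.abs(rng.normal(size=(50, 4)))
        y = rng.normal(size=50)
        d = ModelDesign(
            "m", y, [RandomTerm("a", Z), RandomTerm("b", Z.copy())], row_keys=list(range(50))
        )
        pr = default_priors(d)
        assert pr.S0["a"] == pytest.approx(pr.S0["b"])

    def test_zero_variance_response_rejected(self):
        d = ModelDesign("m", np.ones(10), [RandomTerm("u", np.eye(10))], row_keys=list(range(10)))
        with pytest.raises(ValueError, match="zero variance"):
            default_priors(d)


class TestChainArithmetic:
    def test_production_scale_thinning(self):
        assert expected_samples(100_000, 0, 5) == 20_000

    @pytest.mark.parametrize(
        "n_iter,burn,thin,expect", [(6000, 1000, 5, 1000), (100, 0, 1, 100), (11, 1, 2, 5)]
    )
    def test_counts(self, n_iter, burn, thin, expect):
        assert expected_samples(n_iter, burn, thin) == expect

    def test_invalid(self):
        with pytest.raises(ValueError):
            expected_samples(100, 100, 5)


class TestConjugateOracle:
    """With variances fixed, posterior means must match the generalized-ridge
    closed form; with rows masked, predictions must match explicit kriging."""

    VARS = {"t1": 0.8, "t2": 0.4, "eps": 0.3}
    PRIORS = PriorSpec(df0={"t1": 5, "t2": 5, "eps": 5}, S0={"t1": 1, "t2": 1, "eps": 1})

    def _closed_form(self, y, Z1, B2, obs=None):
        obs = np.ones(len(y), bool) if obs is None else obs
        B = np.hstack([Z1, B2])
        D = np.diag([self.VARS["t1"]] * Z1.shape[1] + [self.VARS["t2"]] * B2.shape[1])
        Bo = B[obs]
        A = Bo.T @ Bo / self.VARS["eps"] + np.linalg.inv(D)
        return B @ np.linalg.solve(A, Bo.T @ y[obs] / self.VARS["eps"])

    def test_effects_match_closed_form(self, toy_design):
        design, Z1, B2 = toy_design
        ps = gibbs_fit(
            design, self.PRIORS, n_iter=12_000, burn_in=2000, thin=1, seed=7,
            fix_variances=self.VARS, fix_mu=0.0,
        )
        fitted = self._closed_form(design.y, Z1, B2)
        total = ps.effects["t1"].mean(axis=0) + ps.effects["t2"].mean(axis=0)
        mc_se = (ps.effects["t1"] + ps.effects["t2"]).std(axis=0) / np.sqrt(ps.B / 20)
        assert np.abs(total - fitted).max() < np.maximum(3 * mc_se, 1e-3).max()

    def test_missing_rows_match_kriging(self, toy_design):
        design, Z1, B2 = toy_design
        y2 = design.y.copy()
        y2[:12] = np.nan
        d2 = ModelDesign("toy", y2, design.terms, design.row_keys)
        ps = gibbs_fit(
            d2, self.PRIORS, n_iter=12_000, burn_in=2000, thin=1, seed=8,
            fix_variances=self.VARS, fix_mu=0.0,
        )
        pred = predict_terms(ps, np.arange(12), include_mu=False).mean(axis=0)
        krig = self._closed_form(y2, Z1, B2, obs=~np.isnan(y2))[:12]
        mc_se = (ps.effects["t1"] + ps.effects["t2"])[:, :12].std(axis=0) / np.sqrt(ps.B / 20)
        assert np.abs(pred - krig).max() < (3 * mc_se).max()

    def test_reproducible_under_seed(self, toy_design):
        design, *_ = toy_design
        a = gibbs_fit(design, self.PRIORS, n_iter=200, burn_in=50, thin=3, seed=5)
        b = gibbs_fit(design, self.PRIORS, n_iter=200, burn_in=50, thin=3, seed=5)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.effects["t1"], b.effects["t1"])


class TestPosteriorSummaries:
    def test_constant_chain(self):
        ps_var = {"u": np.full(500, 1.7), "eps": np.full(500, 0.3)}
        from gxesim.gibbs import PosteriorSamples

        ps = PosteriorSamples(
            model="m", mu=np.zeros(500), variances=ps_var, effects={},
            row_keys=[], observed=np.array([], bool), n_iter=500, burn_in=0, thin=1, seed=0,
        )
        vc = variance_components(ps)
        assert vc.loc["u", "mean"] == pytest.approx(1.7)
        assert vc.loc["u", "lower"] == pytest.approx(vc.loc["u", "upper"]) == pytest.approx(1.7)

    def test_percentiles_match_numpy(self, toy_design):
        design, *_ = toy_design
        ps = gibbs_fit(design, n_iter=800, burn_in=200, thin=2, seed=3)
        vc = variance_components(ps)
        for name, draws in ps.variances.items():
            assert vc.loc[name, "lower"] == pytest.approx(np.percentile(draws, 2.5))
            assert vc.loc[name, "upper"] == pytest.approx(np.percentile(draws, 97.5))
            assert vc.loc[name, "lower"] <= vc.loc[name, "mean"] <= vc.loc[name, "upper"]

    def test_predict_terms_hand_assembled(self, toy_design):
        design, *_ = toy_design
        ps = gibbs_fit(design, n_iter=300, burn_in=100, thin=2, seed=4)
        rows = np.array([0, 3, 7])
        out = predict_terms(ps, rows, ["t1", "t2"])
        hand = ps.mu[:, None] + ps.effects["t1"][:, rows] + ps.effects["t2"][:, rows]
        np.testing.assert_allclose(out, hand)

    def test_unknown_term_errors(self, toy_design):
        design, *_ = toy_design
        ps = gibbs_fit(design, n_iter=120, burn_in=20, thin=2, seed=4)
        with pytest.raises(KeyError):
            predict_terms(ps, [0], ["nope"])

    def test_hdf5_roundtrip(self, toy_design, tmp_path):
        design, *_ = toy_design
        ps = gibbs_fit(design, n_iter=120, burn_in=20, thin=2, seed=4)
        path = tmp_path / "chain.h5"
        ps.to_hdf5(path)
        from gxesim.gibbs import PosteriorSamples

        back = PosteriorSamples.from_hdf5(path)
        np.testing.assert_array_equal(back.mu, ps.mu)
        np.testing.assert_array_equal(back.effects["t2"], ps.effects["t2"])
        assert back.model == ps.model and back.thin == ps.thin


class TestRecoveryFromPrior:
    def test_variances_recovered_on_simulated_data(self):
        """Data simulated from the model: posterior concentrates near truth."""
        rng = np.random.default_rng(10)
        n, m = 600, 30
        Z = np.zeros((n, m))
        Z[np.arange(n), rng.integers(0, m, n)] = 1
        u = rng.normal(0, 1.0, m)
        y = Z @ u + rng.normal(0, 0.5, n)
        d = ModelDesign("m", y, [RandomTerm("u", Z)], row_keys=list(range(n)))
        ps = gibbs_fit(d, n_iter=3000, burn_in=500, thin=2, seed=11)
        vc = variance_components(ps)
        assert vc.loc["eps", "lower"] < 0.25 < vc.loc["eps", "upper"]
        assert vc.loc["u", "lower"] < 1.0 < vc.loc["u", "upper"]
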