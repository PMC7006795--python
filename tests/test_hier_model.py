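import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rangeabund import hier_model as hm
from rangeabund import synthetic_data as sd

GAMMA_NAMES = [
    f"gamma_{eq}_{c}" for eq in hm.EQUATIONS for c in ["0", *hm.L2_COVARIATES]
]
DELTA_NAMES = [f"delta_{k}" for k in hm.INTERACTIONS]


def small_design(seed=4, J=12, plots=60, spp=3, **truth_kw):
    truth = sd.default_truth(seed=seed)
    truth.n_species, truth.n_plots, truth.species_per_plot = J, plots, spp
    for k, v in truth_kw.items():
        setattr(truth, k, v)
    return sd.gen_design(truth, seed=seed)


@pytest.fixture(scope="module")
def tiny_rows():
    sim = small_design()
    rows = sim["rows"].copy()
    rows["rel_abund"] = np.exp(rows["y"] - rows["y"].max() - 0.1)  # valid (0,1]
    rows["range"] = np.where(rows["alien"] == 1, "alien", "native")
    return rows.drop(columns=["y", "alien"])


class TestStandardize:
    def test_zero_mean_unit_sd_all_columns(self, tiny_rows):
        out, params = hm.standardize(tiny_rows)
        for col in ["y"] + hm.MAIN_EFFECTS:
            assert out[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[col].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_rejected_by_name(self, tiny_rows):
        bad = tiny_rows.copy()
        bad["hii"] = 3.0
        with pytest.raises(hm.ModelError, match="hii"):
            hm.standardize(bad)

    def test_round_trip(self, tiny_rows):
        out, params = hm.standardize(tiny_rows)
        x = tiny_rows["dissim"].to_numpy()
        np.testing.assert_allclose(
            params.inverse("dissim", params.transform("dissim", x)), x, atol=1e-12)


class TestModelLogdensity:
    def _params(self, data, rng):
        J = data.n_species
        return {
            "gamma": rng.normal(0, 0.1, (10, 5)),
            "delta": rng.normal(0, 0.1, 7),
            "theta": rng.normal(0, 0.3, (J, 10)),
            "u": rng.normal(0, 0.2, data.n_plots),
            "sigma_theta": np.full(10, 0.4),
            "sigma_plot": 0.3,
            "sigma_resid": 0.7,
        }

    def test_finite_on_interior_point(self):
        sim = small_design(J=5, plots=5, spp=2)
        p = self._params(sim["data"], np.random.default_rng(0))
        assert np.isfinite(hm.model_logdensity(p, sim["data"], hm.HierModelSpec()))

    def test_matches_handcoded_sum_of_normals(self):
        sim = small_design(J=2, plots=3, spp=1)
        data, spec = sim["data"], hm.HierModelSpec()
        p = self._params(data, np.random.default_rng(1))
        # independent oracle: plain python loops over every density term
        expected = 0.0
        for i in range(data.n):
            j, pl = data.species_idx[i], data.plot_idx[i]
            mu = p["theta"][j, 0]
            for k in range(9):
                mu += p["theta"][j, k + 1] * data.X[i, k]
            for k in range(7):
                mu += p["delta"][k] * data.Z[i, k]
            mu += p["u"][pl]
            expected += stats.norm.logpdf(data.y[i], mu, p["sigma_resid"])
        for j in range(data.n_species):
            for e in range(10):
                mu = p["gamma"][e, 0]
                for m in range(4):
                    mu += p["gamma"][e, m + 1] * data.T[j, m]
                expected += stats.norm.logpdf(p["theta"][j, e], mu,
                                              p["sigma_theta"][e])
        for v in p["u"]:
            expected += stats.norm.logpdf(v, 0, p["sigma_plot"])
        sdl = np.sqrt(spec.prior_location_variance)
        expected += stats.norm.logpdf(p["gamma"], 0, sdl).sum()
        expected += stats.norm.logpdf(p["delta"], 0, sdl).sum()
        expected += 12 * np.log(1 / spec.prior_sigma_upper)
        assert hm.model_logdensity(p, data, spec) == pytest.approx(expected, abs=1e-8)

    def test_sigma_outside_support_is_minus_inf(self):
        sim = small_design(J=4, plots=4, spp=2)
        p = self._params(sim["data"], np.random.default_rng(2))
        p["sigma_resid"] = 200.0
        assert hm.model_logdensity(p, sim["data"], hm.HierModelSpec()) == -np.inf

    def test_decreases_with_residual_distance(self):
        sim = small_design(J=4, plots=4, spp=2)
        data = sim["data"]
        p = self._params(data, np.random.default_rng(3))
        base = hm.model_logdensity(p, data, hm.HierModelSpec())
        far = {**p, "u": p["u"] + 50.0}
        assert hm.model_logdensity(far, data, hm.HierModelSpec()) < base


class TestSamplerAgainstConjugateOracle:
    """With the sigma prior cap pinning all standard deviations, the model is
    linear-Gaussian and the (gamma, delta) posterior is available in closed
    form from the joint normal; the Gibbs draws must reproduce it."""

    def test_posterior_matches_joint_gaussian(self):
        cap = 0.2
        sim = small_design(J=15, plots=120, spp=3,
                           sigma_theta=np.full(10, 0.5), sigma_plot=0.5,
                           sigma_resid=0.5, alien_fraction=0.5)
        data = sim["data"]
        spec = hm.HierModelSpec(chains=3, iterations=2500, burn_in=800,
                                prior_sigma_upper=cap)
        draws = hm.sample_posterior(data, spec, seed=7)
        assert draws.get("sigma_resid").mean() == pytest.approx(cap, abs=0.01)

        n, J, P = data.n, data.n_species, data.n_plots
        W = np.column_stack([np.ones(n), data.X])
        U = np.column_stack([np.ones(J), data.T])
        Xg = np.einsum("ie,im->iem", W, U[data.species_idx]).reshape(n, -1)
        Eta = np.zeros((n, J * 10))
        for i in range(n):
            j = data.species_idx[i]
            Eta[i, j * 10 : (j + 1) * 10] = W[i]
        A = np.column_stack([Xg, data.Z, Eta, np.eye(P)[data.plot_idx]])
        prior = np.concatenate([np.full(57, 1 / 1000.0),
                                np.full(J * 10 + P, 1 / cap**2)])
        Prec = A.T @ A / cap**2 + np.diag(prior)
        mean = np.linalg.solve(Prec, A.T @ data.y / cap**2)
        sdv = np.sqrt(np.diag(np.linalg.inv(Prec)))

        names = GAMMA_NAMES + DELTA_NAMES
        emp_m = np.array([draws.get(nm).mean() for nm in names])
        emp_s = np.array([draws.get(nm).std() for nm in names])
        # Monte-Carlo error plus the slight downward sigma-pinning bias
        assert np.abs((emp_m - mean[:57]) / sdv[:57]).max() < 0.25
        ratio = emp_s / sdv[:57]
        assert ratio.min() > 0.8 and ratio.max() < 1.2

    def test_monte_carlo_se_scaling(self):
        # quadrupling iterations roughly halves the spread of chain means
        sim = small_design(J=10, plots=60, spp=3)
        data = sim["data"]
        spread = {}
        for iters in (250, 1000):
            spec = hm.HierModelSpec(chains=8, iterations=iters, burn_in=300)
            draws = hm.sample_posterior(data, spec, seed=21)
            cm = draws.get("gamma_dissim_0").mean(axis=1)
            spread[iters] = cm.std(ddof=1)
        assert spread[1000] < spread[250] * 0.85  # sqrt(4)=2 expected, loose

    def test_species_label_permutation_leaves_gamma_invariant(self):
        sim = small_design(J=8, plots=50, spp=3, seed=13)
        data = sim["data"]
        rng = np.random.default_rng(5)
        perm = rng.permutation(data.n_species)
        data_p = hm.ModelData(
            y=data.y, X=data.X, Z=data.Z,
            species_idx=perm[data.species_idx], plot_idx=data.plot_idx,
            T=data.T[np.argsort(perm)],
            species_ids=[data.species_ids[i] for i in np.argsort(perm)],
            plot_ids=data.plot_ids,
        )
        spec = hm.HierModelSpec(chains=6, iterations=1500, burn_in=500)
        d1 = hm.sample_posterior(data, spec, seed=3)
        d2 = hm.sample_posterior(data_p, spec, seed=3)
        for nm in ["gamma_intercept_0", "gamma_dissim_0", "gamma_d_wd_wd"]:
            m1, m2 = d1.get(nm).mean(), d2.get(nm).mean()
            se1 = d1.get(nm).mean(axis=1).std(ddof=1) / np.sqrt(spec.chains)
            se2 = d2.get(nm).mean(axis=1).std(ddof=1) / np.sqrt(spec.chains)
            assert abs(m1 - m2) < 4 * np.hypot(se1, se2) + 0.005


class TestGelmanRubin:
    def test_identical_chains_formula_value(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=(1, 500, 2))
        draws = np.concatenate([chain, chain], axis=0)
        psrf, _ = hm.gelman_rubin(draws)
        n = 500
        np.testing.assert_allclose(psrf, np.sqrt((n - 1) / n), atol=1e-12)

    def test_same_distribution_converges(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(size=(3, 10_000, 3))
        psrf, mpsrf = hm.gelman_rubin(draws)
        assert psrf.max() < 1.01 and mpsrf < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(2, 1000, 1))
        draws[1] += 10.0
        psrf, mpsrf = hm.gelman_rubin(draws)
        assert psrf[0] > 1.1 and mpsrf > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(hm.ModelError):
            hm.gelman_rubin(np.zeros((1, 100, 2)))

    def test_matches_bruteforce_formula(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(size=(4, 200, 1)) + rng.normal(size=(4, 1, 1)) * 0.3
        psrf, _ = hm.gelman_rubin(draws)
        m, n = 4, 200
        means = draws[:, :, 0].mean(axis=1)
        W = np.mean([draws[c, :, 0].var(ddof=1) for c in range(m)])
        B = n * means.var(ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert psrf[0] == pytest.approx(expected, abs=1e-12)


class TestVif:
    def test_orthogonal_predictors_are_one(self):
        n = 400
        M = np.column_stack([np.ones(n),
                             np.random.default_rng(0).normal(size=(n, 3))])
        X = np.linalg.qr(M)[0][:, 1:]  # orthogonal to each other and intercept
        v = hm.vif(X)
        np.testing.assert_allclose(v, 1.0, atol=1e-10)

    def test_duplicated_predictor_rejected(self):
        x = np.random.default_rng(1).normal(size=200)
        with pytest.raises(hm.ModelError):
            hm.vif(np.column_stack([x, x, np.random.default_rng(2).normal(size=200)]))

    def test_matches_bruteforce_r2_and_statsmodels(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=500)
        X = np.column_stack([
            0.6 * z + np.sqrt(1 - 0.36) * rng.normal(size=500),
            z, rng.normal(size=500)])
        v = hm.vif(X).to_numpy()
        for j in range(3):
            others = np.column_stack([np.ones(500), np.delete(X, j, axis=1)])
            beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            res = X[:, j] - others @ beta
            r2 = 1 - res @ res / ((X[:, j] - X[:, j].mean()) ** 2).sum()
            assert v[j] == pytest.approx(1 / (1 - r2), abs=1e-10)
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        Xc = np.column_stack([np.ones(500), X])
        sm = [variance_inflation_factor(Xc, j + 1) for j in range(3)]
        np.testing.assert_allclose(v, sm, rtol=1e-8)


class TestSummaries:
    def test_constant_draws(self):
        draws = hm.PosteriorDraws(np.full((2, 50, 1), 3.2), ["a"])
        s = hm.summarize_effects(draws)
        assert s.loc["a", ["median", "q2.5", "q97.5"]].tolist() == [3.2, 3.2, 3.2]

    def test_symmetric_draws_straddle_zero(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(3, 2000, 1))
        s = hm.summarize_effects(hm.PosteriorDraws(v, ["a"]))
        assert abs(s.loc["a", "median"]) < 0.1
        assert not s.loc["a", "significant"]

    def test_quantiles_match_sorting_oracle(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(2, 101, 1))
        s = hm.summarize_effects(hm.PosteriorDraws(v, ["a"]))
        flat = np.sort(v.reshape(-1))
        for col, q in [("q2.5", 0.025), ("median", 0.5), ("q97.5", 0.975)]:
            assert s.loc["a", col] == pytest.approx(
                np.quantile(flat, q), abs=1e-12)

    def test_panels_compose_gamma_and_delta(self):
        rng = np.random.default_rng(6)
        names = GAMMA_NAMES + DELTA_NAMES
        arr = rng.normal(size=(2, 300, len(names)))
        draws = hm.PosteriorDraws(arr, names)
        panels = hm.range_effect_panels(draws, r_native_std=-0.5, r_alien_std=2.0)
        g = draws.get("gamma_dissim_0").reshape(-1)
        d = draws.get("delta_dissim").reshape(-1)
        assert panels.loc["effect_dissim_alien", "median"] == pytest.approx(
            np.median(g + 2.0 * d), abs=1e-12)
        # no interaction for richness: both ranges identical
        assert (panels.loc["effect_richness_native"]
                == panels.loc["effect_richness_alien"]).all()
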