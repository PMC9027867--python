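import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cacyreus import CountData, NMixtureModel, NMixtureResults, aicc
from cacyreus.nmixture import ModelSpec, nmix_negloglik

from oracles import brute_force_negloglik


def tiny_data(y, x=None, w=None):
    y = np.atleast_2d(np.asarray(y, dtype=float))
    m = y.shape[0]
    idx = [f"s{i}" for i in range(m)]
    site = pd.DataFrame({"x": x if x is not None else np.zeros(m)}, index=idx)
    obs = pd.DataFrame({"w": w if w is not None else np.zeros(m)}, index=idx)
    ycols = {f"visit_{j+1}": y[:, j] for j in range(y.shape[1])}
    return CountData(y=pd.DataFrame(ycols, index=idx), site_covariates=site,
                     obs_covariates=obs)


class TestAicc:
    def test_closed_form_worked_example(self):
        # -2 loglik + 2K = 10 with K=3, n=75 -> 10 + 24/71
        loglik = -(10 - 2 * 3) / 2
        assert aicc(loglik, 3, 75) == pytest.approx(10 + 24 / 71, abs=1e-12)

    def test_large_n_limit_is_aic(self):
        val = aicc(-100.0, 4, int(1e9))
        assert abs(val - (200 + 8)) < 1e-6

    def test_more_parameters_cost_more_at_equal_likelihood(self):
        assert aicc(-10.0, 3, 20) > aicc(-10.0, 2, 20)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(1, 10), st.integers(30, 500))
    def test_penalty_monotone_in_k(self, k, n):
        assert aicc(0.0, k + 1, n) > aicc(0.0, k, n)


class TestLikelihoodOracle:
    def test_worked_example_single_site(self):
        """One site, y=[1,0], lambda=2, p=0.4, Poisson: matches direct
        enumeration to 1e-10."""
        data = tiny_data([[1, 0]])
        spec = ModelSpec((), (), "P")
        params = np.array([np.log(2.0), np.log(0.4 / 0.6)])
        ours = nmix_negloglik(params, data, spec, k_trunc=100)
        oracle = brute_force_negloglik(np.array([[1.0, 0.0]]), [2.0], [0.4])
        assert ours == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("mixture", ["P", "NB", "ZIP"])
    def test_fuzz_against_brute_force(self, mixture):
        """100 random small instances agree with the enumeration oracle
        to 1e-10 for every mixture."""
        rng = np.random.default_rng(20_000 + hash(mixture) % 1000)
        worst = 0.0
        for _ in range(100):
            m = rng.integers(1, 6)
            j = rng.integers(1, 5)
            y = rng.integers(0, 9, size=(m, j)).astype(float)
            x = rng.normal(size=m)
            w = rng.normal(size=m)
            beta = rng.normal(0, 0.7, size=2)
            alpha = rng.normal(0, 0.7, size=2)
            psi = rng.uniform(0.05, 0.9)
            theta = rng.uniform(0.3, 5.0)
            data = tiny_data(y, x=x, w=w)
            spec = ModelSpec(("x",), ("w",), mixture)
            params = np.concatenate([
                beta, alpha,
                [np.log(psi / (1 - psi))] if mixture == "ZIP" else
                [np.log(theta)] if mixture == "NB" else []])
            ours = nmix_negloglik(params, data, spec, k_trunc=300)
            lam = np.exp(beta[0] + beta[1] * x)
            p = 1 / (1 + np.exp(-(alpha[0] + alpha[1] * w)))
            oracle = brute_force_negloglik(y, lam, p, mixture=mixture,
                                           psi=psi, theta=theta, n_max=1000)
            worst = max(worst, abs(ours - oracle))
        assert worst <= 1e-10

    def test_certain_empty_site_has_zero_negloglik(self):
        """lambda -> 0 makes y = [0,0,0] certain: -log L -> 0."""
        data = tiny_data([[0, 0, 0]])
        val = nmix_negloglik(np.array([-40.0, 0.0]), data,
                             ModelSpec((), (), "P"), k_trunc=50)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_zip_with_zero_inflation_off_equals_poisson(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 6, size=(4, 3)).astype(float)
        data = tiny_data(y)
        base = np.array([0.8, 0.0, 0.3, 0.0])
        pois = nmix_negloglik(base, data, ModelSpec(("x",), ("w",), "P"), 200)
        zip_ = nmix_negloglik(np.append(base, -40.0), data,
                              ModelSpec(("x",), ("w",), "ZIP"), 200)
        assert zip_ == pytest.approx(pois, abs=1e-12)

    def test_nb_with_huge_dispersion_approaches_poisson(self):
        rng = np.random.default_rng(6)
        y = rng.poisson(3, size=(6, 3)).astype(float)
        data = tiny_data(y)
        base = np.array([1.1, 0.0, 0.2, 0.0])
        pois = nmix_negloglik(base, data, ModelSpec(("x",), ("w",), "P"), 200)
        nb = nmix_negloglik(np.append(base, np.log(1e7)), data,
                            ModelSpec(("x",), ("w",), "NB"), 200)
        assert nb == pytest.approx(pois, abs=1e-4)

    def test_truncation_monotone(self):
        """Raising K_trunc only adds probability mass: the negative
        log-likelihood never increases."""
        rng = np.random.default_rng(7)
        y = rng.integers(0, 8, size=(5, 3)).astype(float)
        data = tiny_data(y)
        spec = ModelSpec((), (), "P")
        params = np.array([2.5, -1.0])
        vals = [nmix_negloglik(params, data, spec, k) for k in (10, 30, 100, 300)]
        assert all(vals[i + 1] <= vals[i] + 1e-12 for i in range(len(vals) - 1))

    def test_k_trunc_below_max_count_rejected(self):
        data = tiny_data([[9, 2]])
        with pytest.raises(ValueError, match="K_trunc"):
            nmix_negloglik(np.array([0.0, 0.0]), data, ModelSpec((), (), "P"), 5)

    def test_non_finite_params_rejected(self):
        data = tiny_data([[1, 0]])
        with pytest.raises(ValueError):
            nmix_negloglik(np.array([np.nan, 0.0]), data,
                           ModelSpec((), (), "P"), 50)


class TestGradient:
    @pytest.mark.parametrize("mixture", ["P", "NB", "ZIP"])
    def test_analytic_gradient_matches_finite_differences(self, mixture):
        rng = np.random.default_rng(30)
        y = rng.integers(0, 7, size=(6, 3)).astype(float)
        y[0, 2] = np.nan  # missing visit
        data = tiny_data(y, x=rng.normal(size=6), w=rng.normal(size=6))
        model = NMixtureModel(data, abundance=("x",), detection=("w",),
                              mixture=mixture)
        core = model._make_core(150)
        x0 = np.concatenate([rng.normal(0, 0.4, 4),
                             [0.2] if mixture != "P" else []])
        _, grad = core.value_and_grad(x0)
        num = np.empty_like(x0)
        h = 1e-6
        for i in range(len(x0)):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += h
            xm[i] -= h
            num[i] = (core.value(xp) - core.value(xm)) / (2 * h)
        np.testing.assert_allclose(grad, num, rtol=1e-5, atol=1e-7)


class TestFit:
    def test_known_detection_recovers_sample_mean(self):
        """J=1 with detection fixed at 1 reduces to a Poisson GLM: the
        intercept-only MLE is the sample mean."""
        rng = np.random.default_rng(8)
        y = rng.poisson(4.2, size=(200, 1)).astype(float)
        data = tiny_data(y)
        res = NMixtureModel(data, abundance=(), mixture="P", fixed_p=1.0).fit()
        assert np.exp(res.params["lam:intercept"]) == pytest.approx(
            y.mean(), abs=1e-6)

    def test_fit_recovers_parameters_on_easy_data(self):
        """Moderate detection, strong covariate: estimates land within
        3 SE of truth."""
        rng = np.random.default_rng(9)
        m = 250
        x = rng.normal(size=m)
        lam = np.exp(1.5 + 0.6 * x)
        n_latent = rng.poisson(lam)
        p = 0.6
        y = rng.binomial(n_latent[:, None], p, size=(m, 3)).astype(float)
        data = tiny_data(y, x=x)
        res = NMixtureModel(data, abundance=("x",), detection=(),
                            mixture="P").fit()
        assert res.converged
        est, se = res.params, res.bse
        for name, truth in [("lam:intercept", 1.5), ("lam:x", 0.6),
                            ("p:intercept", np.log(p / (1 - p)))]:
            assert abs(est[name] - truth) < 3 * se[name] + 0.05

    def test_missing_visits_are_skipped(self):
        rng = np.random.default_rng(10)
        y = rng.poisson(3, size=(50, 3)).astype(float)
        y[::3, 1] = np.nan
        res = NMixtureModel(tiny_data(y), abundance=(), detection=(),
                            mixture="P").fit()
        assert np.isfinite(res.llf) and res.converged

    def test_vcov_is_symmetric_psd(self, study_counts_scaled):
        res = NMixtureModel(study_counts_scaled, abundance=("bio01",),
                            detection=("pel_ava",), mixture="P").fit()
        v = res.vcov.to_numpy()
        np.testing.assert_allclose(v, v.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(v) > -1e-10)

    def test_aicc_consistent_with_loglik(self, study_counts_scaled):
        res = NMixtureModel(study_counts_scaled, abundance=("bio01",),
                            detection=("pel_ava",), mixture="P").fit()
        assert res.aicc == pytest.approx(
            aicc(res.llf, res.k_params, res.n_sites))

    def test_rank_deficient_design_rejected(self, study_counts_scaled):
        data = study_counts_scaled
        data2 = CountData(data.y.copy(),
                          data.site_covariates.assign(
                              dup=data.site_covariates["bio01"]),
                          data.obs_covariates.copy(), data.scaling_record)
        with pytest.raises(ValueError, match="rank"):
            NMixtureModel(data2, abundance=("bio01", "dup"),
                          detection=("pel_ava",))

    def test_simulate_respects_missingness(self):
        rng = np.random.default_rng(11)
        y = rng.poisson(2, size=(30, 3)).astype(float)
        y[0, 1] = np.nan
        res = NMixtureModel(tiny_data(y), abundance=(), detection=(),
                            mixture="P").fit()
        sim = res.simulate(seed=3)
        assert np.isnan(sim.iloc[0, 1])
        assert np.isfinite(sim.to_numpy()[1:]).all()


class TestPredict:
    def fixed_results(self, psi=0.5):
        return NMixtureResults.from_coefficients(
            abundance={"intercept": 3.095, "bio01": 0.446, "pel_abu": 0.320,
                       "pel_neigh": -0.343, "pel_abu:bio01": 0.592},
            detection={"intercept": -2.632, "pel_ava": 0.399},
            mixture="ZIP", psi=psi,
            scaling_record={"bio01": (0.0, 1.0), "pel_abu": (0.0, 1.0),
                            "pel_neigh": (0.0, 1.0), "pel_ava": (0.0, 1.0)})

    def test_linear_predictor_at_reference_covariates(self):
        """At all-zero scaled covariates the abundance linear predictor
        equals the intercept, 3.095."""
        res = self.fixed_results()
        newdata = pd.DataFrame({"bio01": [0.0], "pel_abu": [0.0],
                                "pel_neigh": [0.0], "pel_ava": [0.0]})
        pred = res.predict(newdata)
        assert pred["eta"].iloc[0] == pytest.approx(3.095, abs=1e-12)
        assert pred["E_N"].iloc[0] == pytest.approx(0.5 * np.exp(3.095))

    def test_total_zero_inflation_kills_expected_abundance(self):
        res = self.fixed_results(psi=1.0)
        newdata = pd.DataFrame({"bio01": [0.0, 1.0], "pel_abu": [0.0, 2.0],
                                "pel_neigh": [0.0, 0.0], "pel_ava": [0.0, 0.0]})
        assert res.predict(newdata)["E_N"].max() < 1e-10

    def test_monotone_in_temperature_when_sign_condition_holds(self):
        """E[N] rises with bio01 wherever beta_bio01 + beta_int * pel_abu_z
        is positive, and falls where it is negative."""
        res = self.fixed_results()
        thresh = -0.446 / 0.592
        for z_abu, increasing in [(thresh + 0.5, True), (thresh - 0.5, False)]:
            newdata = pd.DataFrame({
                "bio01": np.linspace(-2, 2, 9), "pel_abu": z_abu,
                "pel_neigh": 0.0, "pel_ava": 0.0})
            e = res.predict(newdata)["E_N"].to_numpy()
            assert ((np.diff(e) > 0).all() if increasing
                    else (np.diff(e) < 0).all())

    def test_missing_column_named(self):
        res = self.fixed_results()
        with pytest.raises(KeyError, match="pel_abu"):
            res.predict(pd.DataFrame({"bio01": [0.0]}))
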