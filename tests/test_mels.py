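"""Mixed-effects location-scale model: likelihood, fitting, EB estimation.

The independent oracles here are closed forms, not the quadrature path:
the compound-symmetry (random-intercept) marginal likelihood for the
sigma_w -> 0 limit, and conjugate-normal shrinkage for the EB location.
"""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from melsim import (
    DgpConfig,
    EmaDataset,
    MelsParams,
    MelsSettings,
    eb_estimates,
    fit_mels,
    marginal_loglik,
    plausible_values,
)

from conftest import dataset_from_values, simulate_dataset


def random_intercept_loglik(data, beta0, tau0, sigma_v):
    """Closed-form Gaussian marginal likelihood with a random intercept only
    (within-variance homogeneous): the sigma_w -> 0, rho = 0 limit."""
    st = data.suff_stats()
    n = st["n"].to_numpy()
    ybar = st["ybar"].to_numpy()
    ss = st["ss"].to_numpy()
    s2e = math.exp(tau0)
    per_subject = -0.5 * (
        n * math.log(2 * math.pi)
        + (n - 1) * math.log(s2e)
        + np.log(s2e + n * sigma_v**2)
        + ss / s2e
        + n * (ybar - beta0) ** 2 / (s2e + n * sigma_v**2)
    )
    return float(per_subject.sum())


class TestMarginalLoglik:
    def test_random_intercept_oracle(self, oracle_limit_dataset):
        """AGHQ equals the compound-symmetry closed form when the random
        scale vanishes (1e-6 absolute on a 20-subject fixture)."""
        params = MelsParams(beta0=0.1, tau0=0.2, sigma_v=0.8, sigma_w=1e-6, rho_vw=0.0)
        got = marginal_loglik(oracle_limit_dataset, params, n_quad=15)
        want = random_intercept_loglik(oracle_limit_dataset, 0.1, 0.2, 0.8)
        assert got == pytest.approx(want, abs=1e-6)

    def test_no_random_effects_limit(self):
        """One subject, one observation, both random effects -> 0: the
        marginal collapses to a single normal density."""
        data = EmaDataset(
            pd.DataFrame(
                {"subject_id": [1], "occasion": [1], "value": [1.3], "observed": [True]}
            )
        )
        params = MelsParams(beta0=0.5, tau0=0.4, sigma_v=1e-8, sigma_w=1e-8, rho_vw=0.0)
        want = -0.5 * (math.log(2 * math.pi) + 0.4 + (1.3 - 0.5) ** 2 / math.exp(0.4))
        assert marginal_loglik(data, params, n_quad=15) == pytest.approx(want, abs=1e-6)

    def test_quadrature_refinement(self):
        """9 vs 25 points agree to 1e-4 on a 20-subject fixture."""
        cfg = DgpConfig(n_subjects=20, n_obs=30, sd_logscale=0.3, seed=5)
        _, data = simulate_dataset(cfg, 5)
        params = MelsParams(0.0, 0.0, 1.0, 0.6, 0.0)
        a = marginal_loglik(data, params, 9)
        b = marginal_loglik(data, params, 25)
        assert a == pytest.approx(b, abs=1e-4)

    def test_n_quad_minimum(self, oracle_limit_dataset):
        with pytest.raises(ValueError):
            marginal_loglik(oracle_limit_dataset, MelsParams(0, 0, 1, 1), n_quad=3)

    def test_subject_permutation_invariance(self, quickfit):
        data, _, fit = quickfit
        perm = data.df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        permuted = EmaDataset(perm)
        a = marginal_loglik(data, fit.params, 15)
        b = marginal_loglik(permuted, fit.params, 15)
        assert a == pytest.approx(b, abs=1e-10)

    def test_equivariance_identities(self, quickfit):
        """Location shift and scale change act on (beta0, tau0, sigma_v) in
        the model-implied way, leaving the likelihood (up to the change of
        variables) and the standardized EB estimates untouched."""
        data, _, fit = quickfit
        p = fit.params
        c, b = 2.5, 1.7
        base = marginal_loglik(data, p, 15)
        n_total = len(data.observed())

        shifted = EmaDataset(data.df.assign(value=data.df["value"] + c))
        p_shift = MelsParams(p.beta0 + c, p.tau0, p.sigma_v, p.sigma_w, p.rho_vw)
        assert marginal_loglik(shifted, p_shift, 15) == pytest.approx(base, abs=1e-6)

        scaled = EmaDataset(data.df.assign(value=data.df["value"] * b))
        p_scale = MelsParams(
            p.beta0 * b, p.tau0 + 2 * math.log(b), p.sigma_v * b, p.sigma_w, p.rho_vw
        )
        assert marginal_loglik(scaled, p_scale, 15) == pytest.approx(
            base - n_total * math.log(b), abs=1e-6
        )

        eb0 = eb_estimates(data, p, 15)
        eb_s = eb_estimates(scaled, p_scale, 15)
        np.testing.assert_allclose(eb0["theta_loc"], eb_s["theta_loc"], atol=1e-6)
        np.testing.assert_allclose(eb0["theta_scale"], eb_s["theta_scale"], atol=1e-6)


class TestFit:
    def test_quickfit_converges(self, quickfit):
        _, _, fit = quickfit
        d = fit.convergence_detail
        assert fit.converged and d["hessian_pd"] and not d["boundary"]
        assert d["grad_norm"] <= 1e-5

    def test_loglik_matches_recomputation(self, quickfit):
        data, _, fit = quickfit
        assert fit.loglik == pytest.approx(marginal_loglik(data, fit.params, fit.n_quad), abs=1e-8)

    def test_constant_subject_flagged_nonconverged(self):
        """Zero within-person variation makes the likelihood unbounded in
        sigma_w; the fit must report non-convergence, not an exception."""
        rng = np.random.default_rng(0)
        values = {i: rng.normal(0, 1, 12) for i in range(1, 14)}
        values[14] = [2.0] * 12  # the pathological subject
        fit = fit_mels(dataset_from_values(values))
        assert not fit.converged
        assert fit.convergence_detail.get("reason") == "degenerate_subjects"

    def test_few_subjects_warns(self):
        rng = np.random.default_rng(1)
        data = dataset_from_values({i: rng.normal(0, 1, 8) for i in range(5)})
        with pytest.warns(UserWarning, match="unstable"):
            fit_mels(data, MelsSettings(n_quad=9, compute_se=False))

    def test_subject_order_leaves_fit_unchanged(self, quickfit):
        data, _, fit = quickfit
        perm = data.df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        fit2 = fit_mels(EmaDataset(perm), MelsSettings(n_quad=15))
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-6)
        merged = fit.eb.merge(fit2.eb, on="subject_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["theta_loc_a"], merged["theta_loc_b"], atol=1e-5)

    def test_standard_errors_reported(self, quickfit):
        _, _, fit = quickfit
        assert fit.se is not None
        assert all(v > 0 for v in fit.se.values())
        assert set(fit.se) == {"beta0", "tau0", "s11", "s21", "s22"}


class TestEbEstimates:
    def test_conjugate_shrinkage_oracle(self, oracle_limit_dataset):
        """sigma_w -> 0, rho = 0: the EB location equals the conjugate-normal
        shrinkage lambda_i (ybar_i - beta0) / sigma_v with
        lambda_i = sigma_v^2 / (sigma_v^2 + exp(tau0)/n_i)."""
        beta0, tau0, sigma_v = 0.1, 0.2, 0.8
        params = MelsParams(beta0, tau0, sigma_v, 1e-6, 0.0)
        eb = eb_estimates(oracle_limit_dataset, params, 15)
        st = oracle_limit_dataset.suff_stats()
        lam = sigma_v**2 / (sigma_v**2 + math.exp(tau0) / st["n"].to_numpy())
        oracle = lam * (st["ybar"].to_numpy() - beta0) / sigma_v
        np.testing.assert_allclose(eb["theta_loc"], oracle, atol=1e-4)

    def test_population_matching_subject_sits_at_prior_mean(self):
        """A subject whose sample mean and variance equal the population
        values has standardized EB estimates near 0 even with many obs."""
        rng = np.random.default_rng(4)
        v = rng.normal(size=500)
        v = (v - v.mean()) / v.std(ddof=1)  # exact mean 0, SD 1
        data = dataset_from_values({1: 2.0 + v * math.exp(0.15)})
        params = MelsParams(beta0=2.0, tau0=0.3, sigma_v=1.0, sigma_w=0.8, rho_vw=0.2)
        eb = eb_estimates(data, params, 21)
        assert abs(eb["theta_loc"].iloc[0]) < 0.05
        assert abs(eb["theta_scale"].iloc[0]) < 0.05

    def test_shrinkage_bounded_by_unshrunken_zscore(self, oracle_limit_dataset):
        """|EB location| never exceeds the raw z-score |ybar - beta0|/sigma_v."""
        params = MelsParams(0.0, 0.1, 0.9, 1e-6, 0.0)
        eb = eb_estimates(oracle_limit_dataset, params, 15)
        st = oracle_limit_dataset.suff_stats()
        z = np.abs(st["ybar"].to_numpy() - 0.0) / 0.9
        assert (np.abs(eb["theta_loc"].to_numpy()) <= z + 1e-6).all()

    def test_more_observations_tighter_posterior(self):
        """Same summary statistics, n=10 vs n=50: the sparse subject has
        larger posterior SDs and estimates shrunk closer to 0."""
        rng = np.random.default_rng(5)

        def standardized(n):
            v = rng.normal(size=n)
            return 2.0 + (v - v.mean()) / v.std(ddof=1)

        data = dataset_from_values({1: standardized(10), 2: standardized(50)})
        params = MelsParams(0.0, 0.0, 1.0, 0.6, 0.0)
        eb = eb_estimates(data, params, 15).set_index("subject_id")
        assert eb.loc[1, "psd_loc"] > eb.loc[2, "psd_loc"]
        assert eb.loc[1, "psd_scale"] > eb.loc[2, "psd_scale"]
        assert abs(eb.loc[1, "theta_loc"]) < abs(eb.loc[2, "theta_loc"])

    def test_posterior_sds_in_unit_interval(self, replicate_300x30):
        _, data, params = replicate_300x30
        eb = eb_estimates(data, params, 15)
        for col in ("psd_loc", "psd_scale"):
            assert (eb[col] > 0).all()
            assert (eb[col] < 1.0 + 1e-6).all()

    def test_psd_decreases_with_nobs_on_average(self):
        from melsim import allocate_unbalanced

        counts = allocate_unbalanced(200, (0.5, 0.5), (10, 30), seed=8)
        cfg = DgpConfig(n_subjects=200, n_obs=counts, sd_logscale=0.6, seed=8)
        _, data = simulate_dataset(cfg, 8)
        eb = eb_estimates(data, MelsParams(0.0, 0.0, 1.0, 1.2, 0.0), 15)
        by_n = eb.groupby("n_obs")[["psd_loc", "psd_scale"]].mean()
        assert by_n.loc[10, "psd_loc"] > by_n.loc[30, "psd_loc"]
        assert by_n.loc[10, "psd_scale"] > by_n.loc[30, "psd_scale"]

    def test_standardized_estimates_center_and_shrink(self, replicate_300x30):
        """On correctly specified data the EB estimates average ~0 and their
        spread never exceeds the unit prior scale."""
        _, data, params = replicate_300x30
        eb = eb_estimates(data, params, 15)
        assert abs(eb["theta_loc"].mean()) < 0.1
        assert abs(eb["theta_scale"].mean()) < 0.1
        assert eb["theta_loc"].std(ddof=1) <= 1.0
        assert eb["theta_scale"].std(ddof=1) <= 1.0


class TestPlausibleValues:
    def test_moments_match_eb(self, quickfit):
        data, _, fit = quickfit
        eb = fit.eb
        draws = plausible_values(data, fit.params, n_draws=10_000, seed=1, n_quad=15)
        mean_err = np.abs(draws[:, :, 0].mean(axis=1) - eb["theta_loc"].to_numpy())
        tol = 3.0 * eb["psd_loc"].to_numpy() / math.sqrt(10_000) + 0.01
        assert (mean_err < tol).all()
        sd_ratio = draws[:, :, 1].std(axis=1) / eb["psd_scale"].to_numpy()
        assert ((sd_ratio > 0.9) & (sd_ratio < 1.1)).all()

    def test_seed_reproducibility(self, quickfit):
        data, _, fit = quickfit
        a = plausible_values(data, fit.params, 50, seed=3)
        b = plausible_values(data, fit.params, 50, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_laplace_variant_close_to_grid(self, quickfit):
        data, _, fit = quickfit
        g = plausible_values(data, fit.params, 4000, seed=4, method="grid")
        l = plausible_values(data, fit.params, 4000, seed=4, method="laplace")
        assert np.abs(g[:, :, 0].mean(axis=1) - l[:, :, 0].mean(axis=1)).max() < 0.1

    def test_invalid_draws(self, quickfit):
        data, _, fit = quickfit
        with pytest.raises(ValueError):
            plausible_values(data, fit.params, 0)


class TestParams:
    def test_cholesky_roundtrip(self):
        p = MelsParams(0.3, -0.2, 1.1, 0.7, -0.4)
        q = MelsParams.from_cholesky(0.3, -0.2, *p.cholesky())
        assert q.sigma_w == pytest.approx(0.7)
        assert q.rho_vw == pytest.approx(-0.4)

    @pytest.mark.parametrize("kwargs", [{"sigma_v": 0.0}, {"sigma_w": -1.0}, {"rho_vw": 1.0}])
    def test_validation(self, kwargs):
        base = {"beta0": 0.0, "tau0": 0.0, "sigma_v": 1.0, "sigma_w": 1.0, "rho_vw": 0.0}
        with pytest.raises(ValueError):
            MelsParams(**{**base, **kwargs})
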