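import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import sutse
from sutse.inference import MCMCConfig, PriorSpec

from conftest import degenerate_posterior


@pytest.fixture(scope="module")
def small_fit():
    """Reduced-size posterior used by several tests (C=2, T=60, q=1)."""
    cfg = sutse.make_fixture(2, 60, 1, seed=9)
    res = sutse.simulate(cfg)
    post = sutse.sample_posterior(
        res.log_series, cfg.spec, config=MCMCConfig(n_chains=2, n_warmup=250, n_keep=300, seed=4)
    )
    return cfg, res, post


class TestSampler:
    def test_fixed_seed_reproduces_draw_tables(self):
        cfg = sutse.make_fixture(2, 40, 0, seed=5)
        res = sutse.simulate(cfg)
        mc = MCMCConfig(n_chains=2, n_warmup=120, n_keep=120, seed=11)
        a = sutse.sample_posterior(res.log_series, cfg.spec, config=mc)
        b = sutse.sample_posterior(res.log_series, cfg.spec, config=mc)
        for ca, cb in zip(a.chains, b.chains):
            pd.testing.assert_frame_equal(ca, cb)

    def test_chains_have_equal_lengths_and_valid_correlations(self, small_fit):
        _, _, post = small_fit
        assert len({len(c) for c in post.chains}) == 1
        for mats in (post.corr_draws("evolution"), post.corr_draws("error")):
            assert np.abs(mats).max() <= 1.0
            # stored correlation draws reassemble into PD matrices
            assert min(np.linalg.eigvalsh(m).min() for m in mats[::50]) > 0

    def test_posterior_concentrates_near_truth(self, small_fit):
        cfg, _, post = small_fit
        pool = post.pooled()
        sig = pool[[f"sigma[{n}]" for n in post.series_names]].mean().to_numpy()
        assert np.all(np.abs(sig - cfg.params.obs_sd) < 0.05)

    def test_prior_predictive_correlations_match_lkj_marginals(self):
        """With only two near-noninformative observations the posterior over the
        correlations should be statistically indistinguishable from the LKJ
        prior (uniform marginals at C=2)."""
        data = sutse.ObservedSeries(
            np.array([[7.0, 7.2], [7.01, 7.19]]), ["2007-01", "2007-02"], ["a", "b"]
        )
        spec = sutse.build_model(2, 0)
        post = sutse.sample_posterior(
            data, spec, config=MCMCConfig(n_chains=3, n_warmup=300, n_keep=900, seed=2)
        )
        for col in ("rho_eps[a,b]", "rho_delta[a,b]"):
            draws = post.pooled()[col].to_numpy()[::4]  # thin for the iid KS test
            assert kstest(draws, "uniform", args=(-1, 2)).pvalue > 0.01


class TestSampleStates:
    def test_thin_equal_to_total_yields_one_trajectory(self, small_fit):
        cfg, res, post = small_fit
        sutse.sample_states(post, res.log_series, cfg.spec, thin=post.n_draws, rng=0)
        assert post.state_draws.shape == (1, res.log_series.n_obs + 1, cfg.spec.state_dim)

    def test_thin_validation(self, small_fit):
        cfg, res, post = small_fit
        with pytest.raises(ValueError):
            sutse.sample_states(post, res.log_series, cfg.spec, thin=0)

    def test_deterministic_under_seed(self, small_fit):
        cfg, res, post = small_fit
        a = sutse.sample_states(post, res.log_series, cfg.spec, thin=40, rng=3).state_draws
        b = sutse.sample_states(post, res.log_series, cfg.spec, thin=40, rng=3).state_draws
        assert np.array_equal(a, b)

    def test_pooled_draws_match_smoother_mixture(self, toy_c2):
        """For a degenerate posterior the FFBS mixture collapses to a single
        smoother; pooled state draws must match its moments."""
        post = degenerate_posterior(toy_c2["params"], ["a", "b"], n_draws=60)
        sutse.sample_states(post, toy_c2["data"], toy_c2["spec"], thin=1, rng=1)
        sm, sc = sutse.smooth(
            toy_c2["spec"], toy_c2["params"], toy_c2["data"], init_var=post.priors.init_state_var
        )
        sd = np.sqrt(np.array([np.diag(c) for c in sc]))
        z = np.abs(post.state_draws.mean(axis=0) - sm) / np.maximum(sd / np.sqrt(60), 1e-12)
        assert z.max() < 4.5


class TestDIC:
    def test_identical_draws_give_zero_complexity(self, toy_c2):
        post = degenerate_posterior(toy_c2["params"], ["a", "b"], n_draws=5)
        out = sutse.dic(post, toy_c2["data"], toy_c2["spec"])
        assert out["p_d"] == pytest.approx(0.0, abs=1e-8)
        assert out["dic"] == pytest.approx(out["mean_deviance"], abs=1e-8)

    def test_two_draw_toy_matches_direct_evaluation(self, toy_c2):
        """DIC recomputed term by term from filter likelihood evaluations."""
        rng = np.random.default_rng(1)
        corr = sutse.sample_prior_corr(2, 1.0, 2, rng)
        p1 = sutse.CovParams([0.3, 0.4], corr[0], [0.1, 0.2], corr[1])
        p2 = sutse.CovParams([0.5, 0.3], corr[1], [0.05, 0.15], corr[0])
        post = degenerate_posterior(p1, ["a", "b"], n_draws=1)
        post.chains = [pd.concat([post.chains[0],
                                  degenerate_posterior(p2, ["a", "b"], 1).chains[0]],
                                 ignore_index=True)]
        data, spec = toy_c2["data"], toy_c2["spec"]
        out = sutse.dic(post, data, spec)
        kappa = post.priors.init_state_var
        devs = [-2 * sutse.kalman_filter(spec, p, data, init_var=kappa).log_marginal_likelihood
                for p in (p1, p2)]
        d_bar = np.mean(devs)
        sig_eps = (p1.obs_cov + p2.obs_cov) / 2
        sig_del = (p1.evo_cov + p2.evo_cov) / 2

        def decomp(S):
            sd = np.sqrt(np.diag(S))
            return sd, S / np.outer(sd, sd)

        osd, oc = decomp(sig_eps)
        esd, ec = decomp(sig_del)
        p_bar = sutse.CovParams(osd, oc, esd, ec)
        d_hat = -2 * sutse.kalman_filter(spec, p_bar, data, init_var=kappa).log_marginal_likelihood
        assert out["mean_deviance"] == pytest.approx(d_bar, rel=1e-9)
        assert out["p_d"] == pytest.approx(d_bar - d_hat, rel=1e-9, abs=1e-9)
        assert out["dic"] == pytest.approx(2 * d_bar - d_hat, rel=1e-9)

    def test_needs_at_least_two_draws(self, toy_c2):
        post = degenerate_posterior(toy_c2["params"], ["a", "b"], n_draws=1)
        with pytest.raises(ValueError):
            sutse.dic(post, toy_c2["data"], toy_c2["spec"])

    def test_prefers_the_generating_seasonal_order(self):
        """Median DIC over replicates is lower for the q=2 model when the data
        carry two genuine harmonics."""
        diffs = []
        for rep in range(5):
            spec = sutse.build_model(2, 2)
            params = sutse.CovParams([0.05, 0.05], np.eye(2), [0.001, 0.001], np.eye(2))
            init = np.zeros(spec.state_dim)
            init[0], init[spec.block_dim] = 7.0, 7.5
            init[2:6] = [0.25, 0.10, -0.12, 0.06]
            init[spec.block_dim + 2 : spec.block_dim + 6] = [0.20, -0.15, 0.10, 0.05]
            cfg = sutse.SimulationConfig(
                spec=spec, params=params, init_state=init, n_months=96, seed=300 + rep
            )
            res = sutse.simulate(cfg)
            dics = {}
            for q in (2, 0):
                sp = sutse.build_model(2, q)
                post = sutse.sample_posterior(
                    res.log_series, sp,
                    config=MCMCConfig(n_chains=2, n_warmup=200, n_keep=200, seed=rep),
                )
                dics[q] = sutse.dic(post, res.log_series, sp, thin=4)["dic"]
            diffs.append(dics[2] - dics[0])
        assert np.median(diffs) < 0


class TestDiagnostics:
    def test_constant_equal_chains_have_unit_psrf(self):
        out = sutse.psrf(np.ones((3, 100)))
        assert out["point"] == 1.0 and out["upper95"] == 1.0

    def test_iid_chains_pass_gates(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((3, 4000))
        out = sutse.psrf(chains)
        assert out["point"] < 1.01 and out["upper95"] < 1.01
        assert sutse.ess(chains) >= 0.5 * chains.size

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((2, 1000))
        chains[1] += 5.0
        out = sutse.psrf(chains)
        assert out["point"] > 2.0
        # cross-check: the between/within variance ratio drives the statistic,
        # so the point estimate must be at least the plain (un-adjusted) R
        # and its 95% bound at least the point estimate
        m, n = 4, 500  # split chains
        x = np.concatenate([chains[:, :500], chains[:, 500:]], axis=0)
        W = x.var(axis=1, ddof=1).mean()
        B = n * x.mean(axis=1).var(ddof=1)
        plain = np.sqrt((n - 1) / n + (1 + 1 / m) * B / (n * W))
        assert plain > 2.0
        assert plain <= out["point"] <= np.sqrt(3.0) * plain  # df adjustment < (0+3)/(0+1)
        assert out["upper95"] >= out["point"]

    def test_psrf_input_validation(self):
        with pytest.raises(ValueError):
            sutse.psrf(np.ones((1, 100)))
        with pytest.raises(ValueError):
            sutse.psrf(np.ones(100))


class TestConfigValidation:
    def test_bad_mcmc_config(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=0)

    def test_bad_priors(self):
        with pytest.raises(ValueError):
            PriorSpec(sd_scale=-1.0)
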