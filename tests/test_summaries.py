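import numpy as np
import pandas as pd
import pytest

import sutse
from sutse.summaries import empirical_quantile

from conftest import degenerate_posterior
from oracles import energy_stat_hand


class TestScalarSummaries:
    def test_prob_positive_counts_strictly_positive(self):
        assert sutse.prob_positive([0.5, 0.2, -0.1, 0.3]) == 0.75
        assert sutse.prob_positive([-1.0, -0.2]) == 0.0
        assert sutse.prob_positive([0.0, 1.0]) == 0.5  # zeros are not positive

    def test_prob_positive_matches_direct_count(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.1, 1.0, 12000)
        assert sutse.prob_positive(x) == np.sum(x > 0) / 12000

    def test_one_sided_lower_is_order_statistic(self):
        samples = np.arange(1, 101) / 100.0
        assert sutse.one_sided_lower(samples, 0.95) == pytest.approx(0.05)
        assert sutse.one_sided_lower(np.full(7, 0.3)) == 0.3

    def test_one_sided_lower_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=997)
        k = int(np.ceil(0.05 * 997))
        assert sutse.one_sided_lower(x) == np.sort(x)[k - 1]

    def test_validation(self):
        with pytest.raises(ValueError):
            sutse.one_sided_lower([1.0], level=1.0)
        with pytest.raises(ValueError):
            sutse.prob_positive([])


class TestPartialCorrelations:
    def test_identity_has_no_partial_structure(self):
        assert np.allclose(sutse.partial_correlations(np.eye(4)), np.eye(4))

    @pytest.mark.parametrize("rho", np.linspace(-0.9, 0.9, 7))
    def test_two_by_two_is_involution(self, rho):
        omega = np.array([[1.0, rho], [rho, 1.0]])
        assert sutse.partial_correlations(omega) == pytest.approx(omega, abs=1e-12)

    def test_equicorrelation_closed_form(self):
        omega = np.full((3, 3), 0.5)
        np.fill_diagonal(omega, 1.0)
        out = sutse.partial_correlations(omega)
        expected = np.full((3, 3), 1.0 / 3.0)
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(out, expected, atol=1e-12)

    def test_scale_invariance(self):
        """Partial correlations of a covariance equal those of its correlation."""
        omega = np.array([[1.0, 0.3, -0.2], [0.3, 1.0, 0.5], [-0.2, 0.5, 1.0]])
        sd = np.array([0.3, 2.0, 11.0])
        cov = omega * np.outer(sd, sd)
        assert np.allclose(
            sutse.partial_correlations(cov), sutse.partial_correlations(omega), atol=1e-12
        )

    def test_singular_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            sutse.partial_correlations(np.ones((3, 3)))


class TestCorrelationSummary:
    def test_degenerate_posterior_table(self, toy_c2):
        params = sutse.CovParams(
            obs_sd=[0.1, 0.1], obs_corr=np.eye(2),
            evo_sd=[0.01, 0.01], evo_corr=[[1.0, 0.3], [0.3, 1.0]],
        )
        post = degenerate_posterior(params, ["a", "b"], n_draws=20)
        tab = sutse.correlation_summary(post, "evolution")
        assert tab.prob_positive[0, 1] == 1.0
        assert tab.lower_bound[1, 0] == pytest.approx(0.3)
        # 2x2 partial correlation equals the correlation itself
        part = sutse.correlation_summary(post, "partial-evolution")
        assert part.lower_bound[1, 0] == pytest.approx(0.3, abs=1e-12)

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(5)
        names = ["x", "y", "z"]
        chain = pd.DataFrame(
            {
                **{f"sigma[{n}]": rng.uniform(0.1, 0.2, 400) for n in names},
                **{f"gamma[{n}]": rng.uniform(0.01, 0.02, 400) for n in names},
                **{f"rho_eps[{a},{b}]": rng.uniform(-0.5, 0.9, 400)
                   for a, b in [("x", "y"), ("x", "z"), ("y", "z")]},
                **{f"rho_delta[{a},{b}]": rng.uniform(-0.9, 0.9, 400)
                   for a, b in [("x", "y"), ("x", "z"), ("y", "z")]},
            }
        )
        post = degenerate_posterior(
            sutse.CovParams([0.1] * 3, np.eye(3), [0.01] * 3, np.eye(3)), names, 1
        )
        post.chains = [chain]
        tab = sutse.correlation_summary(post, "error")
        draws = chain["rho_eps[x,z]"].to_numpy()
        assert tab.prob_positive[0, 2] == sutse.prob_positive(draws)
        assert tab.lower_bound[2, 0] == sutse.one_sided_lower(draws)
        # invariant to chain concatenation order
        post.chains = [chain.iloc[200:].reset_index(drop=True),
                       chain.iloc[:200].reset_index(drop=True)]
        tab2 = sutse.correlation_summary(post, "error")
        assert tab2.prob_positive[0, 2] == tab.prob_positive[0, 2]
        assert tab2.lower_bound[2, 0] == tab.lower_bound[2, 0]

    def test_unknown_kind(self, toy_c2):
        post = degenerate_posterior(toy_c2["params"], ["a", "b"], 3)
        with pytest.raises(ValueError):
            sutse.correlation_summary(post, "sideways")

    def test_table_layout(self, toy_c2):
        post = degenerate_posterior(toy_c2["params"], ["a", "b"], 3)
        frame = sutse.correlation_summary(post, "evolution").to_frame()
        assert frame.iat[0, 0] == "-"
        assert 0.0 <= float(frame.iat[0, 1]) <= 1.0


class TestSmoothedSeries:
    def test_single_draw_bands_collapse(self, toy_c2):
        spec = toy_c2["spec"]
        draw = np.random.default_rng(0).normal(size=(1, 7, spec.state_dim))
        out = sutse.smoothed_series(draw, spec, scale="log", component="fit")
        assert np.allclose(out["mean"], out["lower95"])
        assert np.allclose(out["mean"], out["upper95"])

    def test_zero_evolution_trend_is_linear_per_draw(self, toy_c2):
        spec, data = toy_c2["spec"], toy_c2["data"]
        params = sutse.CovParams([0.3, 0.5], toy_c2["params"].obs_corr, [0.0, 0.0], np.eye(2))
        fr = sutse.kalman_filter(spec, params, data)
        draws = sutse.ffbs(fr, spec, params, np.random.default_rng(3), n_draws=1)
        out = sutse.smoothed_series(draws, spec, scale="log", component="trend")
        for _, sub in out.groupby("series"):
            assert np.abs(np.diff(sub["mean"].to_numpy(), n=2)).max() < 1e-9

    def test_count_scale_mean_is_mean_of_exponentials(self, toy_c2):
        spec = toy_c2["spec"]
        rng = np.random.default_rng(1)
        draws = rng.normal(1.0, 0.8, size=(200, 5, spec.state_dim))
        log_out = sutse.smoothed_series(draws, spec, scale="log", component="fit")
        cnt_out = sutse.smoothed_series(draws, spec, scale="count", component="fit")
        # Jensen: E[exp X] > exp(E X) strictly for dispersed draws
        assert np.all(cnt_out["mean"].to_numpy() > np.exp(log_out["mean"].to_numpy()))

    def test_no_draws_rejected(self, toy_c2):
        with pytest.raises(ValueError):
            sutse.smoothed_series(np.empty((0, 3, 8)), toy_c2["spec"])


class TestResiduals:
    def test_pure_subtraction_contract(self, toy_c2):
        spec, data = toy_c2["spec"], toy_c2["data"]
        draws = np.random.default_rng(2).normal(size=(50, 7, spec.state_dim))
        res = sutse.residuals(data, draws, spec)
        manual = data.log_counts - np.einsum(
            "ntp,cp->ntc", draws[:, 1:], spec.obs_matrix
        ).mean(axis=0)
        assert np.allclose(res, manual)
        shifted = sutse.ObservedSeries(
            data.log_counts + 1.0, data.months.astype(str), ["a", "b"]
        )
        assert np.allclose(sutse.residuals(shifted, draws, spec), res + 1.0)

    def test_perfect_fit_gives_zero(self, toy_c2):
        spec, data = toy_c2["spec"], toy_c2["data"]
        # craft a single state draw whose observation mean reproduces the data
        draw = np.zeros((1, 7, spec.state_dim))
        for c in range(2):
            draw[0, 1:, spec.coords_of(c, "level")] = data.log_counts[:, c]
        assert np.abs(sutse.residuals(data, draw, spec)).max() < 1e-12


class TestEnergyTest:
    def test_statistic_matches_hand_formula_in_one_dimension(self):
        y = np.array([-1.2, 0.3, 0.9])
        from sutse.summaries import _energy_statistic

        assert _energy_statistic(y[:, None]) == pytest.approx(
            energy_stat_hand(y, 1), abs=1e-10
        )

    def test_null_calibration(self):
        """Gaussian data should rarely be rejected at the 5% level."""
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(20):
            x = rng.standard_normal((120, 6))
            out = sutse.energy_normality_test(x, n_boot=120, rng=rng)
            rejections += out["p_value"] < 0.05
        assert rejections <= 2

    def test_power_against_heavy_tails(self):
        """Multivariate t with 2 df should almost always be rejected."""
        rng = np.random.default_rng(1)
        rejections = 0
        for _ in range(20):
            z = rng.standard_normal((120, 6))
            chi = rng.chisquare(2, size=120) / 2.0
            x = z / np.sqrt(chi)[:, None]
            out = sutse.energy_normality_test(x, n_boot=120, rng=rng)
            rejections += out["p_value"] < 0.05
        assert rejections >= 18

    def test_validation(self):
        with pytest.raises(ValueError):
            sutse.energy_normality_test(np.zeros((3, 6)), n_boot=120)
        with pytest.raises(ValueError):
            sutse.energy_normality_test(np.random.default_rng(0).normal(size=(30, 2)), n_boot=50)


class TestRawCorrelations:
    def test_proportional_and_negated_columns(self):
        t = np.arange(1, 13, dtype=float)
        table = np.column_stack([t, 3 * t, -t])
        corr = sutse.raw_correlations(table)
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert corr.iloc[0, 2] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 3))
        corr = sutse.raw_correlations(x).to_numpy()
        assert np.allclose(corr, np.corrcoef(x.T), atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sutse.raw_correlations(np.column_stack([np.arange(5.0), np.ones(5)]))


class TestDensitySummary:
    def test_median_and_mass(self):
        rng = np.random.default_rng(4)
        x = np.clip(rng.normal(0.0, 0.3, 4000), -0.99, 0.99)
        out = sutse.density_summary(x)
        assert abs(out["median"]) < 0.02
        assert out["median"] == empirical_quantile(x, 0.5)
        mass = np.trapezoid(out["density"], out["grid"])
        assert abs(mass - 1.0) < 0.02

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            sutse.density_summary(np.arange(5))
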