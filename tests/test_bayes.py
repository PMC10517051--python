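"""Constrained-slope Bayesian model: priors, joint density, grid and MCMC fits."""

import math

import numpy as np
import pytest
from scipy import stats

from corstab import (
    PopulationSpec,
    estimate_trajectory_bayes,
    fit_posterior_grid,
    fit_posterior_mcmc,
    generate_batch,
    log_joint,
    make_prior,
    prefix_pearson,
)
from corstab.bayes import DEFAULT_B_GRID, DEFAULT_S_GRID, PriorSpec


class TestPriors:
    def test_weak_is_beta_2_2_centered_at_zero(self):
        prior = make_prior("weak")
        assert (prior.beta_a, prior.beta_b) == (2.0, 2.0)
        assert prior.mode_correlation() == pytest.approx(0.0, abs=1e-12)

    def test_moderate_shapes_from_mode_identity(self):
        """Mode at rho=0.2 with kappa=10 gives Beta(5.8, 4.2)."""
        prior = make_prior("moderate", rho_center=0.2, concentration=10)
        assert prior.beta_a == pytest.approx(5.8, abs=1e-12)
        assert prior.beta_b == pytest.approx(4.2, abs=1e-12)

    @pytest.mark.parametrize("label", ["moderate", "high"])
    @pytest.mark.parametrize("rho", [-0.5, 0.1, 0.4])
    def test_mode_round_trip(self, label, rho):
        prior = make_prior(label, rho_center=rho)
        assert prior.mode_correlation() == pytest.approx(rho, abs=1e-12)

    def test_flat_concentration_rejected(self):
        with pytest.raises(ValueError):
            make_prior("moderate", rho_center=0.2, concentration=2.0)

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(0.0, 2.0)


class TestLogJoint:
    def test_outside_support_is_minus_infinity(self, small_dataset):
        x, y = small_dataset
        prior = make_prior("weak")
        assert log_joint(x, y, 1.0, 0.0, 1.0, prior) == -np.inf
        assert log_joint(x, y, -1.0, 0.0, 1.0, prior) == -np.inf
        assert log_joint(x, y, 0.5, 0.0, -1.0, prior) == -np.inf

    def test_weak_prior_prefers_center_over_extremes(self):
        prior = make_prior("weak")
        assert prior.log_slope_prior(0.0) > prior.log_slope_prior(0.9)
        assert prior.log_slope_prior(0.0) > prior.log_slope_prior(-0.9)

    def test_matches_independent_term_by_term_sum(self, small_dataset):
        """Independently coded density (scipy building blocks) agrees to 1e-10."""
        x, y = small_dataset
        prior = make_prior("weak")
        b, a, s = 0.25, -0.1, 1.2
        expected = (
            stats.norm.logpdf(y, loc=a + b * x, scale=s).sum()
            + stats.beta.logpdf((b + 1) / 2, 2, 2)
            + math.log(0.5)  # Jacobian of (b+1)/2
            + stats.norm.logpdf(a, 0, 2.5)
            + stats.halfcauchy.logpdf(s, scale=1.0)
        )
        assert log_joint(x, y, b, a, s, prior) == pytest.approx(expected, abs=1e-10)


def brute_force_posterior(x, y, prior, levels=(0.66, 0.90, 0.95)):
    """Independent oracle: dense 3D quadrature over (intercept, slope, scale)."""
    n = len(x)
    a_grid = np.linspace(-3, 3, 241)
    b_grid = DEFAULT_B_GRID
    s_grid = DEFAULT_S_GRID
    resid2 = (
        (y[None, None, :] - a_grid[:, None, None] - b_grid[None, :, None] * x[None, None, :])
        ** 2
    ).sum(-1)
    s2 = s_grid**2
    logf = (
        -n * np.log(s_grid)[None, None, :]
        - resid2[:, :, None] / (2 * s2)[None, None, :]
        + stats.norm.logpdf(a_grid, 0, prior.intercept_scale)[:, None, None]
        + stats.halfcauchy.logpdf(s_grid, scale=prior.sigma_scale)[None, None, :]
        + (stats.beta.logpdf((b_grid + 1) / 2, prior.beta_a, prior.beta_b) + math.log(0.5))[
            None, :, None
        ]
    )
    w_a, w_s = np.gradient(a_grid), np.gradient(s_grid)
    f = np.exp(logf - logf.max())
    pb = np.einsum("abs,a,s->b", f, w_a, w_s)
    Z = np.trapezoid(pb, b_grid)
    mean = np.trapezoid(pb * b_grid, b_grid) / Z
    cdf = np.concatenate([[0], np.cumsum(0.5 * (pb[1:] + pb[:-1]) * np.diff(b_grid))]) / Z
    quants = {
        lvl: (
            float(np.interp(0.5 * (1 - lvl), cdf, b_grid)),
            float(np.interp(0.5 * (1 + lvl), cdf, b_grid)),
        )
        for lvl in levels
    }
    return float(mean), quants


class TestGridPosterior:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_brute_force_3d_quadrature(self, seed):
        """Collapsed grid matches a dense (a, b, s) quadrature on n=20 data."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(20)
        y = 0.2 * x + rng.standard_normal(20)
        prior = make_prior("weak")
        summ = fit_posterior_grid(x, y, prior)
        mean_bf, quants_bf = brute_force_posterior(x, y, prior)
        assert summ.mean == pytest.approx(mean_bf, abs=1e-3)
        for lvl in (0.66, 0.90, 0.95):
            assert summ.quantiles[lvl][0] == pytest.approx(quants_bf[lvl][0], abs=2e-3)
            assert summ.quantiles[lvl][1] == pytest.approx(quants_bf[lvl][1], abs=2e-3)

    def test_sign_antisymmetry_under_y_negation(self, small_dataset):
        """Weak prior: flipping y negates the posterior mean of the slope."""
        x, y = small_dataset
        prior = make_prior("weak")
        pos = fit_posterior_grid(x, y, prior)
        neg = fit_posterior_grid(x, -y, prior)
        assert neg.mean == pytest.approx(-pos.mean, abs=1e-9)
        lo, hi = neg.quantiles[0.95]
        plo, phi = pos.quantiles[0.95]
        assert lo == pytest.approx(-phi, abs=1e-6)
        assert hi == pytest.approx(-plo, abs=1e-6)

    def test_likelihood_dominates_at_large_n(self):
        """rho=0.4, n=400, weak prior: posterior mean within 0.02 of sample r."""
        batch = generate_batch(PopulationSpec(rho=0.4), 1, 10, 400, master_seed=5)
        x, y = batch.data[0, :, 0], batch.data[0, :, 1]
        r = float(prefix_pearson(batch.data, n_min=400)[0, 0])
        summ = fit_posterior_grid(x, y, make_prior("weak"))
        assert summ.mean == pytest.approx(r, abs=0.02)

    def test_posterior_mean_increasing_in_sample_correlation(self, rng):
        """Same x, residuals scaled to sweep r: posterior mean rises with r."""
        n = 40
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        e -= e.mean() + x * (x @ e) / (x @ x)  # orthogonalize to x
        prior = make_prior("weak")
        means = []
        for slope in (-0.6, -0.2, 0.0, 0.3, 0.7):
            y = slope * x + 0.8 * e
            means.append(fit_posterior_grid(x, y, prior).mean)
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_shrinkage_toward_mode_monotone_in_concentration(self, small_dataset):
        """|posterior mean - prior mode| is non-increasing in kappa."""
        x, y = small_dataset
        gaps = []
        for kappa in (5, 10, 25, 50, 200):
            prior = make_prior("moderate", rho_center=0.2, concentration=kappa)
            gaps.append(abs(fit_posterior_grid(x, y, prior).mean - 0.2))
        assert all(a >= b - 1e-12 for a, b in zip(gaps, gaps[1:]))

    def test_weak_and_frequentist_converge_with_n(self):
        """Mean |posterior mean - sample r| shrinks as n grows."""
        batch = generate_batch(PopulationSpec(rho=0.2), 40, 10, 300, master_seed=9)
        prior = make_prior("weak")
        diffs = {}
        for n in (15, 60, 300):
            r = prefix_pearson(batch.data, n_min=n)[:, n - n]
            gaps = []
            for rep in range(40):
                x, y = batch.data[rep, :n, 0], batch.data[rep, :n, 1]
                gaps.append(abs(fit_posterior_grid(x, y, prior).mean - r[rep]))
            diffs[n] = np.mean(gaps)
        assert diffs[15] > diffs[60] > diffs[300]

    def test_minimum_size_enforced(self, rng):
        with pytest.raises(ValueError):
            fit_posterior_grid(rng.standard_normal(2), rng.standard_normal(2), make_prior("weak"))


class TestTrajectoryRecords:
    def test_regularization_pulls_extreme_estimate_toward_zero(self):
        """n=10 with sample r=0.95: weak-prior point estimate is shrunk."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(10)
        e = rng.standard_normal(10)
        e -= e.mean() + x * (x @ e) / (x @ x)
        e /= np.std(e)
        xs = (x - x.mean()) / x.std()
        r_target = 0.95
        y = r_target * xs + math.sqrt(1 - r_target**2) * e
        stream = np.column_stack([x, y])
        recs = estimate_trajectory_bayes(stream, make_prior("weak"), n_min=10, n_max=10)
        assert 0 < recs[0].point < 0.95

    def test_high_prior_keeps_point_in_prior_mass(self):
        rng = np.random.default_rng(4)
        stream = rng.standard_normal((10, 2))
        prior = make_prior("high", rho_center=0.2)
        recs = estimate_trajectory_bayes(stream, prior, n_min=10, n_max=10)
        lo, hi = stats.beta.ppf([0.025, 0.975], prior.beta_a, prior.beta_b) * 2 - 1
        assert lo < recs[0].point < hi

    def test_record_count_matches_grid(self, rng):
        stream = rng.standard_normal((50, 2))
        recs = estimate_trajectory_bayes(
            stream, make_prior("weak"), n_min=10, n_max=50, n_grid=[10, 20, 50]
        )
        assert [r.n for r in recs] == [10, 20, 50]
        assert all(r.model_tag == "weak" for r in recs)

    def test_grid_outside_bounds_rejected(self, rng):
        stream = rng.standard_normal((50, 2))
        with pytest.raises(ValueError):
            estimate_trajectory_bayes(
                stream, make_prior("weak"), n_min=10, n_max=50, n_grid=[5]
            )


class TestMCMC:
    def test_deterministic_given_seed(self, small_dataset):
        x, y = small_dataset
        prior = make_prior("weak")
        a = fit_posterior_mcmc(x, y, prior, seed=11, iterations=500, warmup=100)
        b = fit_posterior_mcmc(x, y, prior, seed=11, iterations=500, warmup=100)
        assert a.mean == b.mean
        assert a.quantiles == b.quantiles

    def test_converges_and_agrees_with_grid(self):
        """Well-behaved n=100 fit: R-hat < 1.01 and mean within 3 MC SE of grid."""
        batch = generate_batch(PopulationSpec(rho=0.3), 1, 10, 100, master_seed=13)
        x, y = batch.data[0, :, 0], batch.data[0, :, 1]
        prior = make_prior("weak")
        mc = fit_posterior_mcmc(x, y, prior, seed=2, chains=4, iterations=4000, warmup=1000)
        assert mc.diagnostics["rhat"] < 1.01
        assert mc.diagnostics["ess"] > 400
        grid = fit_posterior_grid(x, y, prior)
        # posterior sd from the grid quantiles as a scale reference
        sd = (grid.quantiles[0.95][1] - grid.quantiles[0.95][0]) / (2 * 1.96)
        mcse = sd / math.sqrt(mc.diagnostics["ess"])
        assert abs(mc.mean - grid.mean) < 3 * mcse

    def test_chain_count_validated(self, small_dataset):
        x, y = small_dataset
        with pytest.raises(ValueError):
            fit_posterior_mcmc(x, y, make_prior("weak"), chains=1)
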