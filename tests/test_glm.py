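"""IRLS GLM engine vs independent oracles, plus the derived tests."""

import numpy as np
import pytest
from scipy import optimize, stats
from scipy.special import expit, logit

from vertpattern.glm import (
    GLMError,
    compare_slopes,
    fit_severity_glm,
    freq_trend,
    interaction_lrt,
    irls_logit,
    overdispersion_check,
    pattern_covariate_chisq,
)

SEVERITY_VALUES = np.array([0, 1, 3, 4, 6, 7, 8, 9], dtype=float)


def _sim_design(rng, n=300, beta=(-2.0, 0.25)):
    s = rng.choice(SEVERITY_VALUES, size=n)
    X = np.column_stack([np.ones(n), s])
    y = (rng.random(n) < expit(X @ np.asarray(beta))).astype(float)
    return X, y, s


def _brute_force_mle(X, y):
    """Independent maximisation of the Bernoulli log-likelihood with an
    analytic gradient/Hessian handed to a generic trust-region optimiser."""

    def nll(b):
        eta = X @ b
        return float(np.sum(np.logaddexp(0, eta) - y * eta))

    def grad(b):
        return X.T @ (expit(X @ b) - y)

    def hess(b):
        mu = expit(X @ b)
        return (X.T * (mu * (1 - mu))) @ X

    res = optimize.minimize(nll, np.zeros(X.shape[1]), jac=grad, hess=hess,
                            method="trust-exact", tol=1e-14)
    return res.x


class TestIRLS:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_likelihood_maximisation(self, seed):
        rng = np.random.default_rng(seed)
        X, y, _ = _sim_design(rng, n=250)
        fit = irls_logit(X, y)
        assert fit.converged
        assert np.allclose(fit.coef, _brute_force_mle(X, y), atol=1e-8)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X, y, _ = _sim_design(rng, n=400)
        fit = irls_logit(X, y)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.coef, ref.params, atol=1e-6)
        assert np.allclose(fit.se, ref.bse, rtol=1e-4)
        assert fit.deviance == pytest.approx(ref.deviance, abs=1e-6)

    def test_two_severity_closed_form(self):
        """With only two severity values the MLE is the saturated fit:
        slope = [logit(p1) - logit(p0)] / (s1 - s0)."""
        s = np.repeat([0.0, 6.0], 50)
        y = np.concatenate([np.repeat([0, 1], [40, 10]), np.repeat([0, 1], [20, 30])])
        fit = fit_severity_glm(y, s)
        expected = (logit(0.6) - logit(0.2)) / 6.0
        assert fit.coef_of("severity") == pytest.approx(expected, abs=1e-8)

    def test_all_events_rejected(self):
        with pytest.raises(GLMError):
            irls_logit(np.ones((10, 1)), np.ones(10))

    def test_separation_flagged(self):
        s = np.repeat([0.0, 6.0], 20)
        y = (s > 3).astype(float)  # perfectly separable
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_severity_glm(y, s)
        assert fit.separation

    def test_non_available_excluded_per_outcome(self):
        rng = np.random.default_rng(3)
        _, y, s = _sim_design(rng, n=200)
        y_masked = y.copy()
        y_masked[:50] = np.nan
        fit = fit_severity_glm(y_masked, s)
        assert fit.n == 150

    def test_null_wald_p_uniform(self):
        """Under a zero slope, the severity Wald p-value is uniform(0,1)."""
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(400):
            s = rng.choice(SEVERITY_VALUES, size=250)
            y = (rng.random(250) < 0.3).astype(float)
            pvals.append(fit_severity_glm(y, s).p_of("severity"))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestOverdispersion:
    def test_well_specified_ratio_near_one(self, rng):
        X, y, _ = _sim_design(rng, n=2000)
        check = overdispersion_check(irls_logit(X, y))
        assert check.ratio == pytest.approx(1.0, abs=0.15)
        assert not check.overdispersed

    def test_beta_binomial_contamination_detected(self, rng):
        # grouped counts with beta-random success probabilities inflate
        # Pearson chi-square relative to the binomial model
        n_groups, m = 60, 40
        s = rng.choice(SEVERITY_VALUES, size=n_groups)
        p = expit(-1.0 + 0.2 * s)
        p_contam = rng.beta(p * 2, (1 - p) * 2)  # strong extra-binomial noise
        events = rng.binomial(m, p_contam)
        y = np.concatenate([np.repeat([1, 0], [e, m - e]) for e in events]).astype(float)
        s_long = np.repeat(s, m)
        X = np.column_stack([np.ones_like(s_long), s_long])
        # aggregate Pearson at the severity-group level
        fit = irls_logit(X, y)
        mu = expit(X @ fit.coef)[::m]
        pearson_grouped = np.sum((events - m * mu) ** 2 / (m * mu * (1 - mu)))
        ratio = pearson_grouped / (n_groups - 2)
        assert ratio > 1.5

    def test_zero_df_errors(self):
        X = np.column_stack([np.ones(2), [0.0, 1.0]])
        fit = irls_logit(X, np.array([0.0, 1.0]))
        with pytest.raises(GLMError):
            overdispersion_check(fit)


class TestCompareSlopes:
    def test_identical_groups_zero_statistic(self, rng):
        _, y, s = _sim_design(rng)
        comp = compare_slopes(y, y, s)
        assert comp.statistic == pytest.approx(0.0, abs=1e-10)

    def test_label_swap_flips_sign(self, rng):
        _, ya, s = _sim_design(rng, beta=(-2.0, 0.1))
        _, yb, _ = _sim_design(rng, beta=(-2.0, 0.4))
        ab = compare_slopes(ya, yb, s, labels=("a", "b"))
        ba = compare_slopes(yb, ya, s, labels=("b", "a"))
        assert ab.statistic == pytest.approx(-ba.statistic, abs=1e-8)
        assert ab.p == pytest.approx(ba.p, abs=1e-10)

    def test_power_for_study_like_slope_gap(self):
        """Slopes 0.39 vs 0.16 at study-like sizes should be detected in a
        majority of replicates (two-sided alpha 0.05)."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 60
        for _ in range(n_rep):
            s = rng.choice(SEVERITY_VALUES, size=1062,
                           p=[.206, .034, .043, .043, .170, .170, .228, .106])
            ya = (rng.random(1062) < expit(-4.5 + 0.39 * s)).astype(float)
            yb = (rng.random(1062) < expit(-3.0 + 0.16 * s)).astype(float)
            rejections += compare_slopes(ya, yb, s).p < 0.05
        assert rejections / n_rep > 0.5


class TestInteractionLRT:
    def test_df_is_levels_minus_one(self, rng):
        _, y1, s = _sim_design(rng)
        _, y2, _ = _sim_design(rng)
        _, y3, _ = _sim_design(rng)
        res = interaction_lrt({"endo": y1, "meso": y2, "ecto": y3}, s)
        assert res.df == 2
        assert res.chi2 >= 0

    def test_null_distribution_chi2(self):
        """With identical generating slopes the LRT statistic follows its
        reference chi-square distribution (KS over replicates)."""
        rng = np.random.default_rng(42)
        stats_ = []
        for _ in range(150):
            s = rng.choice(SEVERITY_VALUES, size=400)
            levels = {
                lvl: (rng.random(400) < expit(-1.5 + 0.15 * s)).astype(float)
                for lvl in ("a", "b", "c")
            }
            stats_.append(interaction_lrt(levels, s).chi2)
        ks = stats.kstest(stats_, stats.chi2(df=2).cdf)
        assert ks.pvalue > 0.01

    def test_empty_level_dropped(self, rng):
        _, y1, s = _sim_design(rng)
        with pytest.warns(UserWarning, match="empty"):
            res = interaction_lrt({"a": y1, "b": y1, "empty": np.zeros_like(y1)}, s)
        assert res.levels == ["a", "b"]


class TestTrendsAndChisq:
    def test_decreasing_frequencies_negative_r(self):
        res = freq_trend(np.array([0.5, 0.4, 0.25, 0.2, 0.1]))
        assert res.r < 0 and res.n_points == 5

    def test_exactly_linear_gives_unit_correlation(self):
        res = freq_trend(np.array([0.1, 0.2, 0.3, 0.4]))
        assert abs(res.r) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(GLMError):
            freq_trend(np.array([0.1, 0.2]))
        with pytest.raises(GLMError):
            freq_trend(np.array([0.3, 0.3, 0.3]))

    def test_chisq_detects_determined_pattern(self):
        patterns = np.array(["R"] * 50 + ["CT"] * 50)
        cov = np.array(["a"] * 50 + ["b"] * 50)
        res = pattern_covariate_chisq(patterns, cov)
        assert res.p < 1e-10

    def test_chisq_null_uniform_rejection_rate(self):
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            patterns = rng.choice(["R", "CT", "CT_TL"], size=300, p=[0.3, 0.5, 0.2])
            cov = rng.choice(["M", "F"], size=300)
            rejections += pattern_covariate_chisq(patterns, cov).p < 0.05
        assert 0.01 < rejections / n_rep < 0.11

    def test_small_expected_counts_warn_and_simulate(self, rng):
        patterns = np.array(["R"] * 40 + ["CT_TL_LS"] * 3)
        cov = np.array((["a", "b"] * 22)[:43])
        res = pattern_covariate_chisq(patterns, cov, rng=rng)
        assert res.warning is not None
        assert res.simulated_p is not None and 0 < res.simulated_p <= 1
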