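"""Closed-form sustained-dose theory against quadrature and sampling oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from stochpd import (
    ModelParams,
    RegimeError,
    death_density_single,
    extinction_cdf,
    extinction_moments,
    extinction_pdf,
    factor_A,
    gumbel_quantile,
    mean_var_single,
    sample_extinction_time,
    survival_marginal,
    survival_single,
    t_max,
)
from stochpd.analytic import _dens_early, _dens_late, _surv_early, _surv_late, EULER_GAMMA


class TestSurvivalSingle:
    def test_before_pool_entry(self, p_sustained):
        # t_k(0.9) = log(3.6); no hazard accumulates before that
        assert survival_single(1.0, 0.9, p_sustained) == 1.0
        assert survival_single(0.0, 0.3, p_sustained) == 1.0

    def test_exponential_after_entry(self):
        p = ModelParams(mu=1.0, delta=1.0)
        assert survival_single(1.0, 0.25, p) == pytest.approx(math.exp(-1.0))

    def test_monotone_in_t_and_k(self, p_sustained):
        t = np.linspace(0, 20, 100)
        s = survival_single(t, 0.7, p_sustained)
        assert np.all(np.diff(s) <= 0)
        sk = [survival_single(5.0, k, p_sustained) for k in (0.1, 0.4, 0.8)]
        assert sk[0] <= sk[1] <= sk[2]

    def test_linear_kind_matches_numeric_hazard(self):
        from stochpd.model import death_rate, regulator_sustained

        p = ModelParams(mu=0.5, delta=1.0, death_rate_kind="linear")
        for k0, t in [(0.9, 3.0), (0.2, 1.5), (0.5, 8.0)]:
            H_num = integrate.quad(
                lambda s: death_rate(regulator_sustained(k0, s, p.delta), p), 0, t,
                limit=300,
            )[0]
            assert survival_single(t, k0, p) == pytest.approx(math.exp(-H_num), abs=1e-7)


class TestFactorA:
    def test_printed_value(self, p_sustained):
        assert round(factor_A(p_sustained), 2) == 1.14

    def test_limit_and_symmetric_point(self):
        assert factor_A(ModelParams(mu=1e-12, delta=1.0)) == pytest.approx(1.0)
        assert factor_A(ModelParams(mu=1.0, delta=1.0)) == pytest.approx(2.125)

    @pytest.mark.parametrize("mu,delta", [(0.2, 1.0), (1.0, 0.5), (2.0, 3.0)])
    def test_equals_quadrature(self, mu, delta):
        p = ModelParams(mu=mu, delta=delta)

        def integrand(k):
            tk = 0.0 if k <= p.k_death else math.log(k / p.k_death) / delta
            return math.exp(mu * tk)

        val, _ = integrate.quad(integrand, 0, 1, limit=200)
        assert factor_A(p) == pytest.approx(val, abs=1e-10)

    def test_requires_positive_delta(self):
        with pytest.raises(ValueError):
            factor_A(ModelParams(mu=1.0, delta=0.0))


class TestSurvivalMarginal:
    def test_endpoints(self, p_sustained):
        assert survival_marginal(0.0, p_sustained) == pytest.approx(1.0)
        assert survival_marginal(80.0, p_sustained) < 1e-5

    def test_branch_values(self, p_sustained):
        assert survival_marginal(math.log(4), p_sustained) == pytest.approx(0.8649, abs=5e-5)
        A = factor_A(p_sustained)
        assert survival_marginal(10.0, p_sustained) == pytest.approx(A * math.exp(-2.0), rel=1e-12)

    def test_branch_continuity_grid(self):
        for mu in (0.1, 0.5, 1.0, 3.0):
            for delta in (0.2, 1.0, 2.5):
                p = ModelParams(mu=mu, delta=delta)
                ts = math.log(4) / delta
                assert abs(_surv_early(ts, p) - _surv_late(ts, p)) < 1e-12
                assert abs(_dens_early(ts, p) - _dens_late(ts, p)) < 1e-12

    def test_matches_quadrature_of_single_cell(self, rng):
        for _ in range(50):
            mu = rng.uniform(0.05, 2.0)
            delta = rng.uniform(0.1, 3.0)
            t = rng.uniform(0.0, 10.0)
            p = ModelParams(mu=mu, delta=delta)
            val, _ = integrate.quad(
                lambda k: survival_single(t, k, p), 0, 1, limit=300,
                points=[p.k_death, min(1.0, p.k_death * math.exp(delta * t))],
            )
            assert survival_marginal(t, p) == pytest.approx(val, abs=1e-8)

    def test_monotone(self, p_sustained):
        t = np.linspace(0, 40, 500)
        assert np.all(np.diff(survival_marginal(t, p_sustained)) <= 0)


class TestDeathDensity:
    def test_value_at_zero_is_pool_fraction_times_mu(self, p_sustained):
        # exactly a quarter of cells start in the death pool, each dying at rate mu
        assert death_density_single(0.0, p_sustained) == pytest.approx(
            p_sustained.mu * 0.25
        )

    def test_late_branch(self, p_sustained):
        assert death_density_single(10.0, p_sustained) == pytest.approx(0.030890, abs=1e-6)

    def test_normalisation(self, p_sustained):
        val, _ = integrate.quad(
            lambda t: death_density_single(t, p_sustained), 0, np.inf, limit=300
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_is_minus_derivative_of_S(self, p_sustained):
        for t in (0.5, 2.0, 7.0):
            h = 1e-6
            num = (survival_marginal(t - h, p_sustained) - survival_marginal(t + h, p_sustained)) / (2 * h)
            assert death_density_single(t, p_sustained) == pytest.approx(num, rel=1e-5)


class TestSingleCellMoments:
    def test_instantaneous_drug_limit(self):
        mean, var = mean_var_single(ModelParams(mu=1.0, delta=1e9))
        assert mean == pytest.approx(1.0, abs=1e-8)
        assert var == pytest.approx(1.0)

    def test_variance_formula(self):
        _, var = mean_var_single(ModelParams(mu=2.0, delta=0.7))
        assert var == 0.25

    def test_mean_against_monte_carlo(self, rng):
        p = ModelParams(mu=1.0, delta=0.2)
        mean, _ = mean_var_single(p)
        assert mean == pytest.approx(5 * (math.log(4) - 0.75) + 1.0, rel=1e-12)
        k = rng.uniform(size=10**6)
        tk = np.maximum(0.0, np.log(4 * k)) / p.delta
        draws = tk + rng.exponential(1.0, size=k.size)
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - mean) < 3 * se

    def test_exact_variance_includes_entry_spread(self, p_sustained):
        _, v_approx = mean_var_single(p_sustained)
        _, v_exact = mean_var_single(p_sustained, exact_var=True)
        assert v_exact > v_approx
        assert v_exact == pytest.approx(25.2444, abs=1e-3)


class TestExtinctionMoments:
    def test_n1_harmonic_form(self):
        p = ModelParams(mu=1.0, delta=1.0)
        m = extinction_moments(1, p)
        assert m.mean_tau_n == pytest.approx(math.log(factor_A(p)) + 1.0)
        assert m.var_tau_n == pytest.approx(1.0)

    def test_large_n(self, p_sustained):
        m = extinction_moments(1000, p_sustained)
        assert m.mean_tau_n_asymptotic == pytest.approx(38.08, abs=0.02)
        assert m.mean_tau_n == pytest.approx(m.mean_tau_n_asymptotic, rel=1e-3)

    def test_variance_partial_sums_converge_monotonically(self):
        p = ModelParams(mu=1.0, delta=1.0)
        vs = [extinction_moments(n, p).var_tau_n for n in (10, 100, 1000, 10000)]
        assert np.all(np.diff(vs) > 0)
        assert vs[-1] < math.pi**2 / 6
        assert vs[-1] == pytest.approx(math.pi**2 / 6, abs=1e-3)


class TestExtinctionDistribution:
    def test_regime_guard(self, p_sustained):
        with pytest.raises(RegimeError):
            extinction_cdf(1.0, 100, p_sustained)
        # exact fallback is available everywhere
        assert 0 <= extinction_cdf(1.0, 100, p_sustained, strict=False) <= 1

    def test_cdf_at_mode(self, p_sustained):
        n = 100000
        val = extinction_cdf(t_max(n, p_sustained), n, p_sustained)
        assert val == pytest.approx(math.exp(-1.0), abs=1e-4)

    def test_n1_complements_survival(self, p_sustained):
        A = factor_A(p_sustained)
        t = 12.0
        assert extinction_cdf(t, 1, p_sustained) == pytest.approx(
            1 - A * math.exp(-p_sustained.mu * t), rel=1e-12
        )
        assert extinction_cdf(200.0, 1, p_sustained) == pytest.approx(1.0)

    def test_pdf_mode_at_t_max(self, p_sustained):
        n = 1000
        tm = t_max(n, p_sustained)
        t = np.linspace(tm - 10, tm + 10, 4001)
        f = extinction_pdf(t, n, p_sustained)
        assert t[np.argmax(f)] == pytest.approx(tm, abs=0.01)

    def test_pdf_n1_equals_single_density(self, p_sustained):
        assert extinction_pdf(10.0, 1, p_sustained) == pytest.approx(
            death_density_single(10.0, p_sustained), rel=1e-12
        )

    def test_pdf_normalises_in_regime(self, p_sustained):
        n = 1000
        t0 = math.log(4) / p_sustained.delta
        val, _ = integrate.quad(
            lambda t: extinction_pdf(t, n, p_sustained), t0, np.inf, limit=300
        )
        boundary = extinction_cdf(t0 + 1e-12, n, p_sustained)
        assert val == pytest.approx(1.0 - boundary, abs=1e-8)
        assert boundary < 1e-8

    def test_shape_invariance_under_shift(self, p_sustained):
        # increasing n shifts the density right but preserves its shape
        x = np.linspace(-4, 15, 300)
        curves = []
        for n in (10, 100, 1000):
            tm = t_max(n, p_sustained)
            curves.append(extinction_pdf(x + tm, n, p_sustained))
        assert np.max(np.abs(curves[0] - curves[2])) < 5e-3
        assert np.max(np.abs(curves[1] - curves[2])) < 5e-4


class TestGumbel:
    def test_quantiles(self, p_sustained):
        n = 1000
        tm = t_max(n, p_sustained)
        assert gumbel_quantile(math.exp(-1.0), n, p_sustained) == pytest.approx(tm, rel=1e-12)
        mu = p_sustained.mu
        assert mu * (gumbel_quantile(0.50, n, p_sustained) - tm) == pytest.approx(0.3665, abs=5e-5)
        assert mu * (gumbel_quantile(0.99, n, p_sustained) - tm) == pytest.approx(4.600, abs=1e-3)
        # the 1% quantile offset is -1.527/mu (sometimes quoted rounded as -1.50)
        assert mu * (gumbel_quantile(0.01, n, p_sustained) - tm) == pytest.approx(-1.527, abs=1e-3)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.7])
    def test_invalid_p(self, p, p_sustained):
        with pytest.raises(ValueError):
            gumbel_quantile(p, 1000, p_sustained)

    def test_sampler_moments(self, p_sustained, rng):
        n = 1000
        draws = sample_extinction_time(n, p_sustained, rng, size=10**5)
        mu = p_sustained.mu
        tm = t_max(n, p_sustained)
        assert draws.mean() == pytest.approx(tm + EULER_GAMMA / mu, abs=0.1)
        assert draws.var() == pytest.approx(math.pi**2 / 6 / mu**2, rel=0.03)

    def test_sampler_matches_quantile_function(self, p_sustained):
        # the inverse-transform draw at U = e^{-1} is exactly t_max
        class _FixedU:
            def uniform(self, size=None):
                return math.exp(-1.0)

        val = sample_extinction_time(1000, p_sustained, _FixedU())
        assert val == pytest.approx(t_max(1000, p_sustained), rel=1e-12)

    def test_sampler_ks_against_exact_cdf(self, p_sustained, rng):
        n = 1000
        draws = sample_extinction_time(n, p_sustained, rng, size=4000)
        res = stats.kstest(draws, lambda t: extinction_cdf(t, n, p_sustained, strict=False))
        assert res.statistic < 0.05
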