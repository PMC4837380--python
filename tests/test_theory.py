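import numpy as np
import pytest

from noisyvoter import (
    DegreeStats,
    ModelParams,
    acf_components,
    acf_theory,
    birth_death_stationary,
    critical_a,
    crossover_a,
    degree_stats,
    make_network,
    rho_st,
    uniform_variance,
    variance_asymptotic,
    variance_st,
    variance_st_annealed_exact,
)


def dstats(het):
    return DegreeStats.from_moments(mu_k=8.0, var_k=het * 64.0, N=2500)


class TestVarianceSt:
    def test_large_noise_limit_quarter_N(self):
        for het in (0.0, 0.25, 1.5):
            v, ok = variance_st(1000, ModelParams(a=1e7, h=1.0), dstats(het))
            assert v == pytest.approx(1000 / 4, rel=1e-4)
            assert ok

    def test_voter_limit_quarter_N_squared(self):
        for het in (0.0, 0.25, 1.5):
            v, _ = variance_st(1000, ModelParams(a=1e-9, h=1.0), dstats(het))
            assert v == pytest.approx(1000**2 / 4, rel=1e-3)

    def test_a_zero_flagged(self):
        v, ok = variance_st(100, ModelParams(a=0.0, h=1.0), dstats(0.0))
        assert v == 100**2 / 4
        assert not ok

    def test_monotone_decreasing_in_a(self):
        h = 1.0
        a_grid = np.logspace(-4, 3, 60) * h
        v = [variance_st(500, ModelParams(a, h), dstats(0.25))[0] for a in a_grid]
        assert np.all(np.diff(v) < 0)
        assert 500 / 4 <= min(v) and max(v) <= 500**2 / 4

    def test_monotone_increasing_in_heterogeneity(self):
        vals = [variance_st(2500, ModelParams(0.01, 1.0), dstats(g))[0]
                for g in (0.0, 0.1, 0.25, 1.0, 2.0)]
        assert np.all(np.diff(vals) > 0)

    def test_complete_graph_oracle_agreement(self):
        """Closed form within 0.5/N of the exact birth-death variance."""
        for N in (4, 8, 16, 32, 64):
            for a in (0.05, 0.3, 1.0, 5.0):
                p = ModelParams(a, 1.0)
                d = DegreeStats.from_moments(N - 1.0, 0.0, N)
                v, _ = variance_st(N, p, d)
                exact = birth_death_stationary(N, p).var_n
                assert abs(v / exact - 1) <= 0.5 / N

    def test_closed_form_tracks_exact_annealed_solution(self):
        g = make_network("dichotomous", 1000, seed=2, k1=4, k2=12)
        d = degree_stats(g)
        for a in (0.001, 0.01, 0.1, 1.0):
            v, _ = variance_st(1000, ModelParams(a, 1.0), d)
            ve = variance_st_annealed_exact(g.degrees, a, 1.0)
            assert v == pytest.approx(ve, rel=5e-3)

    def test_scale_invariance_in_a_over_h(self):
        for lam in (0.1, 3.0):
            v1, _ = variance_st(600, ModelParams(0.02, 1.0), dstats(0.25))
            v2, _ = variance_st(600, ModelParams(0.02 * lam, lam), dstats(0.25))
            assert v1 == pytest.approx(v2, rel=1e-12)


class TestAsymptoticBranches:
    def test_branches_agree_in_their_regimes(self):
        d = dstats(1.5)
        N, h = 2500, 1.0
        a_star = crossover_a(N, h, d)
        for a in a_star * np.array([1e-3, 1e-2]):
            vs = variance_asymptotic(N, ModelParams(a, h), d, "small_a")
            v, _ = variance_st(N, ModelParams(a, h), d)
            assert vs == pytest.approx(v, rel=0.05)
        for a in a_star * np.array([1e2, 1e3]):
            vl = variance_asymptotic(N, ModelParams(a, h), d, "large_a")
            v, _ = variance_st(N, ModelParams(a, h), d)
            assert vl == pytest.approx(v, rel=0.05)

    def test_branches_diverge_outside_their_regimes(self):
        d = dstats(1.5)
        N, h = 2500, 1.0
        a_star = crossover_a(N, h, d)
        vs = variance_asymptotic(N, ModelParams(a_star * 1e3, h), d, "small_a")
        v, _ = variance_st(N, ModelParams(a_star * 1e3, h), d)
        assert abs(vs / v - 1) > 0.5
        vl = variance_asymptotic(N, ModelParams(a_star * 1e-3, h), d, "large_a")
        v, _ = variance_st(N, ModelParams(a_star * 1e-3, h), d)
        assert abs(vl / v - 1) > 0.5

    def test_homogeneous_branches_need_no_heterogeneity(self):
        # with sigma_k^2 = 0 both branches depend on (N, a, h) only
        d1 = DegreeStats.from_moments(4.0, 0.0, 100)
        d2 = DegreeStats.from_moments(40.0, 0.0, 100)
        p = ModelParams(0.05, 1.0)
        for branch in ("small_a", "large_a"):
            assert variance_asymptotic(100, p, d1, branch) == \
                variance_asymptotic(100, p, d2, branch)


class TestCrossover:
    def test_rescaling_invariance(self):
        d = dstats(1.0)
        a1 = crossover_a(1000, 1.0, d)
        a2 = crossover_a(1000, 5.0, d)
        assert a2 / a1 == pytest.approx(5.0, rel=1e-4)

    def test_sqrtN_scaling_homogeneous(self):
        d = DegreeStats.from_moments(8.0, 0.0)
        Ns = np.array([1e3, 1e4, 1e5])
        stars = [crossover_a(int(n), 1.0, d) for n in Ns]
        slope = np.polyfit(np.log(Ns), np.log(stars), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)


class TestCriticalPoint:
    def test_homogeneous_reduces_to_meanfield(self):
        for N in (100, 1000, 10000):
            a_c, a_mf = critical_a(N, 1.0, DegreeStats.from_moments(8.0, 0.0))
            assert a_mf == 1.0 / N
            assert a_c == pytest.approx(a_mf, rel=10.0 / N)

    def test_linear_in_degree_variance(self):
        var_k = np.linspace(0.0, 64.0, 9)
        a_cs = [critical_a(2500, 1.0, DegreeStats.from_moments(8.0, v))[0]
                for v in var_k]
        resid = np.polyfit(var_k, a_cs, 1, full=True)[1][0]
        ss = np.var(a_cs) * len(a_cs)
        assert resid / ss < 1e-4
        assert np.all(np.diff(a_cs) > 0)

    def test_uniform_variance_value(self):
        assert uniform_variance(10) == pytest.approx(10.0)
        # a_c solves var_small = N(N+2)/12 by construction
        d = dstats(0.25)
        a_c, _ = critical_a(2500, 1.0, d)
        vs = variance_asymptotic(2500, ModelParams(a_c, 1.0), d, "small_a")
        assert vs == pytest.approx(uniform_variance(2500), rel=1e-10)


class TestRhoSt:
    def test_limits(self):
        d = dstats(0.25)
        assert rho_st(1000, ModelParams(1e8, 1.0), d) == pytest.approx(0.5, abs=1e-4)
        assert rho_st(1000, ModelParams(1e-10, 1.0), d) == pytest.approx(0.0, abs=1e-4)
        assert rho_st(1000, ModelParams(0.0, 1.0), d) == 0.0

    def test_decreasing_in_heterogeneity(self):
        vals = [rho_st(2500, ModelParams(0.005, 1.0), dstats(g))
                for g in (0.0, 0.25, 1.0, 2.0)]
        assert np.all(np.diff(vals) < 0)

    def test_bounded(self):
        for a in np.logspace(-5, 4, 40):
            r = rho_st(500, ModelParams(a, 1.0), dstats(1.0))
            assert 0.0 < r <= 0.5


class TestAcf:
    def test_lag_zero_equals_variance(self):
        d = dstats(0.25)
        p = ModelParams(0.02, 1.0)
        v, _ = variance_st(2500, p, d)
        assert acf_theory(0.0, 2500, p, d) == pytest.approx(v, rel=1e-12)

    def test_homogeneous_single_exponential(self):
        d = DegreeStats.from_moments(8.0, 0.0)
        p = ModelParams(0.02, 1.0)
        c = acf_components(1000, p, d)
        assert c.amp_fast == 0.0
        tau = np.linspace(0, 100, 50)
        k = acf_theory(tau, 1000, p, d)
        assert np.allclose(np.log(k / k[0]), -2 * p.a * tau)

    def test_amplitudes_sum_to_variance(self):
        d = dstats(1.0)
        p = ModelParams(0.01, 1.0)
        c = acf_components(2500, p, d)
        v, _ = variance_st(2500, p, d)
        assert c.amp_slow + c.amp_fast == pytest.approx(v, rel=1e-12)
        assert c.rate_slow == pytest.approx(2 * p.a)
        assert c.rate_fast == pytest.approx(2 * p.a + p.h)

    def test_long_lag_parallel_with_upward_shift(self):
        """log K/K(0) at long lags has slope -2a and an offset growing
        with heterogeneity (the fast weight is negative)."""
        p = ModelParams(0.01, 1.0)
        tau = np.array([300.0, 400.0])
        offsets = []
        for het in (0.1, 0.5, 2.0):
            d = dstats(het)
            k = acf_theory(tau, 2500, p, d)
            v = acf_theory(0.0, 2500, p, d)
            logk = np.log(k / v)
            slope = (logk[1] - logk[0]) / (tau[1] - tau[0])
            assert slope == pytest.approx(-2 * p.a, rel=1e-6)
            offsets.append(logk[0] + 2 * p.a * tau[0])
        assert np.all(np.array(offsets) > 0)
        assert np.all(np.diff(offsets) > 0)

    def test_exact_on_annealed_model(self, dich_small):
        """Two-exponential form vs the covariance solution of the annealed
        model itself (K(0) from the exact scalar solve)."""
        a, h = 0.15, 1.0
        k = dich_small.degrees.astype(float)
        v_exact = variance_st_annealed_exact(k, a, h)
        d = degree_stats(dich_small)
        v_closed, _ = variance_st(12, ModelParams(a, h), d)
        # closed form truncates at first order in k_i/(N mu): loose at N=12
        assert v_closed == pytest.approx(v_exact, rel=0.05)


class TestStarGraphRegression:
    def test_frozen_annealed_error_on_star(self, star5):
        """The annealed theory underestimates the exact variance of the
        maximally heterogeneous toy by a recorded, stable amount."""
        from noisyvoter import ctmc_solve
        p = ModelParams(0.3, 1.0)
        exact = ctmc_solve(star5, p).var_n
        v, _ = variance_st(5, p, degree_stats(star5))
        assert exact == pytest.approx(3.023455, rel=1e-4)
        assert v / exact - 1 == pytest.approx(-0.1123, abs=0.005)
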