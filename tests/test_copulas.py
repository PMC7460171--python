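"""Gaussian and t copulas: CDF/density identities, sampling, fitting, GoF."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import special, stats

import copulareg as cr
from copulareg.copulas import (
    DEFAULT_DF_GRID,
    cvm_statistic,
    empirical_copula,
)
from copulareg.errors import DomainError

RHO = 0.364  # the study's fitted copula correlation; a convenient test value


def normal_score_quadrature(m=160, span=8.0):
    """Nodes/weights turning a unit-square integral of a copula density into
    a smooth integral over normal scores."""
    zn, zw = np.polynomial.legendre.leggauss(m)
    z = span * zn
    w = span * zw
    u = special.ndtr(z)
    phi = np.exp(-0.5 * z * z) / math.sqrt(2 * math.pi)
    uu1, uu2 = np.meshgrid(u, u, indexing="ij")
    pts = np.column_stack([uu1.ravel(), uu2.ravel()])
    weights = np.outer(w * phi, w * phi).ravel()
    return pts, weights


class TestDensity:
    def test_independence_density_is_one(self):
        assert cr.copula_density("gaussian", 0.0, None, (0.5, 0.5)) == pytest.approx(1.0)

    def test_gaussian_density_at_medians_closed_form(self):
        # both normal scores vanish at the medians, leaving 1/sqrt(1 - rho^2)
        got = cr.copula_density("gaussian", RHO, None, (0.5, 0.5))
        assert got == pytest.approx(1.0 / math.sqrt(1 - RHO**2), rel=1e-12)

    @pytest.mark.parametrize(
        "family,rho,df",
        [
            ("gaussian", -0.8, None),
            ("gaussian", 0.0, None),
            ("gaussian", RHO, None),
            ("gaussian", 0.8, None),
            ("student_t", -0.8, 3.0),
            ("student_t", RHO, 3.0),
            ("student_t", 0.8, 3.0),
            ("student_t", RHO, 10.0),
        ],
    )
    def test_density_integrates_to_one(self, family, rho, df):
        pts, w = normal_score_quadrature()
        total = float(np.sum(w * cr.copula_density(family, rho, df, pts)))
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_t_density_matches_cdf_mixed_difference(self):
        """Density agrees with the central second mixed difference of the CDF."""
        h = 1e-3
        for u1, u2 in [(0.3, 0.6), (0.5, 0.5), (0.7, 0.2)]:
            c = cr.copula_density("student_t", 0.5, 3.0, (u1, u2))
            pts = np.array(
                [
                    [u1 + h, u2 + h],
                    [u1 + h, u2 - h],
                    [u1 - h, u2 + h],
                    [u1 - h, u2 - h],
                ]
            )
            v = cr.copula_cdf("student_t", 0.5, 3.0, pts)
            fd = (v[0] - v[1] - v[2] + v[3]) / (4 * h * h)
            assert c == pytest.approx(fd, abs=1e-3)

    def test_t_converges_to_gaussian_at_large_df(self):
        g = np.linspace(0.05, 0.95, 10)
        uu1, uu2 = np.meshgrid(g, g, indexing="ij")
        pts = np.column_stack([uu1.ravel(), uu2.ravel()])
        t_dens = cr.copula_density("student_t", RHO, 500.0, pts)
        g_dens = cr.copula_density("gaussian", RHO, None, pts)
        assert np.max(np.abs(t_dens - g_dens)) < 1e-2

    def test_exchangeable(self):
        pts = np.array([[0.2, 0.7], [0.7, 0.2]])
        for family, df in [("gaussian", None), ("student_t", 4.0)]:
            d = cr.copula_density(family, RHO, df, pts)
            assert d[0] == pytest.approx(d[1], rel=1e-12)
            c = cr.copula_cdf(family, RHO, df, pts)
            # CDF symmetry only up to conditional-quadrature accuracy
            assert c[0] == pytest.approx(c[1], abs=5e-6)

    def test_boundary_raises(self):
        with pytest.raises(DomainError):
            cr.copula_density("gaussian", RHO, None, (0.0, 0.5))
        with pytest.raises(DomainError):
            cr.copula_density("gaussian", 1.0, None, (0.5, 0.5))
        with pytest.raises(DomainError):
            cr.copula_density("student_t", RHO, 2.0, (0.5, 0.5))


class TestCdf:
    def test_independence_factorizes(self):
        assert cr.copula_cdf("gaussian", 0.0, None, (0.3, 0.7)) == pytest.approx(0.21)

    def test_uniform_margins(self):
        for u in (0.1, 0.42, 0.9):
            assert cr.copula_cdf("gaussian", RHO, None, (u, 1.0)) == pytest.approx(u, abs=1e-9)
            assert cr.copula_cdf("student_t", RHO, 3.0, (1.0, u)) == pytest.approx(u, abs=1e-9)
            assert cr.copula_cdf("student_t", RHO, 3.0, (u, 0.0)) == 0.0

    def test_median_orthant_closed_form(self):
        """Elliptical orthant probability: C(1/2, 1/2) = 1/4 + arcsin(rho)/2pi."""
        for family, df in [("gaussian", None), ("student_t", 3.0)]:
            for rho in (-0.5, RHO, 0.8):
                got = cr.copula_cdf(family, rho, df, (0.5, 0.5))
                assert got == pytest.approx(0.25 + math.asin(rho) / (2 * math.pi), abs=1e-4)

    def test_gaussian_matches_scipy_mvn(self):
        rho = 0.6
        mvn = stats.multivariate_normal(cov=[[1.0, rho], [rho, 1.0]])
        rng = np.random.default_rng(1)
        pts = rng.random((20, 2)) * 0.9 + 0.05
        mine = cr.copula_cdf("gaussian", rho, None, pts)
        ref = np.array([mvn.cdf(special.ndtri(p)) for p in pts])
        assert np.max(np.abs(mine - ref)) < 1e-6

    def test_invalid_params_raise(self):
        with pytest.raises(DomainError):
            cr.copula_cdf("gaussian", 1.2, None, (0.5, 0.5))
        with pytest.raises(DomainError):
            cr.copula_cdf("student_t", 0.3, 1.5, (0.5, 0.5))


@given(
    u1=st.floats(min_value=0.01, max_value=0.99),
    u2=st.floats(min_value=0.01, max_value=0.99),
    rho=st.floats(min_value=-0.95, max_value=0.95),
    t_df=st.sampled_from([None, 2.5, 5.0, 30.0]),
)
def test_cdf_frechet_bounds_and_monotone(u1, u2, rho, t_df):
    family = "gaussian" if t_df is None else "student_t"
    c = cr.copula_cdf(family, rho, t_df, (u1, u2))
    assert max(u1 + u2 - 1.0, 0.0) - 1e-7 <= c <= min(u1, u2) + 1e-7
    # 2-increasing on the rectangle [u1, u1+d] x [u2, u2+d]
    d = 0.005
    a, b = min(u1, 0.99), min(u2, 0.99)
    pts = np.array([[a + d, b + d], [a + d, b], [a, b + d], [a, b]])
    v = cr.copula_cdf(family, rho, t_df, pts)
    assert v[0] - v[1] - v[2] + v[3] >= -1e-8


class TestSampler:
    def test_independence_tau_near_zero(self):
        u = cr.sample_copula("gaussian", 0.0, None, 100_000, 7)
        tau = stats.kendalltau(u[:, 0], u[:, 1]).statistic
        assert abs(tau) < 0.01

    def test_t_tau_matches_arcsine_law(self):
        u = cr.sample_copula("student_t", RHO, 3.0, 100_000, 8)
        tau = stats.kendalltau(u[:, 0], u[:, 1]).statistic
        assert tau == pytest.approx(2.0 / math.pi * math.asin(RHO), abs=0.01)

    def test_gaussian_tau_matches_arcsine_law(self):
        u = cr.sample_copula("gaussian", 0.7, None, 100_000, 9)
        tau = stats.kendalltau(u[:, 0], u[:, 1]).statistic
        assert tau == pytest.approx(2.0 / math.pi * math.asin(0.7), abs=0.01)

    def test_margins_uniform_under_strong_dependence(self):
        u = cr.sample_copula("gaussian", 0.9, None, 10_000, 10)
        crit_1pct = 1.63 / math.sqrt(10_000)
        for j in (0, 1):
            ks = stats.kstest(u[:, j], "uniform").statistic
            assert ks < crit_1pct

    def test_reproducible(self):
        a = cr.sample_copula("student_t", RHO, 3.0, 100, 5)
        b = cr.sample_copula("student_t", RHO, 3.0, 100, 5)
        np.testing.assert_array_equal(a, b)


class TestPseudoObservations:
    def test_rank_over_n_plus_one(self):
        out = cr.pseudo_observations([(1, 10), (2, 20), (3, 30)])
        np.testing.assert_allclose(out, [[0.25, 0.25], [0.5, 0.5], [0.75, 0.75]])

    def test_monotone_invariance(self):
        rng = np.random.default_rng(0)
        pairs = rng.random((50, 2)) + 0.5
        logged = np.column_stack([np.log(pairs[:, 0]), pairs[:, 1]])
        np.testing.assert_array_equal(
            cr.pseudo_observations(pairs), cr.pseudo_observations(logged)
        )

    def test_average_ranks_on_ties(self):
        out = cr.pseudo_observations([(5.0, 1.0), (5.0, 2.0), (9.0, 3.0)])
        assert out[0, 0] == pytest.approx(1.5 / 4) and out[1, 0] == pytest.approx(1.5 / 4)

    def test_strictly_interior(self):
        rng = np.random.default_rng(4)
        out = cr.pseudo_observations(rng.random((200, 2)))
        assert np.all(out > 0) and np.all(out < 1)


class TestFitAndSelect:
    def test_gaussian_rho_recovery(self):
        u = cr.sample_copula("gaussian", 0.5, None, 5000, 11)
        fit = cr.fit_copula_pseudo_mle("gaussian", cr.pseudo_observations(u))
        assert fit.rho == pytest.approx(0.5, abs=0.03)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2)

    def test_t_df_recovered_on_grid(self):
        u = cr.sample_copula("student_t", RHO, 3.0, 5000, 12)
        fit = cr.fit_copula_pseudo_mle(
            "student_t", cr.pseudo_observations(u), df_grid=DEFAULT_DF_GRID
        )
        assert fit.df_gridpoint == 3.0
        assert fit.rho == pytest.approx(RHO, abs=0.05)
        assert 2.0 < fit.df < 5.0

    def test_rho_recovery_rate_across_sample_sizes(self):
        """Rank-based refits recover rho within 3/sqrt(n) consistently."""
        hits = trials = 0
        for n in (500, 2000):
            for rep in range(10):
                u = cr.sample_copula("gaussian", 0.4, None, n, 100 * n + rep)
                fit = cr.fit_copula_pseudo_mle("gaussian", cr.pseudo_observations(u))
                trials += 1
                hits += abs(fit.rho - 0.4) <= 3.0 / math.sqrt(n)
        assert hits >= trials - 1

    def test_comonotone_boundary_flagged(self):
        x = np.linspace(0.1, 0.9, 100)
        fit = cr.fit_copula_pseudo_mle("gaussian", np.column_stack([x, x]))
        assert fit.boundary and fit.rho > 0.999

    def test_select_prefers_gaussian_on_gaussian_data(self):
        wins = 0
        for rep in range(10):
            u = cr.sample_copula("gaussian", 0.4, None, 5000, 300 + rep)
            sel = cr.select_copula_family(
                cr.pseudo_observations(u), df_grid=(2.1, 3.0, 6.0, 10.0, 30.0)
            )
            wins += sel.family == "gaussian"
        assert wins >= 8

    def test_select_independence_rho_near_zero(self):
        u = cr.sample_copula("gaussian", 0.0, None, 2000, 13)
        sel = cr.select_copula_family(cr.pseudo_observations(u),
                                      df_grid=(2.1, 3.0, 10.0))
        assert abs(sel.rho) < 3.0 / math.sqrt(2000)


class TestGof:
    def test_statistic_zero_against_empirical_model(self):
        u = cr.sample_copula("gaussian", 0.4, None, 200, 14)
        pobs = cr.pseudo_observations(u)
        assert cvm_statistic(pobs, lambda pts: empirical_copula(pobs, pts)) == 0.0

    def test_power_against_tail_dependent_alternative(self):
        """Fitting a Gaussian copula to strongly tail-dependent t data is
        rejected in the majority of replicates."""
        rejections = 0
        for rep in range(5):
            u = cr.sample_copula("student_t", 0.8, 2.5, 1000, 600 + rep)
            pobs = cr.pseudo_observations(u)
            fit = cr.fit_copula_pseudo_mle("gaussian", pobs)
            _, p = cr.gof_copula_cvm(fit, pobs, n_boot=100, seed=rep)
            rejections += p < 0.05
        assert rejections >= 3

    def test_small_n_boot_warns(self):
        u = cr.sample_copula("gaussian", 0.3, None, 100, 15)
        pobs = cr.pseudo_observations(u)
        fit = cr.fit_copula_pseudo_mle("gaussian", pobs)
        with pytest.warns(UserWarning, match="unstable"):
            cr.gof_copula_cvm(fit, pobs, n_boot=20, seed=0)
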