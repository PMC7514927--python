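"""Core distribution layer: closed forms, stability, invariants."""

import math

import mpmath as mp
import numpy as np
import pytest
from scipy import integrate, special, stats

from wgamma import (
    WgParams,
    log_gamma_survival,
    wg_cdf,
    wg_hazard,
    wg_logpdf,
    wg_pdf,
    wg_quantile,
    wg_rvs,
    wg_sf,
)

EXP = WgParams(1.0, 1.0, 1.0, 1.0)  # reduces to the standard exponential


class TestParams:
    @pytest.mark.parametrize("bad", [
        dict(c=0.0), dict(beta=-1.0), dict(k=float("nan")), dict(s=float("inf")),
    ])
    def test_rejects_nonpositive_or_nonfinite(self, bad):
        kwargs = dict(c=1.0, beta=1.0, k=1.0, s=1.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            WgParams(**kwargs)

    def test_array_round_trip(self):
        p = WgParams(1.5, 0.5, 0.5, 0.4)
        assert WgParams.from_array(p.as_array()) == p


class TestLogGammaSurvival:
    @pytest.mark.parametrize("x,k,s,expected", [
        (0.0, 2.0, 1.0, 0.0),                      # survival at the origin is 1
        (1.0, 1.0, 1.0, -1.0),                     # exponential tail e^-x
        (1.0, 2.0, 1.0, math.log(2.0 / math.e)),   # (1+x)e^-x at x=1
    ])
    def test_closed_forms(self, x, k, s, expected):
        assert log_gamma_survival(x, k, s) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("k,z", [(0.0085, 1.45), (41.0, 878.0), (0.5, 700.0),
                                     (3.0, 2000.0), (0.2, 5.0)])
    def test_matches_arbitrary_precision_in_both_tails(self, k, z):
        exact = float(mp.log(mp.gammainc(k, z, mp.inf, regularized=True)))
        assert log_gamma_survival(z, k, 1.0) == pytest.approx(exact, rel=1e-12)

    def test_rejects_bad_domains(self):
        with pytest.raises(ValueError):
            log_gamma_survival(-1.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            log_gamma_survival(float("nan"), 2.0, 1.0)
        with pytest.raises(ValueError):
            log_gamma_survival(1.0, -2.0, 1.0)


class TestDensity:
    def test_exponential_special_case(self):
        assert wg_logpdf(0.5, EXP) == pytest.approx(-0.5, abs=1e-13)

    def test_exponential_gamma_special_case(self):
        # c=1 reduces to the exponential-gamma law; beta=2, k=s=1
        p = WgParams(1.0, 2.0, 1.0, 1.0)
        assert wg_logpdf(1.0, p) == pytest.approx(math.log(0.5) - 0.5, abs=1e-13)

    def test_matches_arbitrary_precision_at_ridge_parameters(self):
        # parameter regime of real-data optima: tiny gamma shape
        p = WgParams(6.0638, 6.4448, 0.0085, 1.891)
        x = mp.mpf("2.75")
        c, b, k, s = (mp.mpf(repr(v)) for v in (p.c, p.beta, p.k, p.s))
        w = mp.gammainc(k, x / s, mp.inf, regularized=True)
        nlw = -mp.log(w)
        exact = (mp.log(c) - c * mp.log(b) + (k - 1) * mp.log(x) - x / s
                 - k * mp.log(s) - mp.loggamma(k) - mp.log(w)
                 + (c - 1) * mp.log(nlw) - (nlw / b) ** c)
        assert wg_logpdf(2.75, p) == pytest.approx(float(exact), rel=1e-12)

    def test_negative_x_gives_zero_density(self):
        assert wg_logpdf(-1.0, EXP) == -np.inf
        assert wg_pdf(-1.0, EXP) == 0.0

    @pytest.mark.parametrize("params,expected", [
        (WgParams(1, 1, 0.5, 1), np.inf),        # ck < 1: diverges at 0
        (WgParams(1, 2, 1, 1), 0.5),             # ck = 1: finite limit 1/(beta*s)
        (WgParams(2, 1, 1.5, 1), 0.0),           # ck > 1: vanishes at 0
    ])
    def test_density_limit_at_origin(self, params, expected):
        assert wg_pdf(0.0, params) == pytest.approx(expected)

    def test_normalization_on_random_parameter_grid(self, random_param_grid):
        """Integral of the density over (0, inf) is 1 for 50 random laws."""
        for p in random_param_grid:
            # substitute x = y^a near 0 to smooth the x^(ck-1) singularity
            a = max(1.0, 2.0 / (p.c * p.k))
            x1 = float(wg_quantile(0.1, p))
            val0, _ = integrate.quad(
                lambda y: wg_pdf(y**a, p) * a * y ** (a - 1.0),
                0.0, x1 ** (1.0 / a), epsabs=1e-11, epsrel=1e-11, limit=200)
            total = val0
            lo = x1
            for q in (0.5, 0.9, 0.999):
                hi = float(wg_quantile(q, p))
                val, _ = integrate.quad(lambda x: wg_pdf(x, p), lo, hi,
                                        epsabs=1e-11, epsrel=1e-11, limit=200)
                total += val
                lo = hi
            val, _ = integrate.quad(lambda x: wg_pdf(x, p), lo, np.inf,
                                    epsabs=1e-11, epsrel=1e-11, limit=200)
            total += val
            assert total == pytest.approx(1.0, abs=1e-8), f"params {p}"


class TestCdfSfHazard:
    def test_exponential_median(self):
        assert wg_cdf(math.log(2.0), EXP) == pytest.approx(0.5, abs=1e-13)

    def test_gamma_special_case_cdf_and_sf(self):
        p = WgParams(1.0, 1.0, 2.0, 1.0)
        assert wg_cdf(1.0, p) == pytest.approx(1.0 - 2.0 / math.e, abs=1e-13)
        assert wg_sf(1.0, p) == pytest.approx(2.0 / math.e, abs=1e-13)

    def test_cdf_zero_at_origin_and_negative(self, random_param_grid):
        for p in random_param_grid[:10]:
            assert wg_cdf(0.0, p) == 0.0
            assert wg_cdf(-0.5, p) == 0.0

    def test_cdf_monotone_in_unit_interval(self, random_param_grid):
        grid = np.linspace(0.0, 20.0, 200)
        for p in random_param_grid[:15]:
            F = wg_cdf(grid, p)
            assert np.all(np.diff(F) >= -1e-14)
            assert np.all((F >= 0) & (F <= 1))

    def test_sf_plus_cdf_is_one(self, random_param_grid):
        grid = np.linspace(0.01, 10.0, 50)
        for p in random_param_grid[:15]:
            assert np.max(np.abs(wg_sf(grid, p) + wg_cdf(grid, p) - 1.0)) < 1e-12

    def test_hazard_times_sf_is_pdf(self, random_param_grid):
        grid = np.linspace(0.05, 5.0, 40)
        for p in random_param_grid[:15]:
            h = wg_hazard(grid, p)
            f = wg_pdf(grid, p)
            sf = wg_sf(grid, p)
            ok = f > 1e-290
            assert np.allclose(h[ok] * sf[ok], f[ok], rtol=1e-10)

    def test_exponential_hazard_is_constant_one(self):
        grid = np.linspace(0.1, 8.0, 30)
        assert np.allclose(wg_hazard(grid, EXP), 1.0, atol=1e-12)

    def test_decreasing_hazard_shape_exists(self):
        p = WgParams(0.5, 1.0, 0.5, 0.4)
        grid = np.linspace(0.1, 5.0, 60)
        h = wg_hazard(grid, p)
        assert np.all(np.diff(h) < 0)

    def test_gamma_reduction_sup_norm(self):
        # c = beta = 1 reduces to the gamma law
        for k, s in [(0.5, 1.0), (2.0, 0.7), (1.3, 2.5)]:
            p = WgParams(1.0, 1.0, k, s)
            grid = np.linspace(0.0, 12.0, 150)
            assert np.max(np.abs(wg_cdf(grid, p) - stats.gamma.cdf(grid, k, scale=s))) < 1e-10

    def test_exponential_gamma_logpdf_reduction(self):
        # c = 1: f = x^(k-1) e^(-x/s) / (beta s^k Gamma(k)) * w^(1/beta - 1)
        b, k, s = 2.5, 1.7, 0.8
        p = WgParams(1.0, b, k, s)
        for x in (0.3, 1.0, 4.2):
            w = special.gammaincc(k, x / s)
            direct = ((k - 1) * np.log(x) - x / s - np.log(b) - k * np.log(s)
                      - special.gammaln(k) + (1.0 / b - 1.0) * np.log(w))
            assert wg_logpdf(x, p) == pytest.approx(direct, abs=1e-12)


class TestQuantile:
    def test_exponential_median(self):
        assert wg_quantile(0.5, EXP) == pytest.approx(math.log(2.0), abs=1e-12)

    def test_inverse_of_gamma_case(self):
        p = WgParams(1.0, 1.0, 2.0, 1.0)
        assert wg_quantile(1.0 - 2.0 / math.e, p) == pytest.approx(1.0, rel=1e-10)

    def test_round_trip_through_cdf(self, random_param_grid):
        probs = np.array([1e-6, 1e-3, 0.1, 0.5, 0.9, 0.999, 1 - 1e-6])
        for p in random_param_grid[:20]:
            x = wg_quantile(probs, p)
            assert np.max(np.abs(wg_cdf(x, p) - probs)) < 1e-10

    def test_bisection_oracle_at_awkward_parameters(self):
        p = WgParams(1.5, 0.5, 0.5, 0.4)
        x = wg_quantile(0.95, p)
        lo, hi = 0.0, 100.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if wg_cdf(mid, p) < 0.95 else (lo, mid)
        assert x == pytest.approx(0.5 * (lo + hi), rel=1e-9)

    def test_edge_probabilities(self):
        assert wg_quantile(0.0, EXP) == 0.0
        assert wg_quantile(1.0, EXP) == np.inf
        with pytest.raises(ValueError):
            wg_quantile(1.5, EXP)
        with pytest.raises(ValueError):
            wg_quantile(-0.1, EXP)


class TestSampling:
    def test_reproducible_given_seed(self):
        a = wg_rvs(5, EXP, seed=42)
        b = wg_rvs(5, EXP, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_exponential_sample_mean(self):
        x = wg_rvs(100_000, EXP, seed=7)
        assert abs(x.mean() - 1.0) < 3.0 / math.sqrt(100_000)

    def test_kolmogorov_smirnov_against_cdf(self):
        p = WgParams(1.5, 0.5, 0.5, 0.4)
        x = wg_rvs(10_000, p, seed=11)
        stat = stats.kstest(x, lambda v: wg_cdf(v, p)).statistic
        assert stat < 1.63 / math.sqrt(10_000)  # 1% critical value

    def test_rejects_bad_n(self):
        with pytest.raises(ValueError):
            wg_rvs(0, EXP, seed=1)
        with pytest.raises(ValueError):
            wg_rvs(-3, EXP, seed=1)
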