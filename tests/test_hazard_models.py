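"""Closed-form hazards against quadrature oracles and algebraic identities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from mstages import (
    CovariateParams,
    CovariateProfile,
    FrailtyWeibullParams,
    armitage_doll_hazard,
    covariate_multiplier,
    frailty_marginal_hazard,
    mode_age,
    model2_rate,
    weibull_baseline_hazard,
)
from mstages.hazard_models import N_LIMIT

AGES = np.array([1.0, 5.0, 20.0, 40.0, 60.0, 80.0, 100.0])


def mixture_hazard_oracle(age, params):
    """Marginal hazard by numerical integration over the frailty law.

    hazard(x) = mu0(x) * E[Z S0(x)^Z] / E[S0(x)^Z] with mean-1 frailty Z
    of variance sigma^2: gamma for n = 1, inverse Gaussian for n = 2.
    """
    m, c, sigma, n = params.m, params.c, params.sigma, params.n
    H = (age / c) ** m
    mu0 = (m / c) * (age / c) ** (m - 1.0)
    if n == 1:
        dist = stats.gamma(a=1.0 / sigma**2, scale=sigma**2)
    elif n == 2:
        dist = stats.invgauss(mu=sigma**2, scale=1.0 / sigma**2)
    else:
        raise ValueError("oracle defined for n in {1, 2}")

    # integrate in CDF space, E[g(Z)] = int_0^1 g(ppf(p)) dp: immune to
    # the near-singular density of gamma frailty with shape < 1 and to
    # mass concentrating far from the prior bulk when H is large
    def num(p):
        z = dist.ppf(p)
        return z * np.exp(-z * H)

    def den(p):
        return np.exp(-dist.ppf(p) * H)

    knots = [0.0, 1e-9, 1e-6, 1e-3, 0.05, 0.5, 0.95, 1 - 1e-3, 1 - 1e-6, 1.0]
    a_int = sum(
        integrate.quad(num, lo, hi, limit=400)[0]
        for lo, hi in zip(knots, knots[1:])
    )
    b_int = sum(
        integrate.quad(den, lo, hi, limit=400)[0]
        for lo, hi in zip(knots, knots[1:])
    )
    return mu0 * a_int / b_int


class TestBaselineAndReductions:
    @pytest.mark.parametrize(
        "age,m,c,expected",
        [(50.0, 2.0, 50.0, 0.04), (25.0, 2.0, 50.0, 0.02), (33.0, 1.0, 80.0, 0.0125)],
    )
    def test_weibull_baseline_values(self, age, m, c, expected):
        p = FrailtyWeibullParams(m=m, c=c, sigma=0.0, n=1.0)
        assert weibull_baseline_hazard(age, p) == pytest.approx(expected)

    def test_sigma_zero_reduces_to_weibull(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = FrailtyWeibullParams(
                m=rng.uniform(1, 15), c=rng.uniform(30, 150), sigma=0.0,
                n=rng.uniform(0, 3),
            )
            np.testing.assert_allclose(
                frailty_marginal_hazard(AGES, p),
                weibull_baseline_hazard(AGES, p),
                rtol=1e-12,
            )

    def test_n_zero_limit_is_continuous(self):
        p0 = FrailtyWeibullParams(m=6.0, c=90.0, sigma=3.0, n=0.0)
        p_eps = FrailtyWeibullParams(m=6.0, c=90.0, sigma=3.0, n=1e-8)
        np.testing.assert_allclose(
            frailty_marginal_hazard(AGES, p0),
            frailty_marginal_hazard(AGES, p_eps),
            rtol=1e-6,
        )
        assert 1e-8 < N_LIMIT  # the limit branch really is exercised

    def test_known_frailty_values(self):
        p = FrailtyWeibullParams(m=2.0, c=50.0, sigma=1.0, n=1.0)
        assert frailty_marginal_hazard(50.0, p) == pytest.approx(0.02)
        p0 = FrailtyWeibullParams(m=2.0, c=50.0, sigma=1.0, n=0.0)
        assert frailty_marginal_hazard(50.0, p0) == pytest.approx(
            0.04 * np.exp(-1.0), rel=1e-6
        )

    def test_invalid_inputs_raise(self):
        p = FrailtyWeibullParams(m=2.0, c=50.0, sigma=1.0, n=1.0)
        with pytest.raises(ValueError):
            frailty_marginal_hazard(-1.0, p)
        with pytest.raises(ValueError):
            FrailtyWeibullParams(m=0.5, c=50.0, sigma=1.0, n=1.0)
        with pytest.raises(ValueError):
            FrailtyWeibullParams(m=2.0, c=-1.0, sigma=1.0, n=1.0)
        with pytest.raises(ValueError):
            CovariateParams(f_year=-120.0)


class TestFrailtyMixtureOracle:
    @pytest.mark.parametrize("n", [1.0, 2.0])
    def test_matches_numerical_marginalization(self, n):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = FrailtyWeibullParams(
                m=rng.uniform(2, 12),
                c=rng.uniform(50, 150),
                sigma=rng.uniform(0.3, 5.0),
                n=n,
            )
            for age in (20.0, 45.0, 70.0, 95.0):
                oracle = mixture_hazard_oracle(age, p)
                assert frailty_marginal_hazard(age, p) == pytest.approx(
                    oracle, rel=1e-6
                )

    def test_specific_gamma_case(self):
        # m=5, c=80, sigma=2, n=1 against the quadrature oracle
        p = FrailtyWeibullParams(m=5.0, c=80.0, sigma=2.0, n=1.0)
        assert frailty_marginal_hazard(40.0, p) == pytest.approx(
            mixture_hazard_oracle(40.0, p), rel=1e-6
        )


class TestModeAge:
    def test_closed_form_matches_numerical_argmax(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 15:
            p = FrailtyWeibullParams(
                m=rng.uniform(1.5, 14),
                c=rng.uniform(40, 140),
                sigma=rng.uniform(0.5, 20),
                n=rng.uniform(0.0, 2.5),
            )
            mode = mode_age(p)
            if mode is None:
                continue
            grid = np.linspace(max(mode / 50, 1e-3), mode * 5, 200001)
            numeric = grid[np.argmax(frailty_marginal_hazard(grid, p))]
            assert mode == pytest.approx(numeric, rel=1e-4)
            checked += 1

    def test_known_modes(self):
        assert mode_age(
            FrailtyWeibullParams(m=2.0, c=50.0, sigma=1.0, n=1.0)
        ) == pytest.approx(50.0)
        assert mode_age(
            FrailtyWeibullParams(m=2.0, c=50.0, sigma=1.0, n=0.0)
        ) == pytest.approx(50.0 / np.sqrt(2.0), rel=1e-6)

    def test_monotone_cases_return_none(self):
        assert mode_age(FrailtyWeibullParams(m=2.0, c=50.0, sigma=0.0, n=1.0)) is None
        assert mode_age(FrailtyWeibullParams(m=1.0, c=50.0, sigma=2.0, n=1.0)) is None
        # m - n(m-1) <= 0: late-age hazard keeps rising, no interior mode
        assert mode_age(FrailtyWeibullParams(m=10.0, c=50.0, sigma=2.0, n=3.0)) is None

    def test_mode_is_strict_local_maximum_and_decline_beyond(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 10:
            p = FrailtyWeibullParams(
                m=rng.uniform(2, 12),
                c=rng.uniform(40, 120),
                sigma=rng.uniform(1, 15),
                n=rng.uniform(0, 2),
            )
            mode = mode_age(p)
            if mode is None:
                continue
            peak = frailty_marginal_hazard(mode, p)
            assert frailty_marginal_hazard(mode - 1e-3, p) < peak
            assert frailty_marginal_hazard(mode + 1e-3, p) < peak
            grid = np.linspace(mode * 1.001, mode * 5, 400)
            h = frailty_marginal_hazard(grid, p)
            assert np.all(np.diff(h) < 0)
            checked += 1


class TestCovariatesAndModel2:
    def test_reference_profile_multiplier_is_one(self):
        cov = CovariateParams(r_sex=0.25, r_race=1.33, f_year=-6.86, ref_year=1988)
        prof = CovariateProfile(female=0, african_american=0, year=1988)
        assert covariate_multiplier(prof, cov) == 1.0

    def test_relative_risk_and_trend_factors(self):
        cov = CovariateParams(r_sex=0.25, r_race=1.0, f_year=0.0, ref_year=1988)
        prof = CovariateProfile(female=1, african_american=0, year=1988)
        assert covariate_multiplier(prof, cov) == pytest.approx(0.25)
        # a +33.20%/decade trend (published lung AC value) over one decade
        cov = CovariateParams(r_sex=1.0, r_race=1.0, f_year=33.20, ref_year=1988)
        prof = CovariateProfile(year=1998)
        assert covariate_multiplier(prof, cov) == pytest.approx(1.332)

    def test_model2_reduces_to_marginal_hazard(self):
        p = FrailtyWeibullParams(m=8.0, c=90.0, sigma=5.0, n=1.0)
        cov = CovariateParams(r_sex=0.5, r_race=2.0, f_year=10.0, ref_year=1988)
        ref = CovariateProfile(year=1988)
        assert model2_rate(60.0, ref, p, cov) == frailty_marginal_hazard(60.0, p)
        both = CovariateProfile(female=1, african_american=1, year=1988)
        assert model2_rate(60.0, both, p, cov) == pytest.approx(
            frailty_marginal_hazard(60.0, p)
        )

    def test_rate_ratio_ten_years_apart(self):
        p = FrailtyWeibullParams(m=8.0, c=90.0, sigma=5.0, n=1.0)
        cov = CovariateParams(f_year=25.0, ref_year=1988)
        prof_a = CovariateProfile(female=1, year=1990)
        prof_b = CovariateProfile(female=1, year=2000)
        ratio = model2_rate(60.0, prof_b, p, cov) / model2_rate(60.0, prof_a, p, cov)
        assert ratio == pytest.approx(1.25)

    def test_invalid_indicator_rejected(self):
        with pytest.raises(ValueError):
            CovariateProfile(female=2)


class TestArmitageDoll:
    def test_power_law_value_and_slope(self):
        assert armitage_doll_hazard(10.0, a=1e-10, m=5.0) == pytest.approx(1e-6)
        ages = np.linspace(20, 80, 50)
        h = armitage_doll_hazard(ages, a=1e-9, m=6.0)
        slope = np.polyfit(np.log(ages), np.log(h), 1)[0]
        assert slope == pytest.approx(5.0, abs=1e-10)

    def test_equals_weibull_baseline_under_reparameterization(self):
        m, c = 7.0, 85.0
        p = FrailtyWeibullParams(m=m, c=c, sigma=0.0, n=1.0)
        a = m / c**m
        np.testing.assert_allclose(
            armitage_doll_hazard(AGES, a=a, m=m),
            weibull_baseline_hazard(AGES, p),
            rtol=1e-12,
        )


@given(
    m=st.floats(1.0, 15.0),
    c=st.floats(20.0, 200.0),
    sigma=st.floats(0.0, 50.0),
    n=st.floats(0.0, 3.0),
    age=st.floats(0.5, 110.0),
)
def test_hazard_is_nonnegative_and_finite(m, c, sigma, n, age):
    p = FrailtyWeibullParams(m=m, c=c, sigma=sigma, n=n)
    h = frailty_marginal_hazard(age, p)
    assert np.isfinite(h) and h >= 0.0
    assert h <= weibull_baseline_hazard(age, p) * (1 + 1e-12)
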