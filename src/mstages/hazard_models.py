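"""Closed-form hazard / incidence-rate models.

The central object is the marginal population hazard of a multistage
(Weibull-baseline) carcinogenesis process in a heterogeneous population.
Each individual carries an unobserved multiplicative frailty ``z`` with
mean 1 and variance ``sigma**2`` drawn from a power-variance-family (PVF)
distribution indexed by a shape parameter ``n`` (``n = 1`` gamma,
``n = 2`` inverse Gaussian, ``n -> 0`` an exponential-attenuation limit).
Averaging the individual hazard ``z * mu0(x)`` over the survivors at age
``x`` gives the population incidence rate

    lambda(x) = (m/c) * (x/c)**(m-1) * (1 + n * sigma**2 * (x/c)**m)**(-1/n)

where ``m`` is the number of rate-limiting stages (m-stages) an individual
passes on the way to a diagnosed cancer and ``c`` (years) is the age-scale
parameter of the Weibull baseline.  Selection of the least frail explains
the downturn of registry incidence rates at advanced ages; with
``sigma = 0`` the model collapses to the homogeneous Weibull form, the
continuous analogue of the classic Armitage-Doll multistage law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrailtyWeibullParams",
    "CovariateParams",
    "CovariateProfile",
    "weibull_baseline_hazard",
    "frailty_marginal_hazard",
    "mode_age",
    "covariate_multiplier",
    "model2_rate",
    "armitage_doll_hazard",
]

#: below this value of ``n`` the exponential (n -> 0) limit form is used
N_LIMIT = 1e-6


@dataclass(frozen=True)
class FrailtyWeibullParams:
    """Baseline model parameters (m, c, sigma, n).

    m : number of m-stages (>= 1, dimensionless)
    c : Weibull age scale, years (> 0)
    sigma : standard deviation of the frailty distribution (>= 0)
    n : PVF frailty shape index (>= 0); 1 = gamma, 2 = inverse Gaussian,
        0 = exponential-attenuation limit
    """

    m: float
    c: float
    sigma: float
    n: float

    def __post_init__(self) -> None:
        if not (self.m >= 1.0):
            raise ValueError(f"m must be >= 1, got {self.m}")
        if not (self.c > 0.0):
            raise ValueError(f"c must be > 0, got {self.c}")
        if not (self.sigma >= 0.0):
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not (self.n >= 0.0):
            raise ValueError(f"n must be >= 0, got {self.n}")

    def to_dict(self) -> dict:
        return {"m": self.m, "c": self.c, "sigma": self.sigma, "n": self.n}


@dataclass(frozen=True)
class CovariateParams:
    """Relative-risk and period-trend parameters of the generalized model.

    r_sex : relative risk for females (> 0)
    r_race : relative risk for African-Americans (> 0)
    f_year : percent change in incidence per 10-year period
    ref_year : calendar year at which the period trend factor equals 1
    """

    r_sex: float = 1.0
    r_race: float = 1.0
    f_year: float = 0.0
    ref_year: int = 1988

    def __post_init__(self) -> None:
        if not (self.r_sex > 0.0):
            raise ValueError(f"r_sex must be > 0, got {self.r_sex}")
        if not (self.r_race > 0.0):
            raise ValueError(f"r_race must be > 0, got {self.r_race}")
        if not (1.0 + self.f_year / 100.0 > 0.0):
            raise ValueError(f"f_year must exceed -100, got {self.f_year}")

    def to_dict(self) -> dict:
        return {
            "r_sex": self.r_sex,
            "r_race": self.r_race,
            "f_year": self.f_year,
            "ref_year": self.ref_year,
        }


@dataclass(frozen=True)
class CovariateProfile:
    """Indicator profile of one population stratum.

    female : 1 for female, 0 for male
    african_american : 1 for African-American, 0 for Caucasian
    year : calendar year of observation
    """

    female: int = 0
    african_american: int = 0
    year: int = 1988

    def __post_init__(self) -> None:
        if self.female not in (0, 1):
            raise ValueError(f"female indicator must be 0 or 1, got {self.female}")
        if self.african_american not in (0, 1):
            raise ValueError(
                f"african_american indicator must be 0 or 1, got {self.african_american}"
            )


def _check_age(age):
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0.0):
        raise ValueError("age must be positive")
    return age


def _maybe_scalar(x, arr):
    return float(arr) if np.isscalar(x) or np.ndim(x) == 0 else arr


def weibull_baseline_hazard(age, params: FrailtyWeibullParams):
    """Homogeneous Weibull hazard (m/c) * (age/c)**(m-1).

    This is the sigma = 0 reduction of the frailty model and, after the
    reparameterization a = m / c**m, the Armitage-Doll power law.
    """
    a = _check_age(age)
    out = (params.m / params.c) * (a / params.c) ** (params.m - 1.0)
    return _maybe_scalar(age, out)


def frailty_marginal_hazard(age, params: FrailtyWeibullParams):
    """Population incidence rate under PVF frailty with Weibull baseline.

    Evaluates ``(m/c)(x/c)**(m-1) * (1 + n sigma^2 (x/c)**m)**(-1/n)``;
    for ``n`` below ``N_LIMIT`` the continuous limit
    ``(m/c)(x/c)**(m-1) * exp(-sigma^2 (x/c)**m)`` is used.
    """
    a = _check_age(age)
    m, c, sigma, n = params.m, params.c, params.sigma, params.n
    u = (a / c) ** m
    base = (m / c) * (a / c) ** (m - 1.0)
    if n < N_LIMIT:
        out = base * np.exp(-(sigma**2) * u)
    else:
        # log1p keeps the bracket accurate when n*sigma^2*u is small
        out = base * np.exp(-np.log1p(n * sigma**2 * u) / n)
    return _maybe_scalar(age, out)


def mode_age(params: FrailtyWeibullParams):
    """Age of maximal incidence, or None when the hazard is monotone.

    Setting the derivative of the marginal hazard to zero gives the
    interior maximum ``c * [(m-1) / (sigma^2 (m - n (m-1)))]**(1/m)``,
    which exists for m > 1, sigma > 0 and m - n (m-1) > 0; in the n -> 0
    limit this reduces to ``c * ((m-1)/(m sigma^2))**(1/m)``.
    """
    m, c, sigma, n = params.m, params.c, params.sigma, params.n
    if m <= 1.0 or sigma == 0.0:
        return None
    denom = m - n * (m - 1.0)
    if denom <= 0.0:
        return None
    return c * ((m - 1.0) / (sigma**2 * denom)) ** (1.0 / m)


def covariate_multiplier(profile: CovariateProfile, cov: CovariateParams) -> float:
    """Sex/race relative risks and the 10-year period trend factor.

    Returns ``r_sex**female * r_race**african_american *
    (1 + f_year/100)**((year - ref_year)/10)``; exactly 1 for a
    male/Caucasian stratum observed in the reference year.
    """
    trend = (1.0 + cov.f_year / 100.0) ** ((profile.year - cov.ref_year) / 10.0)
    return (
        cov.r_sex**profile.female
        * cov.r_race**profile.african_american
        * trend
    )


def model2_rate(
    age,
    profile: CovariateProfile,
    params: FrailtyWeibullParams,
    cov: CovariateParams,
):
    """Generalized age-, year-, sex- and race-specific incidence rate.

    The frailty marginal hazard scaled by the covariate multiplier; equal
    to the baseline model for the reference profile.
    """
    return frailty_marginal_hazard(age, params) * covariate_multiplier(profile, cov)


def armitage_doll_hazard(age, a: float, m: float):
    """Classic multistage power-law hazard ``a * age**(m-1)``.

    Homogeneous-population comparator; identical to the Weibull baseline
    under a = m / c**m.  The log-log slope of the hazard equals m - 1.
    """
    x = _check_age(age)
    if not (a > 0.0):
        raise ValueError(f"scale a must be > 0, got {a}")
    if not (m >= 1.0):
        raise ValueError(f"m must be >= 1, got {m}")
    out = a * x ** (m - 1.0)
    return _maybe_scalar(age, out)
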