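"""Weighted nonlinear least-squares and Poisson-likelihood fitting.

Two estimation routes are provided for the same rate models:

* ``wnls`` — minimize ``sum_i w_i (rate_i - lambda_i)^2`` with weights
  reciprocal to the Wilson-adjusted variance of each observed rate;
* ``mle`` — maximize the Poisson likelihood of the counts given
  ``mu_i = person_years_i * lambda_i``, implemented as least squares on
  signed square-root deviance residuals (the two are equivalent at the
  optimum and the residual formulation is far better conditioned).

The objective is multimodal in (sigma, n), so every fit is run from a
small multistart set: one data-driven initial point (shape from the
log-log slope of the rising limb of the age pattern) plus seeded
Latin-hypercube draws inside the parameter bounds.  Ties are broken by
objective value and then by the smaller number of m-stages.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.special import xlogy
from scipy.stats import qmc
from statsmodels.stats.stattools import durbin_watson

from .data_model import IncidenceTable, filter_min_age, rate_and_variance
from .hazard_models import (
    CovariateParams,
    FrailtyWeibullParams,
    frailty_marginal_hazard,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "ResidualDiagnostics",
    "ModelComparison",
    "fit_model1",
    "fit_model2",
    "goodness_of_fit",
    "residual_diagnostics",
    "compare_models",
    "fitted_curve",
]

MODEL1_NAMES = ("m", "c", "sigma", "n")
MODEL2_NAMES = MODEL1_NAMES + ("r_sex", "r_race", "f_year")

DEFAULT_BOUNDS = {
    "m": (1.0, 30.0),
    "c": (10.0, 300.0),
    "sigma": (0.0, 500.0),
    "n": (0.0, 3.0),
    "r_sex": (0.01, 20.0),
    "r_race": (0.01, 20.0),
    "f_year": (-95.0, 400.0),
    "q_year": (-50.0, 50.0),
    "log_a": (-60.0, 0.0),
}

_TINY_MU = 1e-300


@dataclass
class FitConfig:
    """Estimation settings shared by all fitting entry points.

    method : 'wnls' (weighted nonlinear least squares) or 'mle'
        (Poisson maximum likelihood)
    multistart : number of optimizer starts (>= 1); the first start is
        data-driven, the rest are Latin-hypercube draws within bounds
    seed : seed for the multistart draws (fits are deterministic given
        config + data)
    bounds : per-parameter (lower, upper) overrides of DEFAULT_BOUNDS
    fixed : parameters held at a given value (excluded from estimation)
    tol : relative convergence tolerance passed to the optimizer
    z : Wilson z-level used for rate variances / weights
    include_85plus : keep the open-ended top age bin when filtering
    """

    method: str = "wnls"
    multistart: int = 8
    seed: int = 0
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    tol: float = 1e-10
    z: float = 1.96
    include_85plus: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("wnls", "mle"):
            raise ValueError("method must be 'wnls' or 'mle'")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    def bound(self, name: str) -> tuple:
        return self.bounds.get(name, DEFAULT_BOUNDS.get(name, (-6.0, 6.0)))


@dataclass
class ResidualDiagnostics:
    """Diagnostics on weighted residuals of a fit.

    normality_p : p-value of the moment-based (D'Agostino) omnibus test
    heteroscedasticity_p : p-value of the rank (Spearman) regression of
        squared residuals on fitted values
    autocorrelation_stat : Durbin-Watson statistic over age ordering
        (about 2 for uncorrelated residuals)
    available : False when there are too few (or degenerate) residuals
    """

    normality_p: float = float("nan")
    heteroscedasticity_p: float = float("nan")
    autocorrelation_stat: float = float("nan")
    available: bool = False


@dataclass
class FitResult:
    """Estimates, uncertainties and fit quality for one model fit."""

    model: str
    params: dict
    se: dict
    chi2_dof: float
    converged: bool
    objective: float
    n_points: int
    n_free: int
    diagnostics: ResidualDiagnostics | None = None
    cov: np.ndarray | None = None
    free_names: tuple = ()
    fixed: dict = field(default_factory=dict)
    messages: list = field(default_factory=list)
    method: str = "wnls"
    ref_year: int = 1988
    apc: object = None  # APCParams when the fit came from the APC extension

    @property
    def frailty_params(self) -> FrailtyWeibullParams:
        return FrailtyWeibullParams(
            m=self.params["m"],
            c=self.params["c"],
            sigma=self.params["sigma"],
            n=self.params["n"],
        )

    @property
    def covariate_params(self) -> CovariateParams:
        return CovariateParams(
            r_sex=self.params.get("r_sex", 1.0),
            r_race=self.params.get("r_race", 1.0),
            f_year=self.params.get("f_year", 0.0),
            ref_year=self.ref_year,
        )

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "method": self.method,
            "params": dict(self.params),
            "se": dict(self.se),
            "chi2_dof": self.chi2_dof,
            "converged": self.converged,
            "objective": self.objective,
            "n_points": self.n_points,
            "n_free": self.n_free,
            "ref_year": self.ref_year,
            "messages": list(self.messages),
        }
        if self.diagnostics is not None:
            d["diagnostics"] = {
                "normality_p": self.diagnostics.normality_p,
                "heteroscedasticity_p": self.diagnostics.heteroscedasticity_p,
                "autocorrelation_stat": self.diagnostics.autocorrelation_stat,
                "available": self.diagnostics.available,
            }
        if self.apc is not None:
            d["apc"] = self.apc.to_dict()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class ModelComparison:
    """Ranking of candidate models by chi2/d.o.f. plus nested F-tests."""

    results: dict
    ranking: list  # (model name, chi2_dof), best first
    f_tests: list  # dicts with reduced/full model names, F, df, p
    messages: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# internal machinery
# ---------------------------------------------------------------------------


def _age_midpoints(ages: np.ndarray) -> np.ndarray:
    """Bin midpoints; half-width inferred from the modal bin spacing."""
    uniq = np.unique(ages)
    half = 0.5 if len(uniq) < 2 else float(np.median(np.diff(uniq))) / 2.0
    return ages + half


def _predict_cells(theta: dict, age_mid, female, aa, year, ref_year):
    params = FrailtyWeibullParams(theta["m"], theta["c"], theta["sigma"], theta["n"])
    lam = frailty_marginal_hazard(age_mid, params)
    lam = lam * theta.get("r_sex", 1.0) ** female * theta.get("r_race", 1.0) ** aa
    t = (np.asarray(year, float) - ref_year) / 10.0
    lam = lam * (1.0 + theta.get("f_year", 0.0) / 100.0) ** t
    q = theta.get("q_year", 0.0)
    if q:
        lam = lam * np.exp(q * t * t)
    return lam


def _armitage_doll_rate(theta: dict, age_mid):
    return np.exp(theta["log_a"]) * age_mid ** (theta["m"] - 1.0)


def _rate_function(model: str, arrays: dict, ref_year: int):
    """theta -> predicted rates on the cells described by ``arrays``."""
    age_mid = arrays["age_mid"]
    if model == "armitage_doll":
        return lambda theta: _armitage_doll_rate(theta, age_mid)
    female = arrays.get("female", 0.0)
    aa = arrays.get("african_american", 0.0)
    year = arrays.get("year", float(ref_year))
    return lambda theta: _predict_cells(theta, age_mid, female, aa, year, ref_year)


def _apc_factor(arrays: dict, apc) -> np.ndarray:
    """Fixed cohort x period multiplier per cell from fitted APCParams."""
    births = (arrays["year"] - np.floor(arrays["age"])).astype(int)
    years = arrays["year"].astype(int)
    return np.array(
        [
            apc.cohort_multiplier(b) * apc.period_multiplier(y)
            for b, y in zip(births, years)
        ]
    )


def _result_rate_fn(result: FitResult, arrays: dict):
    """Prediction function for a finished fit (APC multipliers frozen)."""
    base = _rate_function(
        "armitage_doll" if result.model == "armitage_doll" else result.model,
        arrays,
        result.ref_year,
    )
    if result.apc is None:
        return base
    factor = _apc_factor(arrays, result.apc)
    return lambda theta: base(theta) * factor


def _heuristic_start(ages_mid: np.ndarray, rates: np.ndarray, config: FitConfig) -> dict:
    """Data-driven start: m from the log-log slope of the rising limb,
    c from the age of the empirical maximum, sigma = n = 1, neutral
    covariates."""
    pos = rates > 0
    m0, c0 = 5.0, float(ages_mid.max())
    if pos.sum() >= 3:
        x, r = ages_mid[pos], rates[pos]
        imax = int(np.argmax(r))
        c0 = float(x[imax]) if imax > 0 else float(x.max())
        rising = slice(0, max(imax + 1, 3))
        xr, rr = x[rising], r[rising]
        if len(xr) >= 2 and np.ptp(np.log(xr)) > 0:
            slope = np.polyfit(np.log(xr), np.log(rr), 1)[0]
            m0 = slope + 1.0
    lo_m, hi_m = config.bound("m")
    lo_c, hi_c = config.bound("c")
    return {
        "m": float(np.clip(m0, lo_m + 0.1, hi_m - 0.1)),
        "c": float(np.clip(c0, lo_c + 1.0, hi_c - 1.0)),
        "sigma": 1.0,
        "n": 1.0,
        "r_sex": 1.0,
        "r_race": 1.0,
        "f_year": 0.0,
        "q_year": 0.0,
        "log_a": -10.0,
    }


def _start_points(free_names, start0, config: FitConfig):
    lo = np.array([config.bound(p)[0] for p in free_names])
    hi = np.array([config.bound(p)[1] for p in free_names])
    x0 = np.clip(
        np.array([start0.get(p, 0.0) for p in free_names]), lo, hi
    )
    starts = [x0]
    n_extra = config.multistart - 1
    if n_extra > 0:
        sampler = qmc.LatinHypercube(d=len(free_names), seed=config.seed)
        for d in sampler.random(n_extra):
            starts.append(lo + d * (hi - lo))
    return starts, (lo, hi)


def _run_fit(arrays, free_names, config: FitConfig, fixed: dict, rate_fn):
    """Multistart bounded least squares; returns (best scipy result,
    full parameter dict, number of successful starts)."""
    sw = np.sqrt(arrays["weight"])
    rate_obs = arrays["rate"]
    count = arrays["count"]
    py = arrays["person_years"]

    def theta_of(x):
        theta = dict(fixed)
        theta.update(zip(free_names, x))
        return theta

    if config.method == "wnls":

        def residuals(x):
            return sw * (rate_obs - rate_fn(theta_of(x)))

    else:  # Poisson MLE via signed sqrt-deviance residuals

        def residuals(x):
            mu = np.maximum(rate_fn(theta_of(x)) * py, _TINY_MU)
            dev2 = 2.0 * (xlogy(count, count / mu) - (count - mu))
            return np.sign(count - mu) * np.sqrt(np.maximum(dev2, 0.0))

    start0 = _heuristic_start(arrays["age_mid"], rate_obs, config)
    starts, bounds = _start_points(free_names, start0, config)

    best, best_key, n_ok = None, None, 0
    for x0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = least_squares(
                    residuals,
                    x0,
                    bounds=bounds,
                    method="trf",
                    x_scale="jac",
                    ftol=config.tol,
                    xtol=config.tol,
                    gtol=config.tol,
                )
        except Exception:
            continue
        if not np.isfinite(res.cost):
            continue
        n_ok += 1
        m_hat = dict(zip(free_names, res.x)).get("m", fixed.get("m", 0.0))
        key = (res.cost, m_hat)
        if best is None or key < best_key:
            best, best_key = res, key
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    return best, theta_of(best.x), n_ok


def _wilson_chi2(theta, rate_fn, arrays, n_free):
    resid = arrays["rate"] - rate_fn(theta)
    chi2 = float(np.sum(arrays["weight"] * resid**2))
    dof = len(resid) - n_free
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom ({dof})")
    return chi2 / dof


def _standard_errors(res, free_names, method, chi2_dof):
    """Curvature-based covariance of the free parameters.

    WNLS: inv(J'J) of weighted residuals, scaled by chi2/d.o.f.
    MLE: inv(J'J) of deviance residuals, which equals the inverse
    observed Fisher information of the Poisson likelihood at the optimum.
    """
    J = res.jac
    try:
        jtj_inv = np.linalg.pinv(J.T @ J)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        return {p: float("nan") for p in free_names}, None
    cov = jtj_inv * chi2_dof if method == "wnls" else jtj_inv
    se = {p: float(np.sqrt(max(cov[i, i], 0.0))) for i, p in enumerate(free_names)}
    return se, cov


def _diagnostics(theta, rate_fn, arrays) -> ResidualDiagnostics:
    fitted = rate_fn(theta)
    resid = np.sqrt(arrays["weight"]) * (arrays["rate"] - fitted)
    if len(resid) < 20 or np.allclose(resid, 0.0) or np.std(resid) == 0.0:
        return ResidualDiagnostics(available=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm_p = float(stats.normaltest(resid).pvalue)
        het_p = float(stats.spearmanr(fitted, resid**2).pvalue)
    dw = float(durbin_watson(resid))
    return ResidualDiagnostics(
        normality_p=norm_p,
        heteroscedasticity_p=het_p,
        autocorrelation_stat=dw,
        available=True,
    )


def _finalize(
    model, arrays, res, theta, free_names, fixed, config, ref_year, messages,
    n_ok, rate_fn,
):
    n_free = len(free_names)
    chi2_dof = _wilson_chi2(theta, rate_fn, arrays, n_free)
    se = {p: 0.0 for p in fixed}
    se_free, cov = _standard_errors(res, free_names, config.method, chi2_dof)
    se.update(se_free)
    return FitResult(
        model=model,
        params={k: float(v) for k, v in theta.items()},
        se=se,
        chi2_dof=chi2_dof,
        converged=bool(res.success and n_ok > 0),
        objective=float(2.0 * res.cost),
        n_points=len(arrays["rate"]),
        n_free=n_free,
        diagnostics=_diagnostics(theta, rate_fn, arrays),
        cov=cov,
        free_names=tuple(free_names),
        fixed=dict(fixed),
        messages=messages,
        method=config.method,
        ref_year=ref_year,
    )


def _pooled_arrays(table: IncidenceTable, config: FitConfig) -> dict:
    pooled = filter_min_age(table, config.include_85plus).pooled_ages()
    if len(pooled) < 10:
        raise ValueError(f"need >= 10 age points above min_age, got {len(pooled)}")
    if (pooled["count"] == 0).all():
        raise ValueError("degenerate data: all counts are zero")
    count = pooled["count"].to_numpy(float)
    py = pooled["person_years"].to_numpy(float)
    rate, var = rate_and_variance(count, py, z=config.z)
    ages = pooled["age"].to_numpy(float)
    return {
        "age": ages,
        "age_mid": _age_midpoints(ages),
        "rate": rate,
        "weight": 1.0 / var,
        "count": count,
        "person_years": py,
    }


def _cell_arrays(table: IncidenceTable, config: FitConfig) -> dict:
    df = filter_min_age(table, config.include_85plus).with_rates(config.z)
    df = df.sort_values(["female", "african_american", "year", "age"]).reset_index(
        drop=True
    )
    if (df["count"] == 0).all():
        raise ValueError("degenerate data: all counts are zero")
    return {
        "age": df["age"].to_numpy(float),
        "age_mid": _age_midpoints(df["age"].to_numpy(float)),
        "year": df["year"].to_numpy(float),
        "female": df["female"].to_numpy(float),
        "african_american": df["african_american"].to_numpy(float),
        "rate": df["rate"].to_numpy(),
        "weight": df["weight"].to_numpy(),
        "count": df["count"].to_numpy(float),
        "person_years": df["person_years"].to_numpy(),
    }


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------


def fit_model1(
    table: IncidenceTable,
    config: FitConfig | None = None,
    model: str = "frailty_weibull",
) -> FitResult:
    """Fit an age pattern pooled over year/sex/race strata.

    ``model`` selects the rate family: 'frailty_weibull' (m, c, sigma, n),
    'weibull' (sigma fixed at 0), or 'armitage_doll' (a, m power law).
    """
    config = config or FitConfig()
    arrays = _pooled_arrays(table, config)
    fixed = dict(config.fixed)
    if model == "frailty_weibull":
        names = [p for p in MODEL1_NAMES if p not in fixed]
    elif model == "weibull":
        fixed.setdefault("sigma", 0.0)
        fixed.setdefault("n", 1.0)
        names = [p for p in MODEL1_NAMES if p not in fixed]
    elif model == "armitage_doll":
        names = [p for p in ("log_a", "m") if p not in fixed]
    else:
        raise ValueError(f"unknown model {model!r}")
    rate_fn = _rate_function(model, arrays, ref_year=0)
    res, theta, n_ok = _run_fit(arrays, names, config, fixed, rate_fn)
    if model == "armitage_doll":
        theta = dict(theta, a=float(np.exp(theta["log_a"])))
    return _finalize(
        model, arrays, res, theta, names, fixed, config, 0, [], n_ok, rate_fn
    )


def fit_model2(
    table: IncidenceTable,
    config: FitConfig | None = None,
    ref_year: int = 1988,
    quadratic: bool = False,
) -> FitResult:
    """Joint fit of the covariate-generalized model over all panel cells.

    Estimates (m, c, sigma, n, r_sex, r_race, f_year); relative risks
    that are unidentifiable from the panel (single-sex or single-race
    input) are fixed at 1 with a warning message, and f_year is fixed at
    0 when only one calendar year is present.  ``quadratic`` adds the
    curvature term exp(q_year * ((year - ref_year)/10)^2) to the period
    trend.
    """
    config = config or FitConfig()
    arrays = _cell_arrays(table, config)
    messages = []
    fixed = dict(config.fixed)
    if len(np.unique(arrays["female"])) < 2 and "r_sex" not in fixed:
        fixed["r_sex"] = 1.0
        messages.append("r_sex unidentifiable from single-sex panel; fixed at 1")
    if len(np.unique(arrays["african_american"])) < 2 and "r_race" not in fixed:
        fixed["r_race"] = 1.0
        messages.append("r_race unidentifiable from single-race panel; fixed at 1")
    if len(np.unique(arrays["year"])) < 2 and "f_year" not in fixed:
        fixed["f_year"] = 0.0
        messages.append("f_year unidentifiable from single-year panel; fixed at 0")
    names = [p for p in MODEL2_NAMES if p not in fixed]
    if quadratic and "q_year" not in fixed:
        names.append("q_year")
    rate_fn = _rate_function("frailty_weibull2", arrays, ref_year)
    res, theta, n_ok = _run_fit(arrays, names, config, fixed, rate_fn)
    return _finalize(
        "frailty_weibull2", arrays, res, theta, names, fixed, config, ref_year,
        messages, n_ok, rate_fn,
    )


def _arrays_for(result: FitResult, table: IncidenceTable, config: FitConfig) -> dict:
    if result.model in ("frailty_weibull", "weibull", "armitage_doll"):
        return _pooled_arrays(table, config)
    return _cell_arrays(table, config)


def goodness_of_fit(
    result: FitResult, table: IncidenceTable, config: FitConfig | None = None
) -> float:
    """Wilson-weighted chi-square per degree of freedom.

    ``sum_i w_i (rate_i - lambda_hat_i)^2 / (n_points - n_free)``; values
    near 1 indicate residuals consistent with sampling noise.
    """
    config = config or FitConfig(method=result.method)
    arrays = _arrays_for(result, table, config)
    rate_fn = _result_rate_fn(result, arrays)
    return _wilson_chi2(result.params, rate_fn, arrays, result.n_free)


def residual_diagnostics(
    result: FitResult, table: IncidenceTable, config: FitConfig | None = None
) -> ResidualDiagnostics:
    """Normality, heteroscedasticity and autocorrelation checks.

    Weighted residuals are tested with the moment-based omnibus
    normality test, a Spearman rank regression of squared residuals on
    fitted values, and the Durbin-Watson statistic over age ordering
    (strata concatenated in sex/race/year order).
    """
    config = config or FitConfig(method=result.method)
    arrays = _arrays_for(result, table, config)
    return _diagnostics(result.params, _result_rate_fn(result, arrays), arrays)


_N_PARAMS = {"armitage_doll": 2, "weibull": 2, "frailty_weibull": 4}
_NESTED_IN_FRAILTY = ("armitage_doll", "weibull")


def compare_models(
    table: IncidenceTable,
    candidates: list | None = None,
    config: FitConfig | None = None,
) -> ModelComparison:
    """Fit candidate hazard families to a pooled age pattern and rank them.

    Candidates come from {'armitage_doll', 'weibull', 'frailty_weibull'};
    the ranking is by chi2/d.o.f. and each nested pair (power law inside
    the frailty family) is also compared with an F-test on the weighted
    residual sums of squares.
    """
    config = config or FitConfig()
    candidates = list(candidates or ("armitage_doll", "weibull", "frailty_weibull"))
    results, messages = {}, []
    for name in candidates:
        try:
            r = fit_model1(table, config, model=name)
        except Exception as exc:  # pragma: no cover - defensive
            messages.append(f"{name}: fit failed ({exc})")
            continue
        if not r.converged:
            messages.append(f"{name}: did not converge; excluded from ranking")
            continue
        results[name] = r
    ranking = sorted(
        ((name, r.chi2_dof) for name, r in results.items()), key=lambda t: t[1]
    )
    f_tests = []
    if "frailty_weibull" in results:
        full = results["frailty_weibull"]
        for name in _NESTED_IN_FRAILTY:
            if name not in results:
                continue
            red = results[name]
            df1 = _N_PARAMS["frailty_weibull"] - _N_PARAMS[name]
            df2 = full.n_points - _N_PARAMS["frailty_weibull"]
            rss_red = red.chi2_dof * (red.n_points - red.n_free)
            rss_full = full.chi2_dof * df2
            if df2 <= 0 or rss_full <= 0:
                continue
            fstat = ((rss_red - rss_full) / df1) / (rss_full / df2)
            p = float(stats.f.sf(max(fstat, 0.0), df1, df2))
            f_tests.append(
                {
                    "reduced": name,
                    "full": "frailty_weibull",
                    "F": float(fstat),
                    "df": (df1, df2),
                    "p": p,
                }
            )
    return ModelComparison(
        results=results, ranking=ranking, f_tests=f_tests, messages=messages
    )


def fitted_curve(
    result: FitResult, table: IncidenceTable, config: FitConfig | None = None
) -> pd.DataFrame:
    """Observed vs fitted rates (and residuals) on the cells used in the fit."""
    config = config or FitConfig(method=result.method)
    arrays = _arrays_for(result, table, config)
    fitted = _result_rate_fn(result, arrays)(result.params)
    out = {"age": arrays["age"].astype(int)}
    for k in ("year", "female", "african_american"):
        if k in arrays:
            out[k] = arrays[k].astype(int)
    out["observed"] = arrays["rate"]
    out["fitted"] = fitted
    out["residual"] = arrays["rate"] - fitted
    return pd.DataFrame(out)
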