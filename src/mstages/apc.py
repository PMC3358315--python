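"""Age-period-cohort extension of the covariate-generalized frailty model.

The single log-linear period trend of the generalized model is replaced
by nonparametric multiplicative effects: one multiplier per birth-cohort
bin (10-year, calendar-decade aligned by default) and one per
calendar-period bin (5-year, the trailing bin absorbing any remainder of
the study window).  Multipliers are estimated on the log scale to keep
them positive, and the bins containing the panel midpoint are fixed at
exactly 1 — the normalization that removes the k / (1/k) rescaling
indeterminacy between cohort and period effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import IncidenceTable
from .fitting import (
    MODEL1_NAMES,
    FitConfig,
    FitResult,
    _cell_arrays,
    _finalize,
    _rate_function,
    _run_fit,
)
from .hazard_models import (
    CovariateParams,
    CovariateProfile,
    FrailtyWeibullParams,
    frailty_marginal_hazard,
)

__all__ = ["APCParams", "make_bins", "default_apc_params", "apc_rate", "fit_apc"]


def _label(start: int, end: int) -> str:
    return f"{start}-{end}"


@dataclass
class APCParams:
    """Binned cohort and period multipliers with their normalization.

    cohort_bins / period_bins : ordered (start, end) inclusive year spans
    g_cohort / g_period : label -> positive multiplier; reference bins
        carry exactly 1
    ref_cohort / ref_period : labels of the bins fixed at 1
    """

    cohort_bins: list
    period_bins: list
    g_cohort: dict = field(default_factory=dict)
    g_period: dict = field(default_factory=dict)
    ref_cohort: str = ""
    ref_period: str = ""

    def __post_init__(self) -> None:
        for label, g in list(self.g_cohort.items()) + list(self.g_period.items()):
            if not g > 0:
                raise ValueError(f"multiplier for {label} must be positive, got {g}")
        if self.ref_cohort and self.g_cohort.get(self.ref_cohort) != 1.0:
            raise ValueError("reference cohort multiplier must be exactly 1")
        if self.ref_period and self.g_period.get(self.ref_period) != 1.0:
            raise ValueError("reference period multiplier must be exactly 1")

    def cohort_label(self, birth_year: int) -> str:
        for start, end in self.cohort_bins:
            if start <= birth_year <= end:
                return _label(start, end)
        raise ValueError(f"birth year {birth_year} outside defined cohort bins")

    def period_label(self, year: int) -> str:
        for start, end in self.period_bins:
            if start <= year <= end:
                return _label(start, end)
        raise ValueError(f"calendar year {year} outside defined period bins")

    def cohort_multiplier(self, birth_year: int) -> float:
        return self.g_cohort[self.cohort_label(birth_year)]

    def period_multiplier(self, year: int) -> float:
        return self.g_period[self.period_label(year)]

    def to_dict(self) -> dict:
        return {
            "g_cohort": dict(self.g_cohort),
            "g_period": dict(self.g_period),
            "ref_cohort": self.ref_cohort,
            "ref_period": self.ref_period,
        }


def make_bins(years, ages, cohort_width: int = 10, period_width: int = 5) -> tuple:
    """Cohort and period bins covering a panel's (year - age) and year span.

    Cohort bins are calendar-decade aligned; period bins start at the
    first study year, and the trailing period bin is widened to absorb a
    remainder shorter than ``period_width`` (e.g. 1998-2003 for a
    1973-2003 window).
    """
    years = sorted(set(int(y) for y in years))
    ages = sorted(set(int(a) for a in ages))
    b_min = years[0] - ages[-1]
    b_max = years[-1] - ages[0]
    c_start = (b_min // cohort_width) * cohort_width
    cohort_bins = [
        (s, s + cohort_width - 1) for s in range(c_start, b_max + 1, cohort_width)
    ]
    starts = list(range(years[0], years[-1] + 1, period_width))
    if len(starts) > 1 and years[-1] - starts[-1] + 1 < period_width:
        starts.pop()
    period_bins = []
    for i, s in enumerate(starts):
        e = starts[i + 1] - 1 if i + 1 < len(starts) else years[-1]
        period_bins.append((s, e))
    return cohort_bins, period_bins


def _midpoint_bin(bins, mid):
    for start, end in bins:
        if start <= mid <= end:
            return _label(start, end)
    dists = [min(abs(mid - s), abs(mid - e)) for s, e in bins]
    s, e = bins[int(np.argmin(dists))]
    return _label(s, e)


def default_apc_params(
    table: IncidenceTable, cohort_width: int = 10, period_width: int = 5
) -> APCParams:
    """All-ones APC multipliers with midpoint reference bins for a panel."""
    years = table.data["year"].to_numpy(int)
    ages = table.data["age"].to_numpy(int)
    return _default_from_arrays(years, ages, cohort_width, period_width)


def _default_from_arrays(years, ages, cohort_width, period_width) -> APCParams:
    cohort_bins, period_bins = make_bins(years, ages, cohort_width, period_width)
    births = np.asarray(years, int) - np.asarray(ages, int)
    ref_c = _midpoint_bin(cohort_bins, int((births.min() + births.max()) // 2))
    ref_p = _midpoint_bin(period_bins, int((np.min(years) + np.max(years)) // 2))
    return APCParams(
        cohort_bins=cohort_bins,
        period_bins=period_bins,
        g_cohort={_label(s, e): 1.0 for s, e in cohort_bins},
        g_period={_label(s, e): 1.0 for s, e in period_bins},
        ref_cohort=ref_c,
        ref_period=ref_p,
    )


def apc_rate(
    age,
    profile: CovariateProfile,
    params: FrailtyWeibullParams,
    cov: CovariateParams,
    apc: APCParams,
):
    """Incidence rate with binned cohort and period multipliers.

    The log-linear f_year trend of the generalized model is disabled by
    the substitution, so only the sex and race relative risks of ``cov``
    enter; the cohort bin is looked up at birth year = year - age.
    """
    lam = frailty_marginal_hazard(age, params)
    lam = lam * cov.r_sex**profile.female * cov.r_race**profile.african_american
    ages = np.atleast_1d(np.asarray(age, float))
    births = (profile.year - np.floor(ages)).astype(int)
    factor = np.array([apc.cohort_multiplier(b) for b in births])
    factor = factor * apc.period_multiplier(profile.year)
    out = lam * (factor if np.ndim(age) else float(factor[0]))
    return out


def fit_apc(
    table: IncidenceTable,
    config: FitConfig | None = None,
    cohort_width: int = 10,
    period_width: int = 5,
) -> FitResult:
    """Joint estimation of baseline, relative-risk and APC multipliers.

    The period trend parameter f_year is removed (it would be confounded
    with the period multipliers); multipliers are estimated as log g
    with the reference bins held at log g = 0.  Requires a panel
    spanning at least 3 period bins and 4 cohort bins.
    """
    config = config or FitConfig()
    arrays = _cell_arrays(table, config)
    apc0 = _default_from_arrays(
        arrays["year"].astype(int), arrays["age"].astype(int),
        cohort_width, period_width,
    )
    c_names = [_label(s, e) for s, e in apc0.cohort_bins]
    p_names = [_label(s, e) for s, e in apc0.period_bins]
    births = (arrays["year"] - np.floor(arrays["age"])).astype(int)
    c_idx = np.array([c_names.index(apc0.cohort_label(b)) for b in births])
    p_idx = np.array([p_names.index(apc0.period_label(y)) for y in arrays["year"].astype(int)])
    present_c = sorted(set(c_idx))
    present_p = sorted(set(p_idx))
    if len(present_p) < 3 or len(present_c) < 4:
        raise ValueError(
            f"panel spans {len(present_p)} period and {len(present_c)} cohort "
            "bins; need >= 3 periods and >= 4 cohorts"
        )
    messages = []
    fixed = dict(config.fixed)
    fixed.setdefault("f_year", 0.0)
    if len(np.unique(arrays["female"])) < 2 and "r_sex" not in fixed:
        fixed["r_sex"] = 1.0
        messages.append("r_sex unidentifiable from single-sex panel; fixed at 1")
    if len(np.unique(arrays["african_american"])) < 2 and "r_race" not in fixed:
        fixed["r_race"] = 1.0
        messages.append("r_race unidentifiable from single-race panel; fixed at 1")
    base_names = [p for p in (*MODEL1_NAMES, "r_sex", "r_race") if p not in fixed]
    ref_ci = c_names.index(apc0.ref_cohort)
    ref_pi = p_names.index(apc0.ref_period)
    free_c = [i for i in present_c if i != ref_ci]
    free_p = [i for i in present_p if i != ref_pi]
    lg_names = [f"lg_c{i}" for i in free_c] + [f"lg_p{i}" for i in free_p]
    free_names = base_names + lg_names

    ref_year = int(np.median(arrays["year"]))
    base_fn = _rate_function("frailty_weibull2", arrays, ref_year)
    n_c, n_p = len(c_names), len(p_names)

    def rate_fn(theta):
        lg_c = np.zeros(n_c)
        lg_p = np.zeros(n_p)
        for i in free_c:
            lg_c[i] = theta.get(f"lg_c{i}", 0.0)
        for i in free_p:
            lg_p[i] = theta.get(f"lg_p{i}", 0.0)
        return base_fn(theta) * np.exp(lg_c[c_idx] + lg_p[p_idx])

    res, theta, n_ok = _run_fit(arrays, free_names, config, fixed, rate_fn)
    result = _finalize(
        "apc", arrays, res, theta, free_names, fixed, config, ref_year,
        messages, n_ok, rate_fn,
    )
    g_cohort = {c_names[i]: float(np.exp(theta.get(f"lg_c{i}", 0.0))) for i in present_c}
    g_cohort[apc0.ref_cohort] = 1.0
    g_period = {p_names[i]: float(np.exp(theta.get(f"lg_p{i}", 0.0))) for i in present_p}
    g_period[apc0.ref_period] = 1.0
    result.apc = APCParams(
        cohort_bins=[apc0.cohort_bins[i] for i in present_c],
        period_bins=[apc0.period_bins[i] for i in present_p],
        g_cohort=g_cohort,
        g_period=g_period,
        ref_cohort=apc0.ref_cohort,
        ref_period=apc0.ref_period,
    )
    return result
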