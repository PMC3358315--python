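"""SEER-like synthetic incidence panels and stage tables.

Registry extracts of histotype-specific incidence are access-restricted,
so every stage of the pipeline is exercised on simulated panels that
reproduce the registry's statistical structure: 1-year age bins, a
31-year study window (1973-2003), two sexes, two races, cell counts
drawn Poisson around model-generated rates, and stage-at-diagnosis
fraction tables.  The bundled parameter library carries one generating
parameter set per studied cancer (14 adenocarcinomas, 12 squamous cell
carcinomas) at the published precision, so a "known-truth" panel can be
simulated for any of them.

The default exposure is a constant 2e5 person-years per (age, year,
sex, race) cell — the scale at which recovered parameters have standard
errors comparable to published ones — with an optional linear taper
above age 80 mimicking registry thinning at the oldest ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .apc import APCParams, apc_rate
from .data_model import (
    STAGE_CATEGORIES,
    IncidenceTable,
    StageDistribution,
)
from .hazard_models import (
    CovariateParams,
    CovariateProfile,
    FrailtyWeibullParams,
    frailty_marginal_hazard,
    model2_rate,
)

__all__ = [
    "SyntheticCohortSpec",
    "simulate_panel",
    "simulate_stage_table",
    "load_table2",
    "build_table2_library",
    "DEFAULT_EXPOSURE",
    "DEFAULT_YEARS",
]

DEFAULT_EXPOSURE = 2.0e5
DEFAULT_YEARS = range(1973, 2004)
_RATE_OVERFLOW = 1.0e9


@dataclass
class SyntheticCohortSpec:
    """Everything needed to simulate one cancer's incidence panel.

    params / cov : generating model parameters
    apc : optional cohort/period multipliers (requires cov.f_year == 0,
        since the APC substitution replaces the log-linear trend)
    ages, years : integer ranges of 1-year age bins and calendar years
    person_years : scalar exposure per cell, or callable
        (female, african_american, age) -> exposure
    age_taper : if set, exposure is scaled linearly down to this
        fraction between age 80 and the top age
    seed : default simulation seed
    """

    params: FrailtyWeibullParams
    cov: CovariateParams = field(default_factory=CovariateParams)
    apc: APCParams | None = None
    ages: range = field(default_factory=lambda: range(0, 85))
    years: range = field(default_factory=lambda: range(1973, 2004))
    person_years: object = DEFAULT_EXPOSURE
    age_taper: float | None = None
    seed: int = 0
    cancer_label: str = "synthetic"
    histotype: str = "other"
    min_age: int = 0

    def __post_init__(self) -> None:
        if len(self.ages) == 0 or len(self.years) == 0:
            raise ValueError("age and year ranges must be non-empty")
        if self.apc is not None and self.cov.f_year != 0.0:
            raise ValueError("with APC multipliers present, f_year must be 0")

    def exposure(self, female: int, african_american: int, age: int) -> float:
        py = (
            self.person_years(female, african_american, age)
            if callable(self.person_years)
            else float(self.person_years)
        )
        if py <= 0:
            raise ValueError("exposures must be positive")
        if self.age_taper is not None and age > 80:
            top = max(self.ages)
            frac = 1.0 - (1.0 - self.age_taper) * (age - 80) / max(top - 80, 1)
            py *= max(frac, self.age_taper)
        return py

    def cell_rate(self, female: int, african_american: int, age: int, year: int) -> float:
        profile = CovariateProfile(female=female, african_american=african_american, year=year)
        x = age + 0.5  # 1-year bins evaluated at the midpoint
        if self.apc is not None:
            return float(apc_rate(x, profile, self.params, self.cov, self.apc))
        return float(model2_rate(x, profile, self.params, self.cov))


def simulate_panel(spec: SyntheticCohortSpec, seed: int | None = None) -> IncidenceTable:
    """Draw one Poisson incidence panel from a generating spec.

    Each cell's count is Poisson with mean person_years x model rate
    (rates are far below 1, so Poisson and binomial sampling coincide);
    the draw is deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ages = np.array(list(spec.ages))
    years = np.array(list(spec.years))
    haz = np.atleast_1d(frailty_marginal_hazard(ages + 0.5, spec.params))
    if spec.apc is None:
        trend = (1.0 + spec.cov.f_year / 100.0) ** ((years - spec.cov.ref_year) / 10.0)
        shape = haz[:, None] * trend[None, :]
    else:
        g = np.array(
            [
                [
                    spec.apc.cohort_multiplier(int(y - a))
                    * spec.apc.period_multiplier(int(y))
                    for y in years
                ]
                for a in ages
            ]
        )
        shape = haz[:, None] * g
    rows = []
    for f in (0, 1):
        for b in (0, 1):
            py = np.array([spec.exposure(f, b, int(a)) for a in ages])
            A, Y = np.meshgrid(ages, years, indexing="ij")
            lam = shape * spec.cov.r_sex**f * spec.cov.r_race**b
            mu = lam * py[:, None]
            if np.any(mu > _RATE_OVERFLOW):
                raise ValueError(
                    "expected counts exceed 1e9; rescale exposure or rates"
                )
            counts = rng.poisson(mu)
            rows.append(
                pd.DataFrame(
                    {
                        "age": A.ravel(),
                        "year": Y.ravel(),
                        "female": f,
                        "african_american": b,
                        "count": counts.ravel(),
                        "person_years": np.repeat(py, len(years)),
                    }
                )
            )
    data = pd.concat(rows, ignore_index=True)
    return IncidenceTable(
        data=data,
        cancer_label=spec.cancer_label,
        histotype=spec.histotype,
        min_age=spec.min_age,
    )


def simulate_stage_table(
    base: StageDistribution,
    drift: dict | None,
    years,
    seed: int = 0,
) -> list[StageDistribution]:
    """Stage-fraction tables with optional linear per-year drift.

    Fractions drift by ``drift[category]`` percentage points per year
    from the base year, are clipped to [0, 100], then renormalized so
    the total of the base distribution is preserved every year.
    """
    drift = drift or {}
    total0 = base.total()
    out = []
    for year in years:
        dt = year - base.year
        vals = np.array(
            [
                np.clip(base.fractions.get(k, 0.0) + drift.get(k, 0.0) * dt, 0.0, 100.0)
                for k in STAGE_CATEGORIES
            ]
        )
        s = vals.sum()
        if s > 0:
            vals = vals * (total0 / s)
        out.append(
            StageDistribution(
                base.cancer_label, int(year), dict(zip(STAGE_CATEGORIES, vals))
            )
        )
    return out


def load_table2() -> pd.DataFrame:
    """The bundled per-cancer generating parameter table (one row per cancer)."""
    with resources.files("mstages.data").joinpath("table2_parameters.csv").open() as fh:
        return pd.read_csv(fh)


def build_table2_library(
    years=DEFAULT_YEARS,
    person_years: float = DEFAULT_EXPOSURE,
    seed: int = 0,
    ref_year: int = 1988,
) -> dict:
    """One named SyntheticCohortSpec per published cancer (26 in all).

    Generating parameters are the published estimates at printed
    precision; each spec's age range runs from the cancer's minimum
    analysis age through 84.  Seeds are offset per cancer so panels are
    independent but reproducible.
    """
    df = load_table2()
    library = {}
    for i, row in df.iterrows():
        params = FrailtyWeibullParams(
            m=row["m"], c=row["c"], sigma=row["sigma"], n=row["n"]
        )
        cov = CovariateParams(
            r_sex=row["r_sex"],
            r_race=row["r_race"],
            f_year=row["f_year"],
            ref_year=ref_year,
        )
        library[row["name"]] = SyntheticCohortSpec(
            params=params,
            cov=cov,
            ages=range(int(row["age_min"]), 85),
            years=range(min(years), max(years) + 1),
            person_years=person_years,
            seed=seed + i,
            cancer_label=row["cancer"],
            histotype=row["histotype"],
            min_age=int(row["age_min"]),
        )
    return library
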