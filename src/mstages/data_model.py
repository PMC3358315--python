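"""Incidence panels, stage-at-diagnosis tables, rates and weights, CSV I/O.

An incidence panel is a long-format table of registry-style cells
(age bin, calendar year, sex, race) carrying a diagnosis count and the
person-years of exposure.  Rates are count / person-years; the variance
attached to each rate uses the Wilson score-interval adjustment for a
binomial proportion, which stays strictly positive at zero counts so that
every cell receives a finite weight in weighted least squares.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "HISTOTYPES",
    "STAGE_CATEGORIES",
    "IncidenceTable",
    "StageDistribution",
    "EmptyTableError",
    "rate_and_variance",
    "filter_min_age",
    "bin_ages",
    "redistribute_unstaged",
    "read_incidence_csv",
    "write_incidence_csv",
    "read_stage_csv",
    "write_stage_csv",
]

logger = logging.getLogger(__name__)

HISTOTYPES = ("AC", "SCC", "other")
STAGE_CATEGORIES = ("in_situ", "localized", "regional", "distant", "unstaged")

#: long-format panel columns (sex/race stored as binary indicators)
PANEL_COLUMNS = ["age", "year", "female", "african_american", "count", "person_years"]

#: age value labelling the open-ended top bin
TOP_AGE = 85


class EmptyTableError(ValueError):
    """Raised when a filtering operation leaves no records."""


def rate_and_variance(count, person_years, z: float = 1.96):
    """Rate and Wilson-adjusted variance of the rate.

    rate = count / person_years; the variance uses the score-interval
    (Wilson) centre p~ = (count + z^2/2) / (person_years + z^2) so that
    var = p~ (1 - p~) / (person_years + z^2) > 0 even for zero counts.
    The default z = 1.96 corresponds to the conventional 95% level.
    """
    count = np.asarray(count, dtype=float)
    py = np.asarray(person_years, dtype=float)
    if np.any(py <= 0.0):
        raise ValueError("person_years must be positive")
    if np.any(count > py):
        raise ValueError("count cannot exceed person_years")
    if not z > 0:
        raise ValueError("z must be positive")
    rate = count / py
    p_tilde = (count + z * z / 2.0) / (py + z * z)
    var = p_tilde * (1.0 - p_tilde) / (py + z * z)
    if np.ndim(count) == 0 and np.ndim(person_years) == 0:
        return float(rate), float(var)
    return rate, var


@dataclass
class IncidenceTable:
    """Long-format incidence panel for one cancer.

    data : DataFrame with columns age, year, female, african_american,
        count, person_years (one row per cell; keys unique)
    cancer_label : free-text cancer name
    histotype : one of AC / SCC / other
    min_age : minimum age (years) entering any analysis of this cancer
    """

    data: pd.DataFrame
    cancer_label: str = ""
    histotype: str = "other"
    min_age: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel is missing columns: {missing}")
        if self.histotype not in HISTOTYPES:
            raise ValueError(f"histotype must be one of {HISTOTYPES}")
        df = self.data
        if (df["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        if (df["person_years"] <= 0).any():
            raise ValueError("person_years must be positive")
        if df.duplicated(subset=["age", "year", "female", "african_american"]).any():
            raise ValueError("duplicate (age, year, sex, race) cells in panel")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_sexes(self) -> int:
        return self.data["female"].nunique()

    @property
    def n_races(self) -> int:
        return self.data["african_american"].nunique()

    def with_rates(self, z: float = 1.96) -> pd.DataFrame:
        """Copy of the panel with rate, rate_var and weight columns."""
        df = self.data.copy()
        rate, var = rate_and_variance(
            df["count"].to_numpy(), df["person_years"].to_numpy(), z=z
        )
        df["rate"] = rate
        df["rate_var"] = var
        df["weight"] = 1.0 / var
        return df

    def pooled_ages(self) -> pd.DataFrame:
        """Age pattern pooled over year/sex/race (counts and exposure summed)."""
        g = self.data.groupby("age", as_index=False)[["count", "person_years"]].sum()
        return g.sort_values("age").reset_index(drop=True)


@dataclass
class StageDistribution:
    """Stage-at-diagnosis percentages for one cancer and calendar year."""

    cancer_label: str
    year: int
    fractions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k in self.fractions:
            if k not in STAGE_CATEGORIES:
                raise ValueError(f"unknown stage category {k!r}")
        vals = np.array([self.fractions.get(k, 0.0) for k in STAGE_CATEGORIES])
        if (vals < 0).any() or (vals > 100).any():
            raise ValueError("stage fractions must lie in [0, 100]")
        if vals.sum() > 100.0 + 0.5:
            raise ValueError(f"stage fractions sum to {vals.sum():.2f} > 100")

    def total(self) -> float:
        return float(sum(self.fractions.get(k, 0.0) for k in STAGE_CATEGORIES))


def filter_min_age(table: IncidenceTable, include_85plus: bool = False) -> IncidenceTable:
    """Drop cells below the table's minimum age and, by default, the 85+ bin.

    Age bins are half-open [a, a+1); the bin labelled 85 is the open-ended
    85+ group, excluded unless ``include_85plus`` is set.
    """
    df = table.data
    keep = df["age"] >= table.min_age
    if not include_85plus:
        keep &= df["age"] < TOP_AGE
    out = df.loc[keep].reset_index(drop=True)
    if out.empty:
        raise EmptyTableError(
            f"no records at or above min_age={table.min_age} for {table.cancer_label!r}"
        )
    return replace(table, data=out)


def bin_ages(table: IncidenceTable, width: int) -> IncidenceTable:
    """Aggregate 1-year age bins into ``width``-year bins.

    Counts and person-years are summed; the bin is labelled by its start
    age.  A trailing partial bin (when width does not divide the age span)
    is retained and a warning is emitted.
    """
    if width == 1:
        return table
    if width < 1:
        raise ValueError("bin width must be a positive integer")
    df = table.data.copy()
    a0 = int(df["age"].min())
    df["age"] = a0 + ((df["age"] - a0) // width) * width
    span = int(table.data["age"].max()) - a0 + 1
    if span % width:
        warnings.warn(
            f"age span {span} not divisible by width {width}; "
            "trailing partial bin retained",
            stacklevel=2,
        )
    out = (
        df.groupby(["age", "year", "female", "african_american"], as_index=False)[
            ["count", "person_years"]
        ]
        .sum()
        .sort_values(["age", "year", "female", "african_american"])
        .reset_index(drop=True)
    )
    return replace(table, data=out)


def redistribute_unstaged(dist: StageDistribution) -> StageDistribution:
    """Reallocate the unstaged mass proportionally across staged categories.

    Assumes the unobserved stages among unstaged cancers follow the same
    distribution as the staged cases of the same year.  The total of the
    fractions is preserved and the unstaged category becomes 0.
    """
    staged = [k for k in STAGE_CATEGORIES if k != "unstaged"]
    u = dist.fractions.get("unstaged", 0.0)
    staged_sum = sum(dist.fractions.get(k, 0.0) for k in staged)
    if staged_sum <= 0.0:
        raise ValueError("cannot redistribute: all staged fractions are zero")
    if u == 0.0:
        return StageDistribution(
            dist.cancer_label, dist.year, dict(dist.fractions, unstaged=0.0)
        )
    scale = 1.0 + u / staged_sum
    fr = {k: dist.fractions.get(k, 0.0) * scale for k in staged}
    fr["unstaged"] = 0.0
    return StageDistribution(dist.cancer_label, dist.year, fr)


# ---------------------------------------------------------------------------
# CSV I/O — one comma-separated, UTF-8, header-required dialect
# ---------------------------------------------------------------------------

_SEX_OUT = {0: "male", 1: "female"}
_RACE_OUT = {0: "caucasian", 1: "african_american"}
_SEX_IN = {v: k for k, v in _SEX_OUT.items()}
_RACE_IN = {v: k for k, v in _RACE_OUT.items()}


def write_incidence_csv(table: IncidenceTable, path) -> None:
    df = table.data.copy()
    out = pd.DataFrame(
        {
            "cancer": table.cancer_label,
            "histotype": table.histotype,
            "age": df["age"].astype(int),
            "year": df["year"].astype(int),
            "sex": df["female"].map(_SEX_OUT),
            "race": df["african_american"].map(_RACE_OUT),
            "count": df["count"].astype(int),
            "person_years": df["person_years"],
        }
    )
    # %.17g keeps float64 exposures lossless through the round trip
    out.to_csv(path, index=False, float_format="%.17g")


def read_incidence_csv(path, min_age: int | None = None) -> IncidenceTable:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["cancer", "histotype", "age", "year", "sex", "race", "count", "person_years"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"incidence CSV {path} is missing columns: {missing}")
    bad_sex = set(df["sex"].unique()) - set(_SEX_IN)
    if bad_sex:
        raise ValueError(f"unknown sex labels in {path}: {sorted(bad_sex)}")
    bad_race = set(df["race"].unique()) - set(_RACE_IN)
    if bad_race:
        raise ValueError(f"unknown race labels in {path}: {sorted(bad_race)}")
    data = pd.DataFrame(
        {
            "age": df["age"].astype(int),
            "year": df["year"].astype(int),
            "female": df["sex"].map(_SEX_IN).astype(int),
            "african_american": df["race"].map(_RACE_IN).astype(int),
            "count": df["count"].astype(int),
            "person_years": df["person_years"].astype(float),
        }
    )
    label = str(df["cancer"].iloc[0]) if len(df) else ""
    histotype = str(df["histotype"].iloc[0]) if len(df) else "other"
    return IncidenceTable(
        data=data,
        cancer_label=label,
        histotype=histotype,
        min_age=0 if min_age is None else min_age,
    )


def write_stage_csv(dists: list[StageDistribution], path) -> None:
    rows = []
    for d in dists:
        row = {"cancer": d.cancer_label, "year": d.year}
        row.update({k: d.fractions.get(k, np.nan) for k in STAGE_CATEGORIES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_stage_csv(path) -> list[StageDistribution]:
    """Read a stage-fraction table; missing cells are treated as 0."""
    df = pd.read_csv(path)
    required = ["cancer", "year", *STAGE_CATEGORIES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"stage CSV {path} is missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        fractions = {}
        for k in STAGE_CATEGORIES:
            v = row[k]
            if pd.isna(v) or (isinstance(v, str) and v.strip() in ("", "-", "–")):
                logger.warning(
                    "missing %s fraction for %s %s read as 0", k, row["cancer"], row["year"]
                )
                v = 0.0
            fractions[k] = float(v)
        out.append(StageDistribution(str(row["cancer"]), int(row["year"]), fractions))
    return out
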