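import pytest
from hypothesis import settings

from mstages import (
    CovariateParams,
    FitConfig,
    FrailtyWeibullParams,
    SyntheticCohortSpec,
    build_table2_library,
    simulate_panel,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return build_table2_library()


@pytest.fixture
def quick_config():
    """Small multistart for unit tests where the start point is benign."""
    return FitConfig(multistart=2, seed=0)


def make_reference_spec(
    m=9.79,
    c=83.8,
    sigma=9.4,
    n=0.65,
    ages=range(30, 85),
    years=range(1988, 1989),
    person_years=2.0e5,
    seed=0,
    **cov_kwargs,
):
    """Panel spec with neutral covariates unless overridden: pooling the
    four sex/race strata then reproduces the baseline age pattern."""
    return SyntheticCohortSpec(
        params=FrailtyWeibullParams(m=m, c=c, sigma=sigma, n=n),
        cov=CovariateParams(**cov_kwargs),
        ages=ages,
        years=years,
        person_years=person_years,
        seed=seed,
        cancer_label="synthetic reference",
        histotype="other",
        min_age=min(ages),
    )


@pytest.fixture
def reference_spec():
    return make_reference_spec()


@pytest.fixture
def reference_panel(reference_spec):
    return simulate_panel(reference_spec, seed=0)
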