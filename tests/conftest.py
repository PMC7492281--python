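import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import leadselect as ls
from leadselect.synthetic import COHORT_ADULT, COHORT_CHILD

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_survey():
    """One default-configuration synthetic survey (households, individuals)."""
    return ls.generate_survey(seed=11)


@pytest.fixture(scope="session")
def survey_frame(default_survey):
    hh, ind = default_survey
    return ls.survey_table(hh, ind)


@pytest.fixture(scope="session")
def child_fits(survey_frame):
    """OLS and Heckman fits of the child equations on the default survey."""
    child = survey_frame[survey_frame["cohort"] == COHORT_CHILD]
    part = child[child["participated"] == 1]
    ols = ls.fit_ols(ls.build_design(part, ls.ModelSpec.child_outcome()))
    heck = ls.fit_heckman_two_step(
        ls.build_design(part, ls.ModelSpec.child_outcome()),
        ls.build_design(child, ls.ModelSpec.child_selection()),
    )
    return ols, heck


@pytest.fixture(scope="session")
def adult_fits(survey_frame):
    adult = survey_frame[survey_frame["cohort"] == COHORT_ADULT]
    part = adult[adult["participated"] == 1]
    ols = ls.fit_ols(ls.build_design(part, ls.ModelSpec.adult_outcome()))
    heck = ls.fit_heckman_two_step(
        ls.build_design(part, ls.ModelSpec.adult_outcome()),
        ls.build_design(adult, ls.ModelSpec.adult_selection()),
    )
    return ols, heck


def make_child_records(n, *, age_years=None, age_months=None, rng=None, **overrides):
    """Hand-buildable child records with constant covariates (test helper)."""
    rng = rng or np.random.default_rng(0)
    base = {
        "individual_id": np.arange(n),
        "household_id": np.arange(n),
        "sea_id": np.repeat(np.arange(max(2, n // 5)), int(np.ceil(n / max(2, n // 5))))[:n],
        "cohort": COHORT_CHILD,
        "x_km": rng.uniform(-8, 8, n),
        "y_km": rng.uniform(-8, 8, n),
        "altitude_m": 1185.0,
        "location_class": "urban",
        "household_size": 7.0,
        "dependency_ratio": 0.5,
        "per_capita_expenditure": 500.0,
        "female_head": 0.0,
        "window_days": 10,
        "sampling_weight": 1.0,
        "age_years": 5.0 if age_years is None else age_years,
        "age_months": np.nan if age_months is None else age_months,
        "female": 0.0,
        "mother_education_grades": 6.0,
        "mother_absent": 0.0,
        "participated": 1,
    }
    base.update(overrides)
    return pd.DataFrame(base)
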