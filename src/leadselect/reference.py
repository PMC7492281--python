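"""Reference coefficient sets for the Kabwe lead-exposure equations.

These are the survey-calibrated point estimates for a district hosting a
legacy lead mine waste dump (Kabwe, Zambia): a log-linear blood lead level
(BLL) equation per cohort and a probit participation equation per cohort.
Keys match the design-matrix column names of :mod:`leadselect.features`.

They play two roles in this package:

* default data-generating truth for the synthetic survey generator, so that
  simulated data carry realistic effect sizes and participation rates;
* fixed inputs for closed-form derived quantities (the age at which child
  BLL peaks, the percent decline of BLL per year of age, the direction of
  minimum exposure).

Units: distance km (entering as natural log), direction radians, altitude
metres, ages in months (under two years) or years, education in school
grades, expenditure in log local currency, window in days.
"""

from __future__ import annotations

from types import MappingProxyType

#: Child (0-10 y) outcome equation: log BLL on geography, age and covariates.
CHILD_OUTCOME = MappingProxyType(
    {
        "const": -1.71,
        "log_distance": -0.755,
        "direction": -1.08,
        "direction_sq": 0.294,
        "altitude": 0.0053,
        "is_under2": -2.23,
        "mage": 0.308,
        "mage_sq": -0.0093,
        "age_linear": -0.0507,
        "female": -0.0188,
        "mother_education": -0.0212,
        "mother_absent": 0.0145,
        "female_head": -0.0226,
        "household_size": -0.0202,
        "dependency_ratio": 0.469,
        "log_pce": 0.0181,
        "small_farm": 0.116,
        "large_farm": -0.0050,
        "makululu": 0.149,
    }
)

#: Child participation probit (selection equation), including the
#: blood-sampling window exclusion restriction.
CHILD_SELECTION = MappingProxyType(
    {
        "const": 5.07,
        "log_distance": -0.0397,
        "direction": -0.485,
        "direction_sq": 0.123,
        "altitude": -0.0038,
        "is_under2": -1.48,
        "mage": 0.122,
        "mage_sq": -0.0037,
        "age_linear": -0.0511,
        "female": -0.0618,
        "mother_education": -0.0007,
        "mother_absent": -0.144,
        "female_head": 0.0619,
        "household_size": -0.0464,
        "dependency_ratio": -0.413,
        "log_pce": -0.0438,
        "small_farm": -0.0107,
        "large_farm": 0.363,
        "makululu": -0.189,
        "window_days": 0.0202,
    }
)

#: Adult (19+ y) outcome equation.
ADULT_OUTCOME = MappingProxyType(
    {
        "const": 13.2,
        "log_distance": -0.926,
        "direction": -1.39,
        "direction_sq": 0.386,
        "altitude": -0.0074,
        "age_years": -0.0047,
        "female": -0.245,
        "own_education": -0.0200,
        "married": 0.0650,
        "residence_years": 0.0042,
        "household_size": 0.0000,
        "dependency_ratio": 0.121,
        "small_farm": 0.470,
        "large_farm": 0.516,
        "makululu": -0.160,
    }
)

#: Adult participation probit.
ADULT_SELECTION = MappingProxyType(
    {
        "const": 0.416,
        "log_distance": -0.0214,
        "direction": 0.0134,
        "direction_sq": -0.0484,
        "altitude": -0.0017,
        "age_years": 0.0085,
        "female": 0.388,
        "own_education": -0.0296,
        "married": 0.617,
        "residence_years": 0.0058,
        "household_size": -0.0702,
        "dependency_ratio": 0.401,
        "small_farm": 0.0157,
        "large_farm": 0.523,
        "makululu": -0.0286,
        "window_days": 0.0176,
    }
)

#: District population projections as of 2017 from two sources: the survey's
#: own estimate and the national statistics office projection.
POPULATION_ESTIMATES = MappingProxyType(
    {
        "survey_projection": 270389,
        "census_projection": 227551,
    }
)
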