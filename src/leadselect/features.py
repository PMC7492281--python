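"""Regressor construction for the exposure and participation equations.

The exposure model is log-linear in geographic and individual covariates:

    log BLL_i = beta_dis * log(distance_i) + beta_dir1 * direction_i
              + beta_dir2 * direction_i**2 + beta_alt * altitude_i
              + f(age_i) + X_i @ gamma + eps_i

where ``distance_i`` is the planar distance (km) from the household to the
mine waste dump, ``direction_i`` is the unsigned angle (radians, in [0, pi])
between the household bearing and the west-northwest axis -- the prevailing
wind direction along which contamination spreads -- and ``altitude_i`` is in
raw metres.  The age response f is piecewise: a quadratic in months below two
years of age (allowing the early-childhood peak driven by hand-to-mouth
behaviour and breastfeeding transfer) and linear in years from two years on.

The participation (selection) equation is a probit on the same regressors
plus the blood-sampling window length in days, which shifts the probability
of attending a clinic but not the blood lead level itself -- the exclusion
restriction that identifies the selection correction.

This module turns raw survey records into named design matrices for either
equation and either cohort (children 0-10 scored together with adolescents
11-18; adults 19+).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import MissingCovariateError, SchemaError, UndefinedFeatureError

#: Compass bearing (degrees clockwise from north) of the west-northwest axis.
WNW_BEARING_DEG = 292.5

#: Location classes; "urban" is the omitted base category.
LOCATION_CLASSES = ("urban", "small_farm", "large_farm", "makululu")
LOCATION_DUMMIES = ("small_farm", "large_farm", "makululu")

GEO_COLUMNS = ("log_distance", "direction", "direction_sq", "altitude")
CHILD_AGE_COLUMNS = ("is_under2", "mage", "mage_sq", "age_linear")
ADULT_AGE_COLUMNS = ("age_years",)
CHILD_X_COLUMNS = (
    "female",
    "mother_education",
    "mother_absent",
    "female_head",
    "household_size",
    "dependency_ratio",
    "log_pce",
) + LOCATION_DUMMIES
ADULT_X_COLUMNS = (
    "female",
    "own_education",
    "married",
    "residence_years",
    "household_size",
    "dependency_ratio",
) + LOCATION_DUMMIES


@dataclass(frozen=True)
class GeoFeatures:
    """Geographic regressors for one or more locations (arrays broadcast)."""

    distance_km: np.ndarray
    log_distance: np.ndarray
    direction_rad: np.ndarray
    direction_sq: np.ndarray
    altitude_m: np.ndarray


@dataclass(frozen=True)
class AgeFeatures:
    """Piecewise age regressors: quadratic in months under 2y, linear in years 2y+."""

    is_under2: np.ndarray
    mage: np.ndarray
    mage_sq: np.ndarray
    age_linear: np.ndarray


def bearing_unit_vector(bearing_deg: float) -> np.ndarray:
    """Unit vector (x east, y north) of a compass bearing in degrees."""
    b = math.radians(bearing_deg)
    return np.array([math.sin(b), math.cos(b)])


def compute_geo_features(
    x_km, y_km, altitude_m, wnw_bearing_deg: float = WNW_BEARING_DEG
) -> GeoFeatures:
    """Distance and direction of household locations relative to the dump site.

    Coordinates are planar km with the mine waste dump at the origin.
    ``direction`` is the unsigned angle in [0, pi] between the WNW unit
    vector and the household bearing: 0 at WNW, pi/2 at NNE or SSW, pi at
    ESE.  Points mirrored across the WNW axis get identical directions.

    Raises
    ------
    UndefinedFeatureError
        If any location coincides with the dump site (direction undefined).
    """
    x = np.asarray(x_km, dtype=float)
    y = np.asarray(y_km, dtype=float)
    alt = np.broadcast_to(np.asarray(altitude_m, dtype=float), x.shape).copy()
    r = np.hypot(x, y)
    if np.any(r == 0.0):
        raise UndefinedFeatureError(
            "location coincides with the mine waste dump site; direction is undefined"
        )
    u = bearing_unit_vector(wnw_bearing_deg)
    dot = x * u[0] + y * u[1]
    cross = u[0] * y - u[1] * x
    # atan2 of (|cross|, dot) is numerically exact at 0 and pi, where the
    # arccos formulation loses half the significant digits
    direction = np.arctan2(np.abs(cross), dot)
    return GeoFeatures(
        distance_km=r,
        log_distance=np.log(r),
        direction_rad=direction,
        direction_sq=direction**2,
        altitude_m=alt,
    )


def compute_age_features(age_years, age_months=None) -> AgeFeatures:
    """Piecewise age blocks of the child equation.

    Under two years the quadratic block in months is active and the linear
    block is zero; from two years on the reverse.  The two blocks are not
    forced to join continuously at the boundary.

    ``age_months`` must be supplied (non-missing) for every record under two
    years; it is ignored otherwise.
    """
    age = np.asarray(age_years, dtype=float)
    if np.any(age < 0):
        raise ValueError("negative age")
    under2 = age < 2.0
    if age_months is None:
        months = np.full(age.shape, np.nan)
    else:
        months = np.asarray(age_months, dtype=float)
        months = np.broadcast_to(months, age.shape)
    if np.any(under2 & ~np.isfinite(months)):
        raise MissingCovariateError("age_months required for records under 2 years")
    mage = np.where(under2, months, 0.0)
    mage = np.where(np.isfinite(mage), mage, 0.0)
    return AgeFeatures(
        is_under2=under2.astype(float),
        mage=mage,
        mage_sq=mage**2,
        age_linear=np.where(under2, 0.0, age),
    )


def direction_vertex(beta_dir1: float, beta_dir2: float) -> float:
    """Interior extremum of the quadratic direction response, -b1/(2*b2) radians."""
    if beta_dir2 == 0:
        raise ZeroDivisionError("quadratic direction coefficient is zero; no vertex")
    return -beta_dir1 / (2.0 * beta_dir2)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative regressor list for one cohort and one equation.

    ``equation`` is "outcome" (log BLL) or "selection" (participation probit).
    The selection spec always contains ``window_days``; the outcome spec
    never does.
    """

    cohort: str  # "child" | "adult"
    equation: str  # "outcome" | "selection"
    columns: tuple

    @staticmethod
    def child_outcome() -> "ModelSpec":
        cols = ("const",) + GEO_COLUMNS + CHILD_AGE_COLUMNS + CHILD_X_COLUMNS
        return ModelSpec("child", "outcome", cols)

    @staticmethod
    def child_selection() -> "ModelSpec":
        cols = ("const",) + GEO_COLUMNS + CHILD_AGE_COLUMNS + CHILD_X_COLUMNS + ("window_days",)
        return ModelSpec("child", "selection", cols)

    @staticmethod
    def adult_outcome() -> "ModelSpec":
        cols = ("const",) + GEO_COLUMNS + ADULT_AGE_COLUMNS + ADULT_X_COLUMNS
        return ModelSpec("adult", "outcome", cols)

    @staticmethod
    def adult_selection() -> "ModelSpec":
        cols = ("const",) + GEO_COLUMNS + ADULT_AGE_COLUMNS + ADULT_X_COLUMNS + ("window_days",)
        return ModelSpec("adult", "selection", cols)

    @staticmethod
    def for_cohort(cohort: str, equation: str) -> "ModelSpec":
        try:
            return getattr(ModelSpec, f"{cohort}_{equation}")()
        except AttributeError:
            raise ValueError(f"unknown spec {cohort}/{equation}") from None


@dataclass
class DesignMatrix:
    """A named regressor matrix with cluster ids, outcome and weights.

    Rows are indexed by individual id; column order is fixed by the spec and
    recorded in ``X.columns``.  ``clusters`` holds the standard enumeration
    area (SEA) id of each row -- the level at which robust standard errors
    and the bootstrap cluster.
    """

    X: pd.DataFrame
    y: Optional[pd.Series]
    clusters: pd.Series
    cohort: str
    equation: str
    weights: Optional[pd.Series] = None

    @property
    def n_obs(self) -> int:
        return len(self.X)

    @property
    def columns(self) -> list:
        return list(self.X.columns)

    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)


def featurize(records: pd.DataFrame) -> pd.DataFrame:
    """Append derived feature columns (geo, age, dummies, logs) to raw records.

    Expects the merged individual x household table of the survey schema.
    Location dummies use "urban" as the base category; records whose mother
    is absent must already carry ``mother_education_grades`` of zero (the
    schema invariant) -- it is re-checked here.
    """
    df = records.copy()
    geo = compute_geo_features(df["x_km"], df["y_km"], df["altitude_m"])
    df["distance_km"] = geo.distance_km
    df["log_distance"] = geo.log_distance
    df["direction"] = geo.direction_rad
    df["direction_sq"] = geo.direction_sq
    df["altitude"] = geo.altitude_m

    ages = compute_age_features(df["age_years"], df.get("age_months"))
    df["is_under2"] = ages.is_under2
    df["mage"] = ages.mage
    df["mage_sq"] = ages.mage_sq
    df["age_linear"] = ages.age_linear

    unknown = set(df["location_class"].unique()) - set(LOCATION_CLASSES)
    if unknown:
        raise SchemaError(f"unknown location class(es): {sorted(unknown)}")
    for cls in LOCATION_DUMMIES:
        df[cls] = (df["location_class"] == cls).astype(float)

    df["log_pce"] = np.log(df["per_capita_expenditure"].astype(float))
    if "mother_education_grades" in df:
        df["mother_education"] = df["mother_education_grades"].astype(float)
        absent = df.get("mother_absent")
        if absent is not None:
            bad = (np.asarray(absent, dtype=float) == 1) & (df["mother_education"] != 0)
            if bad.any():
                raise SchemaError(
                    "mother_education_grades must be zero when mother_absent = 1"
                )
    if "own_education_grades" in df:
        df["own_education"] = df["own_education_grades"].astype(float)
    df["const"] = 1.0
    return df


def build_design(records: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Assemble the design matrix of ``spec`` from survey records.

    For an outcome spec the response is log(bll_ugdl) and every row must
    carry an observed BLL (fit on participants; pass records without the
    ``bll_ugdl`` column to build a prediction-only design).  For a selection
    spec the response is the participation flag over all rows.

    Raises :class:`MissingCovariateError` if any spec column is absent or
    contains missing values.
    """
    df = featurize(records)
    missing_cols = [c for c in spec.columns if c not in df.columns]
    if missing_cols:
        raise MissingCovariateError(f"missing covariate column(s): {missing_cols}")
    X = df[list(spec.columns)].astype(float)
    if X.isna().any().any():
        bad = sorted(X.columns[X.isna().any()])
        raise MissingCovariateError(f"missing values in covariate(s): {bad}")

    y: Optional[pd.Series] = None
    if spec.equation == "outcome":
        if "bll_ugdl" in df.columns:
            bll = df["bll_ugdl"].astype(float)
            if bll.isna().any():
                raise MissingCovariateError(
                    "bll_ugdl missing for some rows of an outcome design; "
                    "restrict to participants or drop the column for prediction"
                )
            y = pd.Series(np.log(bll.to_numpy()), index=df.index, name="log_bll")
    elif spec.equation == "selection":
        if "participated" not in df.columns:
            raise MissingCovariateError("selection design requires a 'participated' column")
        y = df["participated"].astype(float).rename("participated")
    else:
        raise ValueError(f"unknown equation {spec.equation!r}")

    weights = df["sampling_weight"].astype(float) if "sampling_weight" in df else None
    return DesignMatrix(
        X=X,
        y=y,
        clusters=df["sea_id"],
        cohort=spec.cohort,
        equation=spec.equation,
        weights=weights,
    )
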