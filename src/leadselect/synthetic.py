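"""Synthetic survey generator for the selection-corrected exposure pipeline.

The real survey data are not publicly available, so every downstream stage
is exercised on synthetic data carrying the same statistical structure:

* a two-stage cluster sample -- standard enumeration areas (SEAs) drawn from
  a census frame, then a fixed number of households per sampled SEA, with
  inverse-inclusion-probability sampling weights;
* SEA centroids scattered around the mine waste dump at the origin (uniform
  bearing, log-normal radial distance), so that distance and direction have
  realistic spreads;
* covariates drawn independently per record, matched to target means/SDs;
* latent log blood lead levels from the log-linear exposure equation, and
  voluntary blood-sampling participation from the probit selection equation,
  with bivariate-normal errors correlated at ``rho`` -- the canonical
  selection-on-unobservables data-generating process;
* observed BLLs masked for non-participants; adolescents (11-18 y) are
  never offered participation, mirroring a survey design that prioritised
  young children and their guardians.

A single master seed drives one deterministic stream, so any run is exactly
reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import reference
from .errors import SchemaError
from .features import LOCATION_CLASSES, featurize

COHORT_CHILD = "child_0_10"
COHORT_ADOLESCENT = "adolescent_11_18"
COHORT_ADULT = "adult_19plus"

HOUSEHOLD_COLUMNS = [
    "household_id",
    "sea_id",
    "x_km",
    "y_km",
    "altitude_m",
    "location_class",
    "household_size",
    "dependency_ratio",
    "per_capita_expenditure",
    "female_head",
    "window_days",
    "sampling_weight",
]

INDIVIDUAL_COLUMNS = [
    "individual_id",
    "household_id",
    "cohort",
    "age_years",
    "age_months",
    "female",
    "mother_education_grades",
    "mother_absent",
    "own_education_grades",
    "married",
    "residence_years",
    "participated",
    "bll_ugdl",
]


@dataclass(frozen=True)
class SamplingConfig:
    """Two-stage sampling design parameters.

    ``sea_size_distribution`` gives (mean, sd) of the number of frame
    households per SEA; weights are (frame SEAs / sampled SEAs) x
    (SEA frame households / sampled households).
    """

    n_seas_frame: int = 384
    n_seas_sampled: int = 40
    households_per_sea: int = 25
    sea_size_distribution: Tuple[float, float] = (128.0, 40.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_seas_sampled > self.n_seas_frame:
            raise ValueError("cannot sample more SEAs than the frame contains")
        if self.households_per_sea < 1:
            raise ValueError("households_per_sea must be >= 1")


@dataclass(frozen=True)
class TruthParams:
    """Data-generating coefficients for the outcome and selection equations.

    ``beta_*`` parameterise the log-linear BLL equations, ``delta_*`` the
    probit participation equations (keys are design-matrix column names).
    ``sigma_eps`` is the SD of the outcome error; ``rho`` the correlation
    between outcome and selection errors (selection on unobservables; zero
    means participation is ignorable given covariates).
    """

    beta_child: dict = field(default_factory=lambda: dict(reference.CHILD_OUTCOME))
    beta_adult: dict = field(default_factory=lambda: dict(reference.ADULT_OUTCOME))
    delta_child: dict = field(default_factory=lambda: dict(reference.CHILD_SELECTION))
    delta_adult: dict = field(default_factory=lambda: dict(reference.ADULT_SELECTION))
    sigma_eps: float = 0.40
    rho: float = 0.0

    def __post_init__(self):
        if not self.sigma_eps > 0:
            raise ValueError("sigma_eps must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly in (-1, 1)")


@dataclass(frozen=True)
class CovariateTargets:
    """Target moments for covariate generation (per-cohort means/SDs).

    Defaults reproduce the published summary moments of the non-participant
    group, which is the larger and less selected of the two.  Binary
    covariates are Bernoulli; bounded continuous covariates are truncated
    normals; expenditure and radial distance are log-normal.
    """

    distance_mean: float = 6.07
    distance_sd: float = 5.31
    altitude_mean: float = 1185.0
    altitude_sd: float = 9.0
    household_size_mean: float = 6.98
    household_size_sd: float = 2.72
    dependency_mean: float = 0.47
    dependency_sd: float = 0.20
    pce_mean: float = 505.0
    pce_sd: float = 777.0
    female_head_p: float = 0.22
    window_mean: float = 9.26
    window_sd: float = 8.36
    location_probs: Tuple[float, ...] = (0.36, 0.20, 0.19, 0.25)  # order of LOCATION_CLASSES
    child_female_p: float = 0.49
    mother_education_mean: float = 6.39
    mother_education_sd: float = 4.77
    mother_absent_p: float = 0.19
    adult_female_p: float = 0.51
    adult_education_mean: float = 9.86
    adult_education_sd: float = 4.06
    married_p: float = 0.51
    adult_age_mean: float = 35.6
    adult_age_sd: float = 14.8
    residence_mean: float = 21.7
    residence_sd: float = 13.8
    # Expected roster members per household by cohort (Poisson rates); the
    # adult count gets +1 so every household has at least one adult.
    child_rate: float = 1.69
    adolescent_rate: float = 1.13
    adult_rate: float = 1.65

    def __post_init__(self):
        for name in (
            "distance_sd",
            "altitude_sd",
            "household_size_sd",
            "dependency_sd",
            "pce_sd",
            "window_sd",
            "mother_education_sd",
            "adult_education_sd",
            "adult_age_sd",
            "residence_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "female_head_p",
            "mother_absent_p",
            "child_female_p",
            "adult_female_p",
            "married_p",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(self.location_probs) != len(LOCATION_CLASSES) or not math.isclose(
            sum(self.location_probs), 1.0, abs_tol=0.02
        ):
            raise ValueError("location_probs must give one share per class summing to 1")


def _lognormal_params(mean: float, sd: float) -> Tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _index(df: pd.DataFrame, coefs: dict) -> np.ndarray:
    """Linear index sum_c coefs[c] * df[c] over the coefficient keys."""
    out = np.zeros(len(df))
    for name, value in coefs.items():
        out += value * df[name].to_numpy(dtype=float)
    return out


def generate_survey(
    sampling: Optional[SamplingConfig] = None,
    truth: Optional[TruthParams] = None,
    targets: Optional[CovariateTargets] = None,
    *,
    cohorts: Sequence[str] = (COHORT_CHILD, COHORT_ADOLESCENT, COHORT_ADULT),
    include_latent: bool = False,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one synthetic survey: (households, individuals) DataFrames.

    ``cohorts`` restricts the roster (useful for single-cohort Monte-Carlo
    studies).  With ``include_latent`` the individuals table additionally
    carries ``latent_log_bll`` and ``eps`` (the outcome error) for oracle
    checks; these columns are never written to disk.

    An explicit ``seed`` overrides ``sampling.seed``.
    """
    sampling = sampling or SamplingConfig()
    if seed is not None:
        sampling = dataclasses.replace(sampling, seed=int(seed))
    truth = truth or TruthParams()
    targets = targets or CovariateTargets()
    rng = np.random.default_rng(sampling.seed)

    # --- stage 1: SEAs -----------------------------------------------------
    size_mean, size_sd = sampling.sea_size_distribution
    frame_sizes = np.maximum(
        np.rint(rng.normal(size_mean, size_sd, sampling.n_seas_frame)),
        sampling.households_per_sea,
    ).astype(int)
    sampled = np.sort(
        rng.choice(sampling.n_seas_frame, size=sampling.n_seas_sampled, replace=False)
    )
    sea_weight = (
        (sampling.n_seas_frame / sampling.n_seas_sampled)
        * frame_sizes[sampled]
        / sampling.households_per_sea
    )
    bearing = rng.uniform(0.0, 2.0 * math.pi, sampling.n_seas_sampled)
    mu_d, sigma_d = _lognormal_params(targets.distance_mean, targets.distance_sd)
    radius = rng.lognormal(mu_d, sigma_d, sampling.n_seas_sampled)
    sea_x = radius * np.cos(bearing)
    sea_y = radius * np.sin(bearing)
    sea_alt = rng.normal(targets.altitude_mean, targets.altitude_sd * 0.85, sampling.n_seas_sampled)

    # --- stage 2: households ----------------------------------------------
    m = sampling.households_per_sea
    n_h = sampling.n_seas_sampled * m
    sea_idx = np.repeat(np.arange(sampling.n_seas_sampled), m)
    hh = pd.DataFrame(
        {
            "household_id": np.arange(n_h),
            "sea_id": sampled[sea_idx],
            "x_km": sea_x[sea_idx] + rng.normal(0.0, 0.3, n_h),
            "y_km": sea_y[sea_idx] + rng.normal(0.0, 0.3, n_h),
            "altitude_m": np.round(sea_alt[sea_idx] + rng.normal(0.0, 3.0, n_h), 1),
            "location_class": rng.choice(
                LOCATION_CLASSES, size=n_h, p=np.asarray(targets.location_probs) / sum(targets.location_probs)
            ),
            "household_size": np.clip(
                np.rint(rng.normal(targets.household_size_mean, targets.household_size_sd, n_h)),
                1,
                20,
            ).astype(int),
            "dependency_ratio": np.round(
                np.clip(rng.normal(targets.dependency_mean, targets.dependency_sd, n_h), 0.0, 1.0), 4
            ),
            "per_capita_expenditure": np.round(
                rng.lognormal(*_lognormal_params(targets.pce_mean, targets.pce_sd), n_h), 2
            ),
            "female_head": (rng.random(n_h) < targets.female_head_p).astype(int),
            "window_days": np.clip(
                np.rint(rng.normal(targets.window_mean, targets.window_sd, n_h)), 3, 31
            ).astype(int),
            "sampling_weight": np.round(sea_weight[sea_idx], 4),
        }
    )

    # --- roster ------------------------------------------------------------
    n_child = rng.poisson(targets.child_rate, n_h) if COHORT_CHILD in cohorts else np.zeros(n_h, int)
    n_adol = (
        rng.poisson(targets.adolescent_rate, n_h) if COHORT_ADOLESCENT in cohorts else np.zeros(n_h, int)
    )
    n_adult = (
        1 + rng.poisson(targets.adult_rate, n_h) if COHORT_ADULT in cohorts else np.zeros(n_h, int)
    )

    blocks = []
    hh_ids = hh["household_id"].to_numpy()

    nc = int(n_child.sum())
    if nc:
        months = rng.integers(0, 11 * 12, nc)
        under2 = months < 24
        age_years = np.where(under2, months / 12.0, months // 12).astype(float)
        blocks.append(
            pd.DataFrame(
                {
                    "household_id": np.repeat(hh_ids, n_child),
                    "cohort": COHORT_CHILD,
                    "age_years": age_years,
                    "age_months": np.where(under2, months.astype(float), np.nan),
                    "female": (rng.random(nc) < targets.child_female_p).astype(int),
                    "mother_absent": (rng.random(nc) < targets.mother_absent_p).astype(int),
                    "mother_education_grades": np.clip(
                        np.rint(rng.normal(targets.mother_education_mean, targets.mother_education_sd, nc)),
                        0,
                        17,
                    ),
                }
            )
        )

    na = int(n_adol.sum())
    if na:
        blocks.append(
            pd.DataFrame(
                {
                    "household_id": np.repeat(hh_ids, n_adol),
                    "cohort": COHORT_ADOLESCENT,
                    "age_years": rng.integers(11, 19, na).astype(float),
                    "age_months": np.nan,
                    "female": (rng.random(na) < targets.child_female_p).astype(int),
                    "mother_absent": (rng.random(na) < targets.mother_absent_p).astype(int),
                    "mother_education_grades": np.clip(
                        np.rint(rng.normal(targets.mother_education_mean, targets.mother_education_sd, na)),
                        0,
                        17,
                    ),
                }
            )
        )

    nd = int(n_adult.sum())
    if nd:
        age = np.clip(np.rint(rng.normal(targets.adult_age_mean, targets.adult_age_sd, nd)), 19, 90)
        residence = np.minimum(
            age, np.clip(np.rint(rng.normal(targets.residence_mean, targets.residence_sd, nd)), 0, None)
        )
        blocks.append(
            pd.DataFrame(
                {
                    "household_id": np.repeat(hh_ids, n_adult),
                    "cohort": COHORT_ADULT,
                    "age_years": age.astype(float),
                    "age_months": np.nan,
                    "female": (rng.random(nd) < targets.adult_female_p).astype(int),
                    "own_education_grades": np.clip(
                        np.rint(rng.normal(targets.adult_education_mean, targets.adult_education_sd, nd)),
                        0,
                        17,
                    ),
                    "married": (rng.random(nd) < targets.married_p).astype(int),
                    "residence_years": residence.astype(float),
                }
            )
        )

    ind = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame(
        columns=INDIVIDUAL_COLUMNS[1:-2]
    )
    for col in ("mother_education_grades", "mother_absent", "own_education_grades", "married", "residence_years"):
        if col not in ind.columns:
            ind[col] = np.nan
    if len(ind):
        # Schema invariant: absent mother implies zero recorded education.
        ind.loc[ind["mother_absent"] == 1, "mother_education_grades"] = 0.0
    ind.insert(0, "individual_id", np.arange(len(ind)))

    # --- latent outcome and participation -----------------------------------
    n = len(ind)
    merged = ind.merge(hh, on="household_id", how="left", sort=False)
    feat = featurize(merged) if n else merged
    is_adult = merged["cohort"].to_numpy() == COHORT_ADULT if n else np.zeros(0, bool)

    out_index = np.zeros(n)
    sel_index = np.zeros(n)
    if n:
        child_rows = ~is_adult
        if child_rows.any():
            sub = feat.loc[child_rows]
            out_index[child_rows] = _index(sub, truth.beta_child)
            sel_index[child_rows] = _index(sub, truth.delta_child)
        if is_adult.any():
            sub = feat.loc[is_adult]
            out_index[is_adult] = _index(sub, truth.beta_adult)
            sel_index[is_adult] = _index(sub, truth.delta_adult)

    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    eps = truth.sigma_eps * z1
    v = truth.rho * z1 + math.sqrt(1.0 - truth.rho**2) * z2
    latent = out_index + eps

    offered = merged["cohort"].to_numpy() != COHORT_ADOLESCENT if n else np.zeros(0, bool)
    participated = (offered & (sel_index + v > 0)).astype(int)
    bll = np.where(participated == 1, np.round(np.exp(latent), 4), np.nan)

    ind["participated"] = participated
    ind["bll_ugdl"] = bll
    if include_latent:
        ind["latent_log_bll"] = latent
        ind["eps"] = eps
    ind = ind[INDIVIDUAL_COLUMNS + (["latent_log_bll", "eps"] if include_latent else [])]
    return hh[HOUSEHOLD_COLUMNS], ind


def survey_table(households: pd.DataFrame, individuals: pd.DataFrame) -> pd.DataFrame:
    """Individual-level table with household covariates merged in."""
    return individuals.merge(households, on="household_id", how="left", sort=False)


def validate_survey(households: pd.DataFrame, individuals: pd.DataFrame) -> None:
    """Check the schema and record invariants; raise :class:`SchemaError`."""
    missing = [c for c in HOUSEHOLD_COLUMNS if c not in households.columns]
    if missing:
        raise SchemaError(f"households table missing column(s): {missing}")
    missing = [c for c in INDIVIDUAL_COLUMNS if c not in individuals.columns]
    if missing:
        raise SchemaError(f"individuals table missing column(s): {missing}")
    if len(households):
        if (households["sampling_weight"] <= 0).any():
            raise SchemaError("sampling weights must be positive")
        w = households["window_days"]
        if ((w < 3) | (w > 31)).any():
            raise SchemaError("window_days must lie in [3, 31]")
        unknown = set(households["location_class"].unique()) - set(LOCATION_CLASSES)
        if unknown:
            raise SchemaError(f"unknown location class(es): {sorted(unknown)}")
    if len(individuals):
        has_bll = individuals["bll_ugdl"].notna()
        part = individuals["participated"].astype(int) == 1
        if (has_bll & ~part).any():
            raise SchemaError("bll_ugdl present for a non-participant")
        if (part & ~has_bll).any():
            raise SchemaError("bll_ugdl missing for a participant")
        absent = individuals["mother_absent"] == 1
        educ = individuals["mother_education_grades"].fillna(0.0)
        if (absent & (educ != 0)).any():
            raise SchemaError("mother_education_grades must be zero when mother_absent = 1")
        orphan = ~individuals["household_id"].isin(households["household_id"])
        if orphan.any():
            raise SchemaError("individual references an unknown household_id")


def write_survey(households: pd.DataFrame, individuals: pd.DataFrame, path) -> None:
    """Write households.csv / individuals.csv under ``path`` (a directory)."""
    validate_survey(households, individuals)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    households[HOUSEHOLD_COLUMNS].to_csv(path / "households.csv", index=False)
    individuals[INDIVIDUAL_COLUMNS].to_csv(path / "individuals.csv", index=False)


def read_survey(path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a survey directory written by :func:`write_survey`."""
    path = Path(path)
    try:
        # round_trip parsing keeps read(write(x)) byte-identical
        households = pd.read_csv(path / "households.csv", float_precision="round_trip")
        individuals = pd.read_csv(path / "individuals.csv", float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"cannot read survey at {path}: {exc}") from exc
    validate_survey(households, individuals)
    return households, individuals
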