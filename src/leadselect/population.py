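"""Population-wide prediction and survey-weighted aggregation.

Once the cohort equations are fitted on participants, blood lead levels are
predicted for *every* representative individual -- participants,
non-participants, and adolescents (who are scored with the child equation,
extrapolating the negative age trend through 18 years).  Sampling weights
from the two-stage design enter here, and only here: weighted means,
weighted percentiles by linear interpolation of the weighted empirical CDF,
and weighted shares of the clinically meaningful bands (< 5 ug/dL, the
reference level; 5-45 ug/dL; > 45 ug/dL, the chelation-therapy threshold).

Confidence intervals resample standard enumeration areas (SEAs) with
replacement -- a cluster bootstrap at the primary sampling unit -- and use
the percentile method.

Retransformation from the log scale is naive exponentiation by default,
with Duan smearing and the lognormal sigma^2/2 correction selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import SchemaError, UndefinedStatisticError
from .estimation import FitResult
from .features import ModelSpec, build_design
from .synthetic import COHORT_ADOLESCENT, COHORT_ADULT, COHORT_CHILD

RETRANSFORMS = ("naive", "smearing", "sigma_half")

#: Table-style group labels, in display order.
STANDARD_GROUPS = ("all", "male", "female", "age_0_5", "age_6_10", "age_11_18", "age_19plus")


@dataclass(frozen=True)
class DerivedQuantities:
    """Closed-form scalars implied by the fitted coefficients.

    * ``child_peak_age_months`` -- vertex -phi1/(2 phi2) of the under-2
      quadratic: the age at which child BLL peaks.
    * ``child/adult_decline_pct_per_year`` -- 100 (1 - exp(coef)) for the
      linear age coefficients: the proportional BLL decline per year.
    * ``*_direction_vertex_rad`` -- -b_dir1/(2 b_dir2): the bearing angle of
      minimum exposure (between the WNW and ESE contamination lobes).
    """

    child_peak_age_months: float
    child_decline_pct_per_year: float
    adult_decline_pct_per_year: float
    child_direction_vertex_rad: float
    adult_direction_vertex_rad: float


def _params_of(fit) -> pd.Series:
    params = getattr(fit, "params", fit)
    return pd.Series(dict(params)) if not isinstance(params, pd.Series) else params


def derived_quantities(fit_child, fit_adult) -> DerivedQuantities:
    """Compute the derived scalar summaries from two fitted equations.

    Accepts :class:`FitResult` objects or plain coefficient mappings.
    Raises :class:`UndefinedStatisticError` when a vertex denominator is 0.
    """
    pc = _params_of(fit_child)
    pa = _params_of(fit_adult)
    if pc["mage_sq"] == 0:
        raise UndefinedStatisticError("child age quadratic is degenerate (mage_sq = 0): no peak")
    for p, label in ((pc, "child"), (pa, "adult")):
        if p["direction_sq"] == 0:
            raise UndefinedStatisticError(
                f"{label} direction response is linear (direction_sq = 0): no vertex"
            )
    return DerivedQuantities(
        child_peak_age_months=-pc["mage"] / (2.0 * pc["mage_sq"]),
        child_decline_pct_per_year=100.0 * (1.0 - math.exp(pc["age_linear"])),
        adult_decline_pct_per_year=100.0 * (1.0 - math.exp(pa["age_years"])),
        child_direction_vertex_rad=-pc["direction"] / (2.0 * pc["direction_sq"]),
        adult_direction_vertex_rad=-pa["direction"] / (2.0 * pa["direction_sq"]),
    )


def _retransform_factor(fit, method: str) -> float:
    if method == "naive":
        return 1.0
    if method == "smearing":
        resid = getattr(fit, "resid", None)
        if resid is None:
            raise ValueError("smearing retransformation needs fit residuals")
        return float(np.mean(np.exp(resid)))
    if method == "sigma_half":
        sigma2 = getattr(fit, "sigma2", None)
        if sigma2 is None or sigma2 < 0:
            raise ValueError("sigma_half retransformation needs a nonnegative sigma2")
        return math.exp(sigma2 / 2.0)
    raise ValueError(f"unknown retransformation {method!r}; choose from {RETRANSFORMS}")


def _linear_index(fit, records: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """X @ beta over the spec columns; an 'imr' coefficient, if present in a
    selection-corrected fit, is excluded (population prediction sets the
    selection hazard term to zero)."""
    design = build_design(records.drop(columns=["bll_ugdl"], errors="ignore"), spec)
    params = _params_of(fit)
    params = params.drop("imr", errors="ignore")
    missing = [c for c in params.index if c not in design.X.columns]
    if missing:
        raise ValueError(f"fit has coefficients without design columns: {missing}")
    return design.X[list(params.index)].to_numpy(dtype=float) @ params.to_numpy(dtype=float)


def predict_bll(
    fit_child,
    fit_adult,
    records: pd.DataFrame,
    retransform: str = "naive",
) -> pd.DataFrame:
    """Predicted BLLs for every record (the PredictionSet table).

    Cohort routing: ages 0-18 (child and adolescent cohorts) use the child
    equation; 19+ the adult equation.  Returns one row per input record with
    the predicted log BLL, the retransformed BLL in ug/dL, and the columns
    needed downstream (weight, SEA, sex, age).
    """
    known = {COHORT_CHILD, COHORT_ADOLESCENT, COHORT_ADULT}
    unknown = set(records["cohort"].unique()) - known
    if unknown:
        raise SchemaError(f"unknown cohort(s): {sorted(unknown)}")
    is_adult = records["cohort"] == COHORT_ADULT

    log_pred = np.full(len(records), np.nan)
    if (~is_adult).any():
        log_pred[~is_adult.to_numpy()] = _linear_index(
            fit_child, records.loc[~is_adult], ModelSpec.child_outcome()
        )
    if is_adult.any():
        log_pred[is_adult.to_numpy()] = _linear_index(
            fit_adult, records.loc[is_adult], ModelSpec.adult_outcome()
        )
    factor = np.where(
        is_adult.to_numpy(),
        _retransform_factor(fit_adult, retransform),
        _retransform_factor(fit_child, retransform),
    )
    bll = factor * np.exp(log_pred)
    out = pd.DataFrame(
        {
            "individual_id": records["individual_id"].to_numpy(),
            "cohort": records["cohort"].to_numpy(),
            "log_bll_pred": log_pred,
            "bll_pred": bll,
            "retransform": retransform,
            "weight": records["sampling_weight"].to_numpy(dtype=float),
            "sea_id": records["sea_id"].to_numpy(),
            "female": records["female"].to_numpy(),
            "age_years": records["age_years"].to_numpy(dtype=float),
            "age_months": records["age_months"].to_numpy(dtype=float)
            if "age_months" in records
            else np.nan,
        }
    )
    if (out["weight"] <= 0).any():
        raise SchemaError("sampling weights must be positive")
    return out


def weighted_quantile(values, q, weights) -> np.ndarray:
    """Weighted quantiles by linear interpolation of the weighted empirical CDF.

    The CDF is evaluated at the midpoints (cumw - w/2) / W of each sorted
    observation's weight mass, and interpolated linearly between them.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cdf = (np.cumsum(w) - 0.5 * w) / w.sum()
    return np.interp(q, cdf, v)


def band_shares(values, weights, thresholds: Tuple[float, float] = (5.0, 45.0)) -> dict:
    """Weighted percentage shares of the bands < lo, [lo, hi], > hi.

    The middle band is closed on both ends, matching the conventional
    "5-45 ug/dL" labelling.  Shares always sum to 100.
    """
    lo, hi = sorted(thresholds)
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    return {
        "below": 100.0 * w[v < lo].sum() / total,
        "within": 100.0 * w[(v >= lo) & (v <= hi)].sum() / total,
        "above": 100.0 * w[v > hi].sum() / total,
    }


def _group_masks(preds: pd.DataFrame, groups: Sequence[str]):
    age = preds["age_years"].to_numpy(dtype=float)
    female = preds["female"].to_numpy(dtype=float)
    defs = {
        "all": np.ones(len(preds), dtype=bool),
        "male": female == 0,
        "female": female == 1,
        "age_0_5": age < 6,
        "age_6_10": (age >= 6) & (age < 11),
        "age_11_18": (age >= 11) & (age < 19),
        "age_19plus": age >= 19,
    }
    for g in groups:
        if g not in defs:
            raise ValueError(f"unknown group {g!r}; known: {sorted(defs)}")
        yield g, defs[g]


def _cluster_bootstrap_mean_ci(
    values: np.ndarray,
    weights: np.ndarray,
    clusters: np.ndarray,
    reps: int,
    rng: np.random.Generator,
    alpha: float = 0.05,
) -> Tuple[float, float]:
    """Percentile CI for the weighted mean, resampling clusters with replacement."""
    codes = pd.factorize(clusters)[0]
    G = codes.max() + 1
    sw = np.zeros(G)
    sv = np.zeros(G)
    np.add.at(sw, codes, weights)
    np.add.at(sv, codes, weights * values)
    draws = rng.integers(0, G, size=(reps, G))
    means = sv[draws].sum(axis=1) / sw[draws].sum(axis=1)
    lo, hi = np.quantile(means, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def aggregate(
    preds: pd.DataFrame,
    groups: Sequence[str] = STANDARD_GROUPS,
    thresholds: Tuple[float, float] = (5.0, 45.0),
    ci: str = "none",
    bootstrap_reps: int = 2000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Survey-weighted summaries per subgroup (the Table-6-style panel).

    One row per group: weighted mean (with cluster-bootstrap 95% CI when
    ``ci='cluster_bootstrap'``), weighted quartiles, weighted band shares
    and unweighted n.  Empty groups are omitted.
    """
    if ci not in ("none", "cluster_bootstrap"):
        raise ValueError("ci must be 'none' or 'cluster_bootstrap'")
    rng = np.random.default_rng(seed)
    rows = []
    for label, mask in _group_masks(preds, groups):
        sub = preds.loc[mask]
        if not len(sub):
            continue
        v = sub["bll_pred"].to_numpy(dtype=float)
        w = sub["weight"].to_numpy(dtype=float)
        mean = float(np.average(v, weights=w))
        if ci == "cluster_bootstrap":
            lo, hi = _cluster_bootstrap_mean_ci(
                v, w, sub["sea_id"].to_numpy(), bootstrap_reps, rng
            )
        else:
            lo = hi = float("nan")
        q25, q50, q75 = weighted_quantile(v, [0.25, 0.5, 0.75], w)
        bands = band_shares(v, w, thresholds)
        rows.append(
            {
                "group": label,
                "n": int(len(sub)),
                "weighted_mean": mean,
                "ci_low": lo,
                "ci_high": hi,
                "p25": float(q25),
                "p50": float(q50),
                "p75": float(q75),
                "pct_below_lo": bands["below"],
                "pct_within": bands["within"],
                "pct_above_hi": bands["above"],
            }
        )
    return pd.DataFrame(rows)


def percent_reduction(mean_a: float, mean_b: float) -> float:
    """Percentage by which ``mean_a`` falls below ``mean_b``: 100 (b - a) / b."""
    if not mean_b > 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (mean_b - mean_a) / mean_b


def population_counts(proportion_above: float, population_totals: Iterable[int]) -> list:
    """Residents above the reference level: proportion x total, to the nearest hundred."""
    if not 0.0 <= proportion_above <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    counts = []
    for total in population_totals:
        if int(total) <= 0:
            raise ValueError("population totals must be positive")
        counts.append(int(round(proportion_above * int(total) / 100.0)) * 100)
    return counts


def age_profile(
    preds: pd.DataFrame,
    ci: str = "none",
    bootstrap_reps: int = 2000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Weighted mean BLL by age: months 0-23 individually, then whole years.

    The machinery behind the BLL-age profile figure; with
    ``ci='cluster_bootstrap'`` each point gets a percentile 95% CI.
    """
    rng = np.random.default_rng(seed)
    age = preds["age_years"].to_numpy(dtype=float)
    months = preds["age_months"].to_numpy(dtype=float)
    under2 = age < 2
    key_unit = np.where(under2, "months", "years")
    key_age = np.where(under2, months, np.floor(age))
    rows = []
    frame = preds.assign(_unit=key_unit, _age=key_age)
    for (unit, a), sub in frame.groupby(["_unit", "_age"], sort=False):
        v = sub["bll_pred"].to_numpy(dtype=float)
        w = sub["weight"].to_numpy(dtype=float)
        if ci == "cluster_bootstrap" and len(sub) > 1:
            lo, hi = _cluster_bootstrap_mean_ci(
                v, w, sub["sea_id"].to_numpy(), bootstrap_reps, rng
            )
        else:
            lo = hi = float("nan")
        rows.append(
            {
                "unit": unit,
                "age": float(a),
                "weighted_mean": float(np.average(v, weights=w)),
                "ci_low": lo,
                "ci_high": hi,
                "n": int(len(sub)),
            }
        )
    out = pd.DataFrame(rows)
    # "months" sorts before "years", so the under-2 profile comes first
    return out.sort_values(["unit", "age"], ignore_index=True)
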