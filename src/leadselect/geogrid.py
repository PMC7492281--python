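"""Gridded exposure surface over the district.

The district is covered by square cells (1 km x 1 km by default); each cell
centroid gets its own distance and direction to the mine waste dump, while
the remaining covariates are fixed at the means of the ward -- the official
inner-district division -- containing the cell.  Child predictions fix age
at the peak of the fitted age response (16 months by default); adult
predictions use the ward's local mean adult age.

Real ward boundaries and covariate means are not available, so a synthetic
district fixture (a square district with quadrant wards carrying the
generator's default covariate targets) is provided for tests and the demo
pipeline; the surface is reproducible in structure, not in real cell values.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from shapely import contains_xy as _contains_xy
from shapely.geometry import Polygon, box

from .errors import SchemaError
from .population import predict_bll
from .synthetic import COHORT_ADULT, COHORT_CHILD, CovariateTargets

#: Ward covariate columns required by predict_surface.
WARD_COVARIATE_COLUMNS = [
    "altitude_m",
    "location_class",
    "household_size",
    "dependency_ratio",
    "per_capita_expenditure",
    "female_head",
    "female",
    "mother_education_grades",
    "mother_absent",
    "own_education_grades",
    "married",
    "residence_years",
    "adult_mean_age",
]


def make_grid(district_polygon: Polygon, cell_km: float = 1.0) -> pd.DataFrame:
    """Square cells covering the polygon; centroid-in-polygon inclusion.

    Returns a DataFrame with ``row``, ``col`` (lattice indices), and
    centroid coordinates ``x_km``, ``y_km`` in the dump-at-origin frame,
    ordered row-major (rows south to north, columns west to east).
    """
    if district_polygon.is_empty or district_polygon.area == 0:
        raise ValueError("district polygon is empty or degenerate")
    minx, miny, maxx, maxy = district_polygon.bounds
    col0 = math.floor(minx / cell_km)
    row0 = math.floor(miny / cell_km)
    cols = np.arange(col0, math.ceil(maxx / cell_km))
    rows = np.arange(row0, math.ceil(maxy / cell_km))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    x = (cc.ravel() + 0.5) * cell_km
    y = (rr.ravel() + 0.5) * cell_km
    inside = _contains_xy(district_polygon, x, y)
    return pd.DataFrame(
        {
            "row": rr.ravel()[inside],
            "col": cc.ravel()[inside],
            "x_km": x[inside],
            "y_km": y[inside],
        }
    ).reset_index(drop=True)


def assign_wards(cells: pd.DataFrame, ward_polygons: Dict[object, Polygon]) -> pd.DataFrame:
    """Attach a ``ward_id`` column by centroid containment (first match wins)."""
    out = cells.copy()
    ward_id = np.full(len(out), None, dtype=object)
    x = out["x_km"].to_numpy()
    y = out["y_km"].to_numpy()
    for wid, poly in ward_polygons.items():
        hit = _contains_xy(poly, x, y) & pd.isna(ward_id)
        ward_id[hit] = wid
    out["ward_id"] = ward_id
    return out


def predict_surface(
    cells: pd.DataFrame,
    fit_child,
    fit_adult,
    ward_covariates: pd.DataFrame,
    child_age_months: float = 16.0,
    retransform: str = "naive",
) -> pd.DataFrame:
    """Fill the grid with predicted child and adult mean BLLs.

    ``cells`` must carry a ``ward_id`` column (see :func:`assign_wards`);
    ``ward_covariates`` is indexed by ward id with the columns of
    :data:`WARD_COVARIATE_COLUMNS`.  Children are scored at
    ``child_age_months`` (the fitted peak), adults at the ward mean age.
    """
    if "ward_id" not in cells.columns:
        raise SchemaError("cells need a 'ward_id' column; run assign_wards first")
    unmapped = cells["ward_id"].isna()
    if unmapped.any():
        raise SchemaError(f"{int(unmapped.sum())} cell(s) fall outside every ward")
    missing = [c for c in WARD_COVARIATE_COLUMNS if c not in ward_covariates.columns]
    if missing:
        raise SchemaError(f"ward covariates missing column(s): {missing}")
    unknown = set(cells["ward_id"]) - set(ward_covariates.index)
    if unknown:
        raise SchemaError(f"no covariates for ward(s): {sorted(map(str, unknown))}")

    wards = ward_covariates.loc[cells["ward_id"]].reset_index(drop=True)
    base = pd.DataFrame(
        {
            "individual_id": cells.index.to_numpy(),
            "x_km": cells["x_km"].to_numpy(),
            "y_km": cells["y_km"].to_numpy(),
            "altitude_m": wards["altitude_m"].to_numpy(),
            "location_class": wards["location_class"].to_numpy(),
            "household_size": wards["household_size"].to_numpy(),
            "dependency_ratio": wards["dependency_ratio"].to_numpy(),
            "per_capita_expenditure": wards["per_capita_expenditure"].to_numpy(),
            "female_head": wards["female_head"].to_numpy(),
            "female": wards["female"].to_numpy(),
            "sampling_weight": 1.0,
            "sea_id": 0,
        }
    )
    child_recs = base.assign(
        cohort=COHORT_CHILD,
        age_years=child_age_months / 12.0,
        age_months=float(child_age_months),
        mother_education_grades=wards["mother_education_grades"].to_numpy(),
        mother_absent=wards["mother_absent"].to_numpy(),
    )
    adult_recs = base.assign(
        cohort=COHORT_ADULT,
        age_years=wards["adult_mean_age"].to_numpy(dtype=float),
        age_months=np.nan,
        own_education_grades=wards["own_education_grades"].to_numpy(),
        married=wards["married"].to_numpy(),
        residence_years=wards["residence_years"].to_numpy(),
    )
    child_pred = predict_bll(fit_child, fit_adult, child_recs, retransform=retransform)
    adult_pred = predict_bll(fit_child, fit_adult, adult_recs, retransform=retransform)

    out = cells.copy()
    out["child_bll"] = child_pred["bll_pred"].to_numpy()
    out["adult_bll"] = adult_pred["bll_pred"].to_numpy()
    return out


def synthetic_district(
    half_width_km: float = 10.0,
    targets: Optional[CovariateTargets] = None,
) -> Tuple[Polygon, Dict[str, Polygon], pd.DataFrame]:
    """A synthetic square district with quadrant wards, for tests and demos.

    Returns (district polygon, ward polygons, ward covariate means).  The
    covariates are the generator's default targets, identical across wards;
    the adult mean age is set near the survey's local adult means.
    """
    t = targets or CovariateTargets()
    district = box(-half_width_km, -half_width_km, half_width_km, half_width_km)
    h = half_width_km
    wards = {
        "ward_ne": box(0, 0, h, h),
        "ward_nw": box(-h, 0, 0, h),
        "ward_sw": box(-h, -h, 0, 0),
        "ward_se": box(0, -h, h, 0),
    }
    cov = pd.DataFrame(
        {
            "altitude_m": t.altitude_mean,
            "location_class": "urban",
            "household_size": t.household_size_mean,
            "dependency_ratio": t.dependency_mean,
            "per_capita_expenditure": t.pce_mean,
            "female_head": t.female_head_p,
            "female": 0.5,
            "mother_education_grades": t.mother_education_mean,
            "mother_absent": 0.0,
            "own_education_grades": t.adult_education_mean,
            "married": t.married_p,
            "residence_years": t.residence_mean,
            "adult_mean_age": 36.0,
        },
        index=pd.Index(list(wards), name="ward_id"),
    )
    return district, wards, cov
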