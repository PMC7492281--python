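"""End-to-end pipeline: simulate -> fit -> predict -> aggregate -> map.

Each stage reads only the artifacts of earlier stages from the output
directory, writes its own artifacts at the end (so a failing stage leaves
prior outputs untouched), and logs its timing.  All data outputs are
deterministic functions of the config and seed; the run log is the only
file carrying wall-clock timings.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
import pandas as pd

from .config import PipelineConfig
from .errors import LeadSelectError
from .estimation import fit_heckman_two_step, fit_ols, participation_balance
from .features import ModelSpec, build_design
from .geogrid import assign_wards, make_grid, predict_surface, synthetic_district
from .population import (
    STANDARD_GROUPS,
    aggregate,
    derived_quantities,
    population_counts,
    predict_bll,
)
from .synthetic import (
    COHORT_ADULT,
    COHORT_CHILD,
    generate_survey,
    read_survey,
    survey_table,
    write_survey,
)

BALANCE_VARIABLES = [
    "distance_km",
    "direction",
    "altitude",
    "age_years",
    "female",
    "household_size",
    "dependency_ratio",
    "window_days",
]


class StageError(LeadSelectError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


def _meta(config: PipelineConfig) -> dict:
    return {"seed": config.seed, "config_hash": config.config_hash()}


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _fit_payload(fit) -> dict:
    r2 = getattr(fit, "r_squared", None)
    payload = {
        "params": {k: float(v) for k, v in fit.params.items()},
        "bse": {k: float(v) for k, v in fit.bse.items()},
        "pvalues": {k: float(v) for k, v in fit.pvalues.items()},
        "r_squared": None if r2 is None else float(r2),
        "n_obs": int(fit.n_obs),
        "n_clusters": int(fit.n_clusters),
    }
    ll = getattr(fit, "loglike", None)
    if ll is not None:
        payload["loglike"] = float(ll)
    return payload


class _Runner:
    def __init__(self, config: PipelineConfig, out_dir):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.log_lines = []
        self.fits = {}

    def _log(self, msg: str) -> None:
        self.log_lines.append(msg)

    def _stage(self, name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            self._log(f"{name}: FAILED ({exc})")
            self._write_log()
            raise StageError(name, exc) from exc
        self._log(f"{name}: ok ({time.perf_counter() - t0:.2f}s)")

    def _write_log(self) -> None:
        header = [
            f"seed={self.config.seed}",
            f"config_hash={self.config.config_hash()}",
        ]
        (self.out / "run.log").write_text("\n".join(header + self.log_lines) + "\n")

    # --- stages -----------------------------------------------------------

    def simulate(self) -> None:
        hh, ind = generate_survey(
            self.config.sampling, self.config.truth, self.config.targets
        )
        write_survey(hh, ind, self.out / "data")

    def _compute_fits(self) -> None:
        hh, ind = read_survey(self.out / "data")
        table = survey_table(hh, ind)
        opts = self.config.estimator
        for cohort, label in ((COHORT_CHILD, "child"), (COHORT_ADULT, "adult")):
            rows = table[table["cohort"] == cohort]
            part = rows[rows["participated"] == 1]
            ols = fit_ols(build_design(part, ModelSpec.for_cohort(label, "outcome")))
            heck = fit_heckman_two_step(
                build_design(part, ModelSpec.for_cohort(label, "outcome")),
                build_design(rows, ModelSpec.for_cohort(label, "selection")),
                tol=opts.tol,
                max_iter=opts.max_iter,
            )
            self.fits[label] = {"ols": ols, "heckman": heck}

    def _ensure_fits(self) -> None:
        # fitting is a deterministic function of the cached survey data, so
        # a stand-alone downstream stage simply refits in memory
        if not self.fits:
            self._compute_fits()

    def fit(self) -> None:
        self._compute_fits()
        hh, ind = read_survey(self.out / "data")
        table = survey_table(hh, ind)
        report = {"meta": _meta(self.config), "cohorts": {}}
        for label in ("child", "adult"):
            ols = self.fits[label]["ols"]
            heck = self.fits[label]["heckman"]
            report["cohorts"][label] = {
                "ols": _fit_payload(ols),
                "selection": _fit_payload(heck.first_stage),
                "heckman": _fit_payload(heck.second_stage),
                "selection_test_pvalue": heck.selection_test,
            }
        dq = derived_quantities(self.fits["child"]["ols"], self.fits["adult"]["ols"])
        report["derived"] = {
            "child_peak_age_months": dq.child_peak_age_months,
            "child_decline_pct_per_year": dq.child_decline_pct_per_year,
            "adult_decline_pct_per_year": dq.adult_decline_pct_per_year,
            "child_direction_vertex_rad": dq.child_direction_vertex_rad,
            "adult_direction_vertex_rad": dq.adult_direction_vertex_rad,
        }
        _dump_json(report, self.out / "fit_report.json")
        (self.out / "fit_report.txt").write_text(self._format_report(report))
        balance = participation_balance(
            build_balance_table(table), BALANCE_VARIABLES
        )
        balance.to_csv(self.out / "balance.csv")

    def _format_report(self, report: dict) -> str:
        lines = []
        for label, block in report["cohorts"].items():
            lines.append(f"== {label} equations ==")
            lines.append(
                f"{'regressor':<22}{'OLS BLL':>12}{'(P)':>8}{'selection':>12}{'(P)':>8}"
                f"{'Heckman BLL':>13}{'(P)':>8}"
            )
            names = list(block["heckman"]["params"])
            for name in names:

                def cell(vals, key):
                    c = vals["params"].get(key)
                    p = vals["pvalues"].get(key)
                    return (
                        (f"{c:>12.4g}", f"({p:.2f})".rjust(8))
                        if c is not None
                        else (" " * 12, " " * 8)
                    )

                o = cell(block["ols"], name)
                s = cell(block["selection"], name)
                h = cell(block["heckman"], name)
                lines.append(f"{name:<22}{o[0]}{o[1]}{s[0]}{s[1]}{h[0].rjust(13)}{h[1]}")
            lines.append(
                f"n(participants)={block['ols']['n_obs']}  n(all)={block['selection']['n_obs']}  "
                f"R2(OLS)={block['ols']['r_squared']:.3f}  "
                f"selection-test P={block['selection_test_pvalue']:.2f}"
            )
            lines.append("")
        d = report["derived"]
        lines.append(
            f"child BLL peak at {d['child_peak_age_months']:.1f} months; "
            f"decline {d['child_decline_pct_per_year']:.1f}%/yr (child), "
            f"{d['adult_decline_pct_per_year']:.1f}%/yr (adult)"
        )
        return "\n".join(lines) + "\n"

    def predict(self) -> None:
        self._ensure_fits()
        hh, ind = read_survey(self.out / "data")
        table = survey_table(hh, ind)
        opts = self.config.estimator
        key = "heckman" if opts.use_heckman else "ols"
        fit_child = (
            self.fits["child"][key].second_stage
            if key == "heckman"
            else self.fits["child"]["ols"]
        )
        fit_adult = (
            self.fits["adult"][key].second_stage
            if key == "heckman"
            else self.fits["adult"]["ols"]
        )
        preds = predict_bll(fit_child, fit_adult, table, retransform=opts.retransform)
        preds.to_csv(self.out / "predictions.csv", index=False)

    def aggregate(self) -> None:
        preds = pd.read_csv(self.out / "predictions.csv")
        opts = self.config.estimator
        summary = aggregate(
            preds,
            groups=STANDARD_GROUPS,
            thresholds=self.config.thresholds,
            ci="cluster_bootstrap",
            bootstrap_reps=opts.bootstrap_reps,
            seed=self.config.seed,
        )
        summary.to_csv(self.out / "summary.csv", index=False)
        all_row = summary.set_index("group").loc["all"]
        prop_above = (all_row["pct_within"] + all_row["pct_above_hi"]) / 100.0
        counts = population_counts(prop_above, self.config.population_totals)
        _dump_json(
            {
                "meta": _meta(self.config),
                "proportion_above_reference": prop_above,
                "population_totals": list(self.config.population_totals),
                "counts_above_reference": counts,
                "weighted_mean_bll_ugdl": float(all_row["weighted_mean"]),
            },
            self.out / "counts.json",
        )

    def map(self) -> None:
        if not self.config.grid.enabled:
            self._log("map: skipped (disabled)")
            return
        self._ensure_fits()
        g = self.config.grid
        district, wards, cov = synthetic_district(half_width_km=g.half_width_km)
        cells = assign_wards(make_grid(district, cell_km=g.cell_km), wards)
        surface = predict_surface(
            cells,
            self.fits["child"]["ols"],
            self.fits["adult"]["ols"],
            cov,
            child_age_months=g.child_age_months,
            retransform=self.config.estimator.retransform,
        )
        surface.to_csv(self.out / "grid.csv", index=False)


def build_balance_table(table: pd.DataFrame) -> pd.DataFrame:
    """Children's participant/non-participant diagnostic table with features."""
    from .features import featurize

    child = table[table["cohort"] == COHORT_CHILD]
    return featurize(child)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run every stage into ``out_dir`` and return the directory path.

    Raises :class:`StageError` naming the failing stage; completed stages'
    outputs are left in place.
    """
    runner = _Runner(config, out_dir)
    runner._stage("simulate", runner.simulate)
    runner._stage("fit", runner.fit)
    runner._stage("predict", runner.predict)
    runner._stage("aggregate", runner.aggregate)
    runner._stage("map", runner.map)
    _dump_json(
        {
            "meta": _meta(config),
            "outputs": sorted(
                p.name for p in runner.out.iterdir() if p.is_file() and p.name != "run.log"
            ),
        },
        runner.out / "manifest.json",
    )
    runner._write_log()
    return runner.out
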