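"""Pipeline configuration: plain-YAML, fully seeded, hashable.

A :class:`PipelineConfig` captures everything a run depends on -- sampling
design, data-generating truth, estimator options, thresholds and population
totals -- so that two runs with the same config and seed are byte-identical.
The config hash stamped into run outputs is the SHA-256 of the canonical
YAML serialisation.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .population import RETRANSFORMS
from .synthetic import CovariateTargets, SamplingConfig, TruthParams


@dataclass(frozen=True)
class EstimatorOptions:
    tol: float = 1e-8
    max_iter: int = 100
    retransform: str = "naive"
    bootstrap_reps: int = 2000
    use_heckman: bool = False  # predict from the selection-corrected fits instead of OLS

    def __post_init__(self):
        if self.retransform not in RETRANSFORMS:
            raise ValueError(f"retransform must be one of {RETRANSFORMS}")


@dataclass(frozen=True)
class GridOptions:
    enabled: bool = True
    cell_km: float = 1.0
    half_width_km: float = 10.0
    child_age_months: float = 16.0


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    truth: TruthParams = field(default_factory=TruthParams)
    targets: CovariateTargets = field(default_factory=CovariateTargets)
    estimator: EstimatorOptions = field(default_factory=EstimatorOptions)
    grid: GridOptions = field(default_factory=GridOptions)
    thresholds: Tuple[float, float] = (5.0, 45.0)
    population_totals: Tuple[int, ...] = (270389, 227551)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        d["population_totals"] = list(self.population_totals)
        d["sampling"]["sea_size_distribution"] = list(self.sampling.sea_size_distribution)
        d["targets"]["location_probs"] = list(self.targets.location_probs)
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(
            self, seed=int(seed), sampling=replace(self.sampling, seed=int(seed))
        )


def _build(cls, data: Optional[dict]):
    return cls(**data) if data else cls()


def load_config(path) -> PipelineConfig:
    """Read a YAML pipeline config; absent sections take their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sampling = dict(raw.get("sampling") or {})
    if "sea_size_distribution" in sampling:
        sampling["sea_size_distribution"] = tuple(sampling["sea_size_distribution"])
    targets = dict(raw.get("targets") or {})
    if "location_probs" in targets:
        targets["location_probs"] = tuple(targets["location_probs"])
    cfg = PipelineConfig(
        seed=int(raw.get("seed", 0)),
        sampling=_build(SamplingConfig, sampling),
        truth=_build(TruthParams, raw.get("truth")),
        targets=_build(CovariateTargets, targets),
        estimator=_build(EstimatorOptions, raw.get("estimator")),
        grid=_build(GridOptions, raw.get("grid")),
        thresholds=tuple(raw.get("thresholds", (5.0, 45.0))),
        population_totals=tuple(raw.get("population_totals", (270389, 227551))),
    )
    # the top-level seed drives the sampling stream unless overridden there
    if "seed" not in sampling:
        cfg = cfg.with_seed(cfg.seed)
    return cfg


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
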