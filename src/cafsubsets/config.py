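"""Pipeline configuration: one validated YAML file for every stage.

All numeric gates and model parameters live here so the visually drawn
flow/IF thresholds of the source assays become explicit, versioned
numbers.  Unknown keys are rejected at load time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .profiles import SchemaError

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass
class PipelineConfig:
    """Validated settings for all pipeline stages."""

    seed: int = 0
    out_dir: str = "results"

    # synthetic flow cohort
    flow_n_samples: int = 14
    flow_n_events: int = 800
    flow_downsample_n: int = 300
    flow_min_fibroblasts: int = 300

    # SOM metaclustering
    som_grid_rows: int = 10
    som_grid_cols: int = 10
    som_epochs: int = 20
    som_k_max: int = 15

    # multiplex IF
    mif_n_cells: int = 2000
    mif_ruleset: str = "without_CD90"

    # scRNA
    scrna_cells_per_group: int = 150
    scrna_n_genes: int = 200
    de_fdr: float = 0.05
    de_top_n: int = 50

    # survival
    surv_n_patients: int = 163
    surv_hazard_ratio: float = 2.0
    surv_censoring_rate: float = 0.2
    surv_minprop: float = 0.1

    def __post_init__(self) -> None:
        if self.mif_ruleset not in ("without_CD90", "with_CD90"):
            raise SchemaError(f"unknown mif_ruleset {self.mif_ruleset!r}")
        if not (0 < self.surv_minprop < 0.5):
            raise SchemaError("surv_minprop must be in (0, 0.5)")
        if not (0 <= self.surv_censoring_rate < 1):
            raise SchemaError("surv_censoring_rate must be in [0, 1)")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config, rejecting unknown keys; overrides win."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise SchemaError("config file must contain a mapping")
            data.update(loaded)
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of a config, recorded in run manifests."""
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
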