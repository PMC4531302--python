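"""Pipeline configuration: one auditable place for every analysis constant.

Defaults mirror the conventional single-subject resting-state analysis the
package implements: 30 ICA components, 6 mm cubic ROIs, r > 0.35 graph
threshold, z > 2.3 cluster criterion, 4 mm smoothing FWHM, 100 s high-pass
sigma.  The resolved configuration (and its hash) is echoed into every
output manifest.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # paths
    cohort_dir: str = "cohort"
    output_dir: str = "out"
    node_table: str = ""         # optional CSV of literature coordinates
    # analysis parameters
    n_components: int = 30
    edge_mm: float = 6.0
    r_thresh: float = 0.35
    z_thresh: float = 2.3
    fwhm_mm: float = 4.0
    hp_sigma_s: float = 100.0
    search_radius_mm: float = 16.0
    alpha: float = 0.05
    head_radius_mm: float = 50.0
    match_floor: float = 0.2
    # seeds
    seed_synthetic: int = 0
    seed_ica: int = 0
    seed_louvain: int = 0
    # toggles
    nuisance_regression: bool = False
    fisher_z: bool = False
    # synthetic cohort block (passed to CohortConfig / aging variant)
    synthetic: dict = field(default_factory=dict)
    aging: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**doc)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
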