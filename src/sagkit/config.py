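"""Pipeline configuration: every numeric threshold used by the analysis stages.

All stage functions take their thresholds from a :class:`PipelineConfig` so a
run is fully described by one config object; its hash is stamped into every
report for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and knobs for the SAG analysis pipeline.

    Defaults follow common practice for multiplexed single-cell bacterial
    sequencing: ultra-high-coverage source regions (>5000x) shed misassigned
    reads that pile up thinly (<=20x) in foreign datasets; ortholog hits
    require 50% identity over 50% of both proteins; dS values >=3 are treated
    as saturated.
    """

    random_seed: int = 0
    coverage_region_threshold: float = 5000.0
    read_removal_depth: float = 20.0
    mapper_max_mismatches: int = 2
    min_hit_identity: float = 0.50
    min_hit_coverage: float = 0.50
    min_rescue_identity: float = 0.90
    mcl_inflation: float = 1.5
    ds_cap: float = 3.0
    window_size: int = 200
    window_step: int = 50
    gscale_set: tuple = (0, 1, 2)
    fragment_p_cutoff: float = 0.05
    bootstrap_reps: int = 100
    support_threshold: float = 80.0
    evalue_cutoff: float = 1e-5
    read_length: int = 76
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        positive = [
            ("coverage_region_threshold", self.coverage_region_threshold),
            ("read_removal_depth", self.read_removal_depth),
            ("ds_cap", self.ds_cap),
            ("window_size", self.window_size),
            ("window_step", self.window_step),
            ("fragment_p_cutoff", self.fragment_p_cutoff),
            ("bootstrap_reps", self.bootstrap_reps),
        ]
        for name, value in positive:
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.window_step > self.window_size:
            raise ValueError("window_step must not exceed window_size")
        for name, value in [
            ("min_hit_identity", self.min_hit_identity),
            ("min_hit_coverage", self.min_hit_coverage),
            ("min_rescue_identity", self.min_rescue_identity),
        ]:
            if not (0 < value <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.mcl_inflation <= 1:
            raise ValueError("mcl_inflation must exceed 1")
        if not set(self.gscale_set) <= {0, 1, 2}:
            raise ValueError("gscale_set must be a subset of {0, 1, 2}")
        self.gscale_set = tuple(sorted(set(self.gscale_set)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable short hash of every threshold, stamped into reports."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
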