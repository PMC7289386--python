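"""Pipeline configuration: one YAML file, fully echoed into the run manifest.

Several parameters of the original analysis workflow are not recoverable
(significance level, imputation constants, split percentile), so every run
must be self-describing: the config round-trips losslessly through its
on-disk YAML representation and is copied verbatim into the manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # inputs
    matrix: str = "matrix.tsv"
    peptide_counts: str = "peptide_counts.tsv"
    groups: str = "groups.tsv"
    clinical: str = "clinical.tsv"
    annotation: str = "annotation.tsv"
    annotation_background: int = 20_000
    outdir: str = "run"
    # preprocessing
    min_unique_peptides: int = 2
    min_detect_fraction: float = 0.75
    width_factor: float = 0.3
    downshift_factor: float = 1.8
    # structure learning
    alpha: float = 0.01
    max_cond_size: int | None = None
    corr_method: str = "pearson"
    # components
    min_component_size: int = 9
    max_component_size: int | None = None
    # survival
    threshold_percentile: float = 50.0
    scan: list[float] | None = None  # [low, high, step] percentile scan
    permutations: int = 1000
    # reproducibility
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.min_detect_fraction <= 1.0):
            raise ValueError("min_detect_fraction must be in (0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.threshold_percentile < 100.0):
            raise ValueError("threshold_percentile must be in (0, 100)")
        if self.permutations < 100:
            raise ValueError("permutations must be at least 100")
        if self.min_component_size < 1:
            raise ValueError("min_component_size must be >= 1")
        if self.scan is not None and len(self.scan) != 3:
            raise ValueError("scan must be [low, high, step]")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
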