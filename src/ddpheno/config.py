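"""Run configuration: every tunable of the phenotyping procedure.

Defaults are the published procedure's defaults; flags and YAML config
files override them (flags > config file > defaults).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    flank_bp:              region extension around each gene (bases)
    pseudocount:           added before every log2 transform
    target_mean_bins:      calibration target, mean bins per gene
    n_calibration_genes:   genes sampled for threshold calibration
    n_binning_samples:     samples used for variance profiles
    max_bin_size:          bins wider than this are subdivided (bases)
    variance_target:       cumulative EVR the retained PCs must reach
    max_components:        hard cap on retained PCs per gene
    min_nonzero_fraction:  gene filter, fraction of samples w/ coverage
    retention_alpha:       KDP p-value cutoff for residualization
    """

    flank_bp: int = 1000
    pseudocount: float = 8.0
    target_mean_bins: int = 256
    n_calibration_genes: int = 128
    n_binning_samples: int = 256
    max_bin_size: int = 1024
    variance_target: float = 0.80
    max_components: int = 16
    min_nonzero_fraction: float = 0.5
    retention_alpha: float = 0.01
    kdp_missing_genes: str = "skip"  # or "drop"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        positive = (
            "pseudocount", "target_mean_bins", "n_calibration_genes",
            "n_binning_samples", "max_bin_size", "max_components",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("variance_target", "min_nonzero_fraction", "retention_alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if self.kdp_missing_genes not in ("skip", "drop"):
            raise ValueError("kdp_missing_genes must be 'skip' or 'drop'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        """Load from a YAML mapping; keyword overrides win over the file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
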