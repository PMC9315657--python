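"""Pipeline configuration: defaults, validation, YAML round-trip.

The resolved configuration of every run is written next to its outputs
so any artifact can be regenerated from the config file alone.  Unknown
keys are errors — a typo in a scale vector must not pass silently.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    """All tunables of the hybrid BoVW pipeline with their defaults."""

    grid_step: int = 8
    gaussian_scales: tuple[int, ...] = (17, 34, 51, 68)
    nonlinear_scales: tuple[int, ...] = (16, 32, 48, 64)
    keep_fraction: float = 0.8
    vocab_k: int = 400
    split_fraction: float = 0.8
    classifier: str = "svm"
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    orientation: str = "upright"
    histogram_norm: str = "l1"
    conductivity: str = "g2"
    contrast_percentile: float = 70.0
    aos_substeps: int = 1
    resize: int | None = None
    split_seed: int = 0
    kmeans_seed: int = 0
    data_seed: int = 0

    def __post_init__(self) -> None:
        self.gaussian_scales = tuple(int(s) for s in self.gaussian_scales)
        self.nonlinear_scales = tuple(int(s) for s in self.nonlinear_scales)
        if self.grid_step < 1:
            raise ConfigError("grid_step must be >= 1")
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ConfigError("keep_fraction must be in (0, 1]")
        if not 0.0 < self.split_fraction < 1.0:
            raise ConfigError("split_fraction must be in (0, 1)")
        if self.vocab_k < 1:
            raise ConfigError("vocab_k must be >= 1")
        if self.orientation not in ("upright", "assigned"):
            raise ConfigError("orientation must be upright|assigned")
        if self.histogram_norm not in ("l1", "l2", "count"):
            raise ConfigError("histogram_norm must be l1|l2|count")
        for vec_name in ("gaussian_scales", "nonlinear_scales"):
            vec = getattr(self, vec_name)
            if not vec or any(s2 <= s1 for s1, s2 in zip(vec, vec[1:])):
                raise ConfigError(f"{vec_name} must be strictly increasing, got {vec}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(known)}"
            )
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a flat key-value mapping")
        return cls.from_mapping(data)

    def to_file(self, path: str | Path) -> None:
        data = asdict(self)
        data["gaussian_scales"] = list(self.gaussian_scales)
        data["nonlinear_scales"] = list(self.nonlinear_scales)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
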