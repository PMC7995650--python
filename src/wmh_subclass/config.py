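"""Run configuration: every tunable threshold in one validated record.

Defaults mirror the method's published operating point (WMH probability
0.9, white-matter PVE 0.5, alpha 0.05) together with explicit choices
for what the method leaves open (connectivity 26, ventricle-map
threshold 0.05, natural log).  Everything is overridable from a flat
YAML file or CLI flags and is echoed into provenance sidecars.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """A configuration value violates an operation's preconditions."""


@dataclass
class RunConfig:
    # thresholds
    wmh_probability_threshold: float = 0.9
    wmh_threshold_strict: bool = True  # value > threshold (strict) vs >=
    pve_threshold: float = 0.5
    ventricle_map_threshold: float = 0.05
    # structural options
    connectivity: int = 26
    # volumetrics
    log_base: str = "e"
    zero_policy: str = "missing"
    brain_volume_dm3: float | None = None
    # statistics
    alpha: float = 0.05
    bonferroni_m: int | None = None  # None -> number of modelled outcomes
    stats_mode: str = "subclass"
    # reproducibility
    seed: int = 0
    # paths (optional; subcommands may supply them as flags instead)
    wmh_path: str | None = None
    pve_path: str | None = None
    ventricle_path: str | None = None
    brain_path: str | None = None
    dti_paths: dict[str, str] = field(default_factory=dict)
    cohort_path: str | None = None
    out_dir: str | None = None

    def validate(self) -> "RunConfig":
        """Check every value against its operation's preconditions."""
        if not 0.0 <= self.wmh_probability_threshold <= 1.0:
            raise ConfigError(
                f"wmh_probability_threshold {self.wmh_probability_threshold} outside [0, 1]"
            )
        if not 0.0 < self.pve_threshold < 1.0:
            raise ConfigError(f"pve_threshold {self.pve_threshold} outside (0, 1)")
        if not 0.0 <= self.ventricle_map_threshold <= 1.0:
            raise ConfigError(
                f"ventricle_map_threshold {self.ventricle_map_threshold} outside [0, 1]"
            )
        if self.connectivity not in (6, 18, 26):
            raise ConfigError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        if self.log_base not in ("e", "10"):
            raise ConfigError(f"log_base must be 'e' or '10', got {self.log_base!r}")
        if self.zero_policy not in ("error", "epsilon", "missing"):
            raise ConfigError(f"unknown zero_policy {self.zero_policy!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha {self.alpha} outside (0, 1)")
        if self.bonferroni_m is not None and self.bonferroni_m < 1:
            raise ConfigError(f"bonferroni_m must be >= 1, got {self.bonferroni_m}")
        if self.stats_mode not in ("total", "subclass"):
            raise ConfigError(f"stats_mode must be 'total' or 'subclass'")
        if self.brain_volume_dm3 is not None and self.brain_volume_dm3 <= 0:
            raise ConfigError(f"brain_volume_dm3 must be positive")
        return self

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a flat key-value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def dump_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)
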