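"""Run configuration: every tunable constant of the pipeline, with the
defaults the algorithm was designed around, loadable from a YAML mapping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Optional, Union

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # signal QC
    beat_ma_window: int = 10
    beat_ma_delta: float = 0.25
    min_resting_minutes: float = 7.5
    max_fraction_filtered: float = 0.20
    min_activity_mean_hr: float = 80.0
    # prescription engine
    framework_path: Optional[str] = None  # None = packaged default table
    compliance_fraction: float = 0.70
    default_hrrest: float = 65.0
    # dose metrics
    k_male: float = 1.92
    k_female: float = 1.67
    hrr_mode: str = "reserve"
    # monitoring
    no_download_days: int = 3
    # plumbing
    store_dir: str = "store"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hrr_mode not in ("reserve", "literal"):
            raise ConfigError(f"hrr_mode must be reserve|literal, got {self.hrr_mode!r}")
        for name in ("beat_ma_delta", "max_fraction_filtered", "compliance_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.min_resting_minutes <= 0 or self.min_activity_mean_hr <= 0:
            raise ConfigError("QC thresholds must be positive")

    @classmethod
    def from_mapping(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_mapping(data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
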