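"""Analysis configuration with strict schema validation."""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError


@dataclass
class AnalysisConfig:
    """Tunable parameters of the optical/electrical analysis pipelines.

    Units: windows in ms, rates in Hz, thresholds dimensionless.  Savitzky-
    Golay windows are specified in ms and converted to odd sample counts per
    trace (never below ``sg_order + 2``).
    """

    sg_window_ms_optical: float = 1.0
    sg_window_ms_electrical: float = 1.0
    sg_order: int = 2
    detection_threshold_factor: float = 5.0
    refractory_ms: float = 30.0
    merge_gap_ms: float = 10.0
    apd_levels: tuple[int, ...] = (50, 70, 90)
    drift_order: int = 3
    rest_window_ms: float = 50.0
    min_petals: int = 4
    cv_n_directions: int = 36
    cv_trajectory_mm: float = 3.0
    cv_min_r2: float = 0.9
    units: dict = field(default_factory=lambda: {"time": "ms", "length": "mm", "velocity": "mm/s"})

    def __post_init__(self) -> None:
        if self.sg_order < 1:
            raise ConfigError("sg_order must be >= 1")
        if self.sg_window_ms_optical <= 0 or self.sg_window_ms_electrical <= 0:
            raise ConfigError("SG windows must be positive")
        if self.detection_threshold_factor <= 0:
            raise ConfigError("detection_threshold_factor must be positive")
        if self.drift_order < 0:
            raise ConfigError("drift_order must be >= 0")
        if not self.apd_levels or any(not (0 < l < 100) for l in self.apd_levels):
            raise ConfigError("apd_levels must lie strictly between 0 and 100")
        self.apd_levels = tuple(int(l) for l in self.apd_levels)
        if self.min_petals < 1:
            raise ConfigError("min_petals must be >= 1")
        if self.cv_n_directions < 8:
            raise ConfigError("cv_n_directions must be >= 8")
        if not (0 <= self.cv_min_r2 <= 1):
            raise ConfigError("cv_min_r2 must lie in [0, 1]")

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        try:
            data = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON ({exc})") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top-level JSON must be an object")
        return cls.from_dict(data)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["apd_levels"] = list(self.apd_levels)
        Path(path).write_text(json.dumps(d, indent=2) + "\n")
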