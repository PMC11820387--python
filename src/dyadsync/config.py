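"""Pipeline configuration: every analysis constant in one validated object.

Defaults are the study constants: a 0.7-4.0 Hz cardiac bandpass, 2.5-s / 0.5-s
signal-quality frames gated at 0.7, 120-s / 5-s pNN50 windows with a
3-segment session minimum, Pearson pair synchrony, and Bonferroni thresholds
0.017 (3-test families) and 0.008 (6-comparison families).  Every constant
is overridable from YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class BandpassConfig:
    low_hz: float = 0.7
    high_hz: float = 4.0


@dataclass
class SqiConfig:
    win_s: float = 2.5
    step_s: float = 0.5
    threshold: float = 0.7


@dataclass
class HrvConfig:
    win_s: float = 120.0
    step_s: float = 5.0
    min_segments: int = 3
    metric: str = "pnn50"


@dataclass
class SynchronyConfig:
    method: str = "pearson"


@dataclass
class StatsConfig:
    alpha_between: float = 0.017
    alpha_within: float = 0.008


@dataclass
class PipelineConfig:
    bandpass: BandpassConfig = field(default_factory=BandpassConfig)
    sqi: SqiConfig = field(default_factory=SqiConfig)
    hrv: HrvConfig = field(default_factory=HrvConfig)
    synchrony: SynchronyConfig = field(default_factory=SynchronyConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ValueError on any out-of-range constant, before computing."""
        if not 0 < self.bandpass.low_hz < self.bandpass.high_hz:
            raise ValueError("bandpass edges must satisfy 0 < low < high")
        if not 0.0 <= self.sqi.threshold <= 1.0:
            raise ValueError(
                f"sqi.threshold must lie in [0, 1], got {self.sqi.threshold}")
        if self.sqi.win_s <= 0 or self.sqi.step_s <= 0:
            raise ValueError("sqi frame geometry must be positive")
        if self.hrv.win_s <= 0 or self.hrv.step_s <= 0:
            raise ValueError("hrv window geometry must be positive")
        if self.hrv.min_segments < 1:
            raise ValueError("hrv.min_segments must be >= 1")
        if self.hrv.metric != "pnn50":
            raise ValueError(f"unsupported hrv metric {self.hrv.metric!r}")
        if self.synchrony.method not in ("pearson", "spearman"):
            raise ValueError("synchrony.method must be pearson or spearman")
        for name in ("alpha_between", "alpha_within"):
            a = getattr(self.stats, name)
            if not 0 < a < 1:
                raise ValueError(f"stats.{name} must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def sub(section, klass):
            return klass(**data.get(section, {}))
        return cls(
            bandpass=sub("bandpass", BandpassConfig),
            sqi=sub("sqi", SqiConfig),
            hrv=sub("hrv", HrvConfig),
            synchrony=sub("synchrony", SynchronyConfig),
            stats=sub("stats", StatsConfig),
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
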