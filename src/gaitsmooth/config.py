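"""Pipeline configuration: a single YAML/JSON document, validated up front.

Unknown keys are rejected so typos fail before any computation; every key
has a documented default (see DEFAULTS). Cross-field constraints (filter
cutoff below Nyquist, SPARC bound below Nyquist) are checked here too.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["PipelineConfig", "load_config", "DEFAULTS"]


@dataclass
class IOConfig:
    target_rate: float = 100.0
    filter_order: int = 4
    filter_fc: float = 5.0


@dataclass
class EventsConfig:
    min_separation: float | None = None   # s; None -> autocorrelation-adaptive
    prominence_factor: float = 0.3
    stride_anchor: str = "foot_off"       # foot_off | foot_strike
    min_strides: int = 4


@dataclass
class SmoothnessConfig:
    fc_max: float = 10.0
    amp_threshold: float = 0.05
    fixed_cutoff: bool = False
    zero_pad_factor: int = 4
    profile_source: str = "gyro"          # gyro | accel
    sparc_abs: bool = True
    min_window: int = 8


@dataclass
class StatsConfig:
    alpha: float = 0.05
    posthoc_method: str = "dunn"          # dunn | mannwhitney
    pooling: str = "trial_mean"           # trial_mean | stride


@dataclass
class PipelineConfig:
    io: IOConfig = field(default_factory=IOConfig)
    events: EventsConfig = field(default_factory=EventsConfig)
    smoothness: SmoothnessConfig = field(default_factory=SmoothnessConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    output_dir: str = "gaitsmooth_out"

    def validate(self) -> "PipelineConfig":
        nyq = self.io.target_rate / 2.0
        if not 0 < self.io.filter_fc < nyq:
            raise ParameterError(
                f"io.filter_fc={self.io.filter_fc} must lie in (0, Nyquist={nyq})")
        if self.io.filter_order < 1:
            raise ParameterError("io.filter_order must be >= 1")
        if not 0 < self.smoothness.fc_max < nyq:
            raise ParameterError(
                f"smoothness.fc_max={self.smoothness.fc_max} must lie in (0, {nyq})")
        if self.events.stride_anchor not in ("foot_off", "foot_strike"):
            raise ParameterError("events.stride_anchor must be foot_off|foot_strike")
        if self.smoothness.profile_source not in ("gyro", "accel"):
            raise ParameterError("smoothness.profile_source must be gyro|accel")
        if self.stats.posthoc_method not in ("dunn", "mannwhitney"):
            raise ParameterError("stats.posthoc_method must be dunn|mannwhitney")
        if self.stats.pooling not in ("trial_mean", "stride"):
            raise ParameterError("stats.pooling must be trial_mean|stride")
        if not 0 < self.stats.alpha < 1:
            raise ParameterError("stats.alpha must lie in (0, 1)")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


_SECTIONS = {"io": IOConfig, "events": EventsConfig,
             "smoothness": SmoothnessConfig, "stats": StatsConfig}

DEFAULTS = PipelineConfig()


def _build_section(cls, data: dict, name: str):
    known = cls.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise ParameterError(f"unknown config keys in {name!r}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    top_known = set(_SECTIONS) | {"seed", "output_dir"}
    unknown = set(data) - top_known
    if unknown:
        raise ParameterError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ParameterError(f"config section {name!r} must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    cfg = PipelineConfig(seed=int(data.get("seed", 0)),
                         output_dir=str(data.get("output_dir", DEFAULTS.output_dir)),
                         **kwargs)
    return cfg.validate()


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML (or JSON) config file; None gives defaults."""
    if path is None:
        return PipelineConfig().validate()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParameterError("config file must contain a mapping")
    return config_from_dict(raw)
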