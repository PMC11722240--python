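"""Pipeline configuration: defaults, YAML/JSON loading, strict key validation."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ParameterError
from .tracks import QCThresholds

__all__ = ["SolverConfig", "GmmConfig", "TrackConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class SolverConfig:
    rtol: float = 1e-8
    atol: float = 1e-10
    dt_out: float = 0.01

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0 or self.dt_out <= 0:
            raise ParameterError("solver tolerances and dt_out must be > 0")


@dataclass(frozen=True)
class GmmConfig:
    n_restarts: int = 20
    seed: int = 0
    var_floor: float = 1e-4
    min_samples: int = 20

    def __post_init__(self) -> None:
        if self.n_restarts < 1 or self.min_samples < 2 or self.var_floor <= 0:
            raise ParameterError("invalid GMM settings")


@dataclass(frozen=True)
class TrackConfig:
    qc: QCThresholds = field(default_factory=QCThresholds)
    window: int = 5
    rapid_threshold: float = 0.025
    rise_floor: float = 0.002
    fall_floor: float = 0.002
    min_amplitude: float = 0.1

    def __post_init__(self) -> None:
        if self.rapid_threshold <= 0:
            raise ParameterError("rapid_threshold must be > 0")
        if self.rise_floor < 0 or self.fall_floor < 0:
            raise ParameterError("pattern floors must be >= 0")


@dataclass(frozen=True)
class PipelineConfig:
    solver: SolverConfig = field(default_factory=SolverConfig)
    gmm: GmmConfig = field(default_factory=GmmConfig)
    tracks: TrackConfig = field(default_factory=TrackConfig)
    out_dir: str = "results"
    log_level: str = "INFO"


def _build(cls, data: dict):
    if not isinstance(data, dict):
        raise ParameterError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ParameterError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        nested = {"SolverConfig": SolverConfig, "GmmConfig": GmmConfig,
                  "TrackConfig": TrackConfig, "QCThresholds": QCThresholds}
        if isinstance(ftype, str) and ftype in nested:
            kwargs[key] = _build(nested[ftype], value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON; unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else (yaml.safe_load(text) or {})
    if overrides:
        data.update(overrides)
    return _build(PipelineConfig, data)
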