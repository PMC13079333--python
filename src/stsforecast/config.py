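"""End-to-end pipeline configuration (YAML-serializable, strict keys)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .forecaster import ForecastConfig
from .preprocess import KalmanConfig
from .synthgen import SynthConfig


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class NmfOptions:
    restarts: int = 20
    seed: int = 0
    vaf_threshold: float = 90.0
    mse_threshold: float = 1e-5
    max_iter: int = 600


@dataclass
class PipelineConfig:
    """Everything needed to run the full simulate -> evaluate pipeline.

    ``activation_source`` selects whether synergy analysis runs on the
    generator's activation envelopes (``envelopes``) or on envelopes
    recovered from raw EMG by the offline filter chain (``raw``).
    ``n_synergies`` is ``auto`` (VAF/MSE order selection) or an integer.
    """

    out_dir: str = "sts_out"
    seed: int = 0
    log_level: str = "INFO"
    activation_source: str = "envelopes"
    analysis_fs: float = 100.0
    n_synergies: int | str = "auto"
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    hard_filter: bool = False
    simulate: bool = True
    save_artifacts: bool = True
    synth: SynthConfig = field(default_factory=SynthConfig)
    kalman: KalmanConfig = field(default_factory=KalmanConfig)
    nmf: NmfOptions = field(default_factory=NmfOptions)
    forecast: ForecastConfig = field(default_factory=ForecastConfig.scaled_down)

    def __post_init__(self) -> None:
        if self.activation_source not in ("envelopes", "raw"):
            raise ConfigError("activation_source must be 'envelopes' or 'raw'")
        if self.n_synergies != "auto" and not (
            isinstance(self.n_synergies, int) and self.n_synergies >= 1
        ):
            raise ConfigError("n_synergies must be 'auto' or a positive integer")
        self.split_fractions = tuple(float(f) for f in self.split_fractions)
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigError("split_fractions must sum to 1")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _from_dict(cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping for {cls.__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    defaults = cls()
    for name, value in data.items():
        current = getattr(defaults, name)
        if dataclasses.is_dataclass(current):
            kwargs[name] = _from_dict(type(current), value)
        elif isinstance(current, tuple):
            kwargs[name] = tuple(value)
        elif isinstance(current, np.ndarray):
            kwargs[name] = np.asarray(value, dtype=float)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def to_dict(cfg: PipelineConfig) -> dict:
    return _to_plain(cfg)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=True)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(PipelineConfig, data)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the full configuration (for provenance logging)."""
    blob = json.dumps(to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
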