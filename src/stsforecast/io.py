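"""Delimited-text readers and writers for signals, markers and labels.

All on-disk formats are plain text: a header row naming the columns,
then one row per sample.  The first column is always ``time_s`` on a
regular grid; the delimiter (comma or tab) is auto-detected on read.
Model checkpoints are a binary ``.npz`` of parameter arrays plus a YAML
sidecar with the configuration snapshot and label vocabulary.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import ActivationMatrix, EmgRecording


class DataFormatError(ValueError):
    """Raised when an on-disk file violates the expected layout."""


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"file not found: {path}")
    with open(path) as fh:
        head = fh.readline()
    delim = "\t" if head.count("\t") >= head.count(",") else ","
    df = pd.read_csv(path, sep=delim, float_precision="round_trip")
    if df.columns[0] != "time_s":
        raise DataFormatError(f"{path}: first column must be 'time_s' (header row required)")
    return df


def _check_time(time_s: np.ndarray, path, tol: float = 0.01) -> float:
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        raise DataFormatError(f"{path}: time_s must be strictly increasing")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > tol * med):
        raise DataFormatError(f"{path}: irregular sampling (> {tol:.0%} jitter)")
    return 1.0 / med


def write_signals(
    path: str | Path, time_s: np.ndarray, values: np.ndarray, names
) -> None:
    """Write (K x T) channel data as columns ``time_s, <names...>``."""
    path = Path(path)
    values = np.atleast_2d(values)
    df = pd.DataFrame({"time_s": time_s})
    for name, row in zip(names, values):
        df[name] = row
    df.to_csv(path, sep=_delimiter_for(path), index=False, float_format="%.17g")


def read_signals(path: str | Path):
    """Read a signals file; returns ``(time_s, values (K,T), names, fs)``."""
    df = _read_table(path)
    time_s = df["time_s"].to_numpy(dtype=float)
    fs = _check_time(time_s, path)
    names = tuple(df.columns[1:])
    if not names:
        raise DataFormatError(f"{path}: no channel columns")
    return time_s, df[list(names)].to_numpy(dtype=float).T, names, fs


def read_emg(path: str | Path, trial_id: str = "", strategy=None) -> EmgRecording:
    _, values, names, fs = read_signals(path)
    return EmgRecording(values, fs, names, trial_id=trial_id, strategy=strategy)


def read_activation(path: str | Path) -> ActivationMatrix:
    _, values, names, fs = read_signals(path)
    return ActivationMatrix(values, fs, names)


def write_markers(path: str | Path, time_s, hip_height) -> None:
    write_signals(path, time_s, np.atleast_2d(hip_height), ("hip_height",))


def read_markers(path: str | Path):
    """Returns ``(time_s, hip_height, fs)``."""
    time_s, values, names, fs = read_signals(path)
    if "hip_height" not in names:
        raise DataFormatError(f"{path}: missing 'hip_height' column")
    return time_s, values[list(names).index("hip_height")], fs


def write_labels(path: str | Path, time_s, labels, strategy: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": time_s, "state": np.asarray(labels).astype(str)})
    df["strategy"] = strategy if strategy is not None else ""
    df.to_csv(path, sep=_delimiter_for(path), index=False, float_format="%.17g")


def read_labels(path: str | Path):
    """Returns ``(time_s, labels, strategy_or_None, fs)``."""
    df = _read_table(path)
    time_s = df["time_s"].to_numpy(dtype=float)
    fs = _check_time(time_s, path)
    if "state" not in df.columns:
        raise DataFormatError(f"{path}: missing 'state' column")
    strategy = None
    if "strategy" in df.columns:
        vals = set(df["strategy"].fillna("").astype(str)) - {""}
        strategy = vals.pop() if len(vals) == 1 else None
    return time_s, df["state"].to_numpy(dtype=str), strategy, fs


def write_matrix(path: str | Path, M: np.ndarray, row_names, col_names) -> None:
    """Delimited matrix with a header row (columns) and an index column."""
    pd.DataFrame(np.asarray(M), index=list(row_names), columns=list(col_names)).to_csv(
        Path(path), sep=_delimiter_for(Path(path)), float_format="%.17g"
    )


def read_matrix(path: str | Path):
    df = pd.read_csv(Path(path), sep=_delimiter_for(Path(path)), index_col=0,
                     float_precision="round_trip")
    return df.to_numpy(dtype=float), tuple(df.index), tuple(df.columns)


def write_trial(trial, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Persist one synthetic trial (signals / markers / labels / config)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "signals": out / f"{stem}_signals.csv",
        "markers": out / f"{stem}_markers.csv",
        "labels": out / f"{stem}_labels.csv",
        "config": out / f"{stem}_config.yaml",
    }
    write_signals(paths["signals"], trial.time_s, trial.raw_emg, trial.config.muscle_names)
    write_markers(paths["markers"], trial.time_s, trial.hip_height)
    write_labels(paths["labels"], trial.time_s, trial.true_states, trial.strategy)
    cfg = dataclasses.asdict(trial.config)
    cfg["true_spatial"] = np.asarray(cfg["true_spatial"]).tolist()
    cfg["muscle_names"] = list(cfg["muscle_names"])
    cfg["bump_amplitudes"] = list(cfg["bump_amplitudes"])
    cfg["carrier_band_hz"] = list(cfg["carrier_band_hz"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


def save_model(model, path: str | Path) -> None:
    """Checkpoint: ``<path>.npz`` parameters + ``<path>.yaml`` metadata."""
    path = Path(path)
    np.savez(
        path.with_suffix(".npz"),
        **model.net.params,
        _class_weights=model.class_weights,
        _W_spatial=(model.W_spatial if model.W_spatial is not None else np.empty(0)),
        _activation_scale=(
            model.activation_scale if model.activation_scale is not None else np.empty(0)
        ),
    )
    meta = {
        "config": _config_to_dict(model.config),
        "classes": list(model.classes),
        "fallback_label": model.fallback_label,
        "best_val_accuracy": float(model.best_val_accuracy),
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def load_model(path: str | Path):
    from ._recurrent import MultiResolutionNet, NetConfig
    from .forecaster import ForecastConfig, ForecastModel

    path = Path(path)
    with open(path.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    cfg = ForecastConfig(**{**meta["config"], "classes": tuple(meta["classes"])})
    arrays = dict(np.load(path.with_suffix(".npz")))
    net = MultiResolutionNet(
        NetConfig(
            n_inputs=arrays[f"Wx_s{cfg.strides[0]}"].shape[0],
            strides=cfg.strides,
            hidden=cfg.hidden,
            fc1_units=cfg.fc1_units,
            n_classes=len(meta["classes"]),
            buffer_len=cfg.buffer_len,
            dtype=cfg.dtype,
        ),
        seed=cfg.seed,
    )
    net.load_state_dict({k: v for k, v in arrays.items() if not k.startswith("_")})
    W = arrays["_W_spatial"]
    scale = arrays["_activation_scale"]
    model = ForecastModel(
        net=net,
        config=cfg,
        classes=tuple(meta["classes"]),
        class_weights=arrays["_class_weights"],
        fallback_label=meta["fallback_label"],
        W_spatial=W if W.size else None,
        activation_scale=scale if scale.size else None,
        best_val_accuracy=meta["best_val_accuracy"],
    )
    return model


def _config_to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    d.pop("classes", None)
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
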