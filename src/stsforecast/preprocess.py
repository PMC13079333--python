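"""EMG preprocessing: activation envelopes and real-time filtering.

Offline chain (used for synergy analysis): zero-phase Butterworth
band-pass 20-450 Hz -> full-wave rectification -> zero-phase 4 Hz
low-pass -> clamp tiny negatives -> per-muscle max normalization.

Real-time chain: the zero-phase low-pass is replaced by a strictly
causal scalar Kalman filter (random-walk state model) so that the
activation estimate at time ``t`` uses only samples up to ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


@dataclass
class EmgRecording:
    """Multi-channel raw EMG: ``signals`` is (K muscles x T samples)."""

    signals: np.ndarray
    fs: float
    muscle_names: tuple[str, ...]
    trial_id: str = ""
    strategy: str | None = None

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] != len(self.muscle_names):
            raise ValueError("signals row count must match muscle_names")


@dataclass
class ActivationMatrix:
    """Non-negative activation envelopes with their normalization record.

    ``scale`` holds the per-muscle divisor applied during normalization
    (the pre-normalization per-muscle maximum), so the original units can
    be restored and so that held-out data can be normalized with the
    scales fitted on training data.
    """

    values: np.ndarray  # (K, T'), >= 0
    fs: float
    muscle_names: tuple[str, ...]
    scale: np.ndarray | None = None
    trial_boundaries: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("activation values must be non-negative")
        if self.values.shape[0] != len(self.muscle_names):
            raise ValueError("values row count must match muscle_names")

    @property
    def n_muscles(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class KalmanConfig:
    """Scalar Kalman filter parameters (random walk: G = F = 1).

    ``sigma_b2`` is the process-noise variance (small: track slow trends),
    ``sigma_v2`` the observation-noise variance (large: distrust noisy
    rectified EMG samples).
    """

    G: float = 1.0
    F: float = 1.0
    sigma_b2: float = 0.1
    sigma_v2: float = 10.0
    x0: float = 0.0
    p0: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_b2 <= 0 or self.sigma_v2 <= 0:
            raise ValueError("noise variances must be positive")


def normalize_per_muscle(
    values: np.ndarray, scale: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Divide each muscle row by ``scale`` (default: its own maximum)."""
    values = np.asarray(values, dtype=float)
    if scale is None:
        scale = values.max(axis=1)
        scale = np.where(scale > 0, scale, 1.0)
    return values / scale[:, None], np.asarray(scale, dtype=float)


def bandpass_rectify_smooth(
    rec: EmgRecording,
    band_hz: tuple[float, float] = (20.0, 450.0),
    lowpass_hz: float = 4.0,
    order: int = 4,
    normalize: bool = True,
    scale: np.ndarray | None = None,
) -> ActivationMatrix:
    """Offline zero-phase envelope extraction (see module docstring)."""
    x = rec.signals
    if not np.all(np.isfinite(x)):
        raise ValueError("EMG signals contain non-finite values")
    if rec.fs < 2 * band_hz[1]:
        raise ValueError(
            f"fs={rec.fs} too low for the {band_hz[1]} Hz band edge"
        )
    sos_bp = sps.butter(order, band_hz, btype="bandpass", fs=rec.fs, output="sos")
    sos_lp = sps.butter(order, lowpass_hz, btype="lowpass", fs=rec.fs, output="sos")
    env = sps.sosfiltfilt(sos_lp, np.abs(sps.sosfiltfilt(sos_bp, x, axis=1)), axis=1)
    env = np.clip(env, 0.0, None)
    if normalize:
        env, scale = normalize_per_muscle(env, scale)
    else:
        scale = None
    return ActivationMatrix(env, rec.fs, rec.muscle_names, scale=scale)


def kalman_filter(signal: np.ndarray, config: KalmanConfig | None = None) -> np.ndarray:
    """Strictly causal scalar Kalman recursion over a 1-D signal.

    predict:  x <- G x,        p <- G^2 p + sigma_b2
    update :  k = p F / (F^2 p + sigma_v2);  x <- x + k (y - F x)
    """
    config = config or KalmanConfig()
    y = np.asarray(signal, dtype=float)
    if y.ndim != 1:
        raise ValueError("kalman_filter expects a 1-D signal")
    if not np.all(np.isfinite(y)):
        raise ValueError("signal contains non-finite values")
    G, F = config.G, config.F
    q, r = config.sigma_b2, config.sigma_v2
    x, p = config.x0, config.p0
    out = np.empty_like(y)
    for i in range(y.size):
        x = G * x
        p = G * G * p + q
        k = p * F / (F * F * p + r)
        x = x + k * (y[i] - F * x)
        p = (1.0 - k * F) * p
        out[i] = x
    return out


def causal_envelope(
    rec: EmgRecording,
    kconfig: KalmanConfig | None = None,
    band_hz: tuple[float, float] = (20.0, 450.0),
    order: int = 4,
    scale: np.ndarray | None = None,
) -> ActivationMatrix:
    """Causal counterpart of :func:`bandpass_rectify_smooth`.

    Causal band-pass -> rectify -> per-channel Kalman smoothing.  When
    ``scale`` is given (per-muscle maxima fitted on training data) it is
    used for normalization, as required for online operation.
    """
    x = rec.signals
    if not np.all(np.isfinite(x)):
        raise ValueError("EMG signals contain non-finite values")
    sos_bp = sps.butter(order, band_hz, btype="bandpass", fs=rec.fs, output="sos")
    rect = np.abs(sps.sosfilt(sos_bp, x, axis=1))
    env = np.vstack([kalman_filter(row, kconfig) for row in rect])
    env = np.clip(env, 0.0, None)
    env, scale = normalize_per_muscle(env, scale)
    return ActivationMatrix(env, rec.fs, rec.muscle_names, scale=scale)


def downsample_pool(x: np.ndarray, in_fs: float, out_fs: float) -> np.ndarray:
    """Non-overlapping block averaging from ``in_fs`` to ``out_fs``.

    The block size is ``in_fs / out_fs`` (must be integral); trailing
    samples that do not fill a block are dropped.
    """
    ratio = in_fs / out_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"in_fs={in_fs} not divisible by out_fs={out_fs}")
    block = int(round(ratio))
    if block == 1:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    n = (x.shape[1] // block) * block
    pooled = x[:, :n].reshape(x.shape[0], -1, block).mean(axis=2)
    return pooled[0] if squeeze else pooled
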