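"""Ground-truth motion-state segmentation from the hip-marker height.

The vertical hip trajectory alternates between a low (sitting) and a
high (standing) plateau.  Frames between a plateau exit and the next
plateau entry are labelled ``SiTSt`` when the height increases and
``StTSi`` when it decreases; remaining frames are ``Sitting`` or
``Standing`` according to the plateau level.  Because the extreme
positions are non-unique on flat holds, a transition onset is defined as
the last sample within 2 % (of the sit-stand range) of the pre-transition
plateau level and the offset as the first sample within 2 % of the
post-transition level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .states import (
    SITST,
    SITTING,
    STANDING,
    STTSI,
    base_state,
    is_valid_sequence,
    tag_strategy,
)

#: fraction of the sit-stand range that bounds a plateau sample
PLATEAU_BAND = 0.02
#: minimum plateau duration (s) used when estimating plateau levels
MIN_PLATEAU_S = 1.0


@dataclass
class MarkerTrajectory:
    """Vertical hip-marker trajectory sampled on a regular time grid."""

    time_s: np.ndarray
    hip_height: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.hip_height = np.asarray(self.hip_height, dtype=float)
        if self.time_s.shape != self.hip_height.shape:
            raise ValueError("time_s and hip_height must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if not np.all(np.isfinite(self.hip_height)):
            raise ValueError("hip_height contains non-finite values")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))


@dataclass
class StateSequence:
    """Per-frame motion-state labels plus transition segment indices.

    ``labels`` uses the 4-class vocabulary, or the strategy-tagged
    6-class vocabulary when ``strategy`` is set at construction through
    :meth:`tagged`.  ``transitions`` lists ``(state, start_idx, end_idx)``
    with ``end_idx`` exclusive.
    """

    time_s: np.ndarray
    labels: np.ndarray
    transitions: list[tuple[str, int, int]] = field(default_factory=list)
    strategy: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(str)
        if self.labels.shape != np.asarray(self.time_s).shape:
            raise ValueError("labels and time_s must have equal length")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))

    def is_valid(self) -> bool:
        return is_valid_sequence(self.labels)

    def count(self, state: str) -> int:
        return sum(1 for s, _, _ in self.transitions if s == state)

    def to_four_class(self) -> "StateSequence":
        labels = np.array([base_state(s) for s in self.labels])
        trans = [(base_state(s), a, b) for s, a, b in self.transitions]
        return StateSequence(self.time_s, labels, trans, strategy=self.strategy)

    def tagged(self, strategy: str) -> "StateSequence":
        """Return the 6-class (strategy-tagged) view of this sequence."""
        labels = np.array([tag_strategy(s, strategy) for s in self.labels])
        trans = [(tag_strategy(s, strategy), a, b) for s, a, b in self.transitions]
        return StateSequence(self.time_s, labels, trans, strategy=strategy)


def _plateau_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal True runs of length >= min_len, as (start, end) exclusive."""
    runs = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for a, b in zip(idx[0::2], idx[1::2]):
        if b - a >= min_len:
            runs.append((int(a), int(b)))
    return runs


def segment_states(
    traj: MarkerTrajectory,
    strategy: str | None = None,
    smooth_hz: float = 4.0,
    band: float = PLATEAU_BAND,
) -> StateSequence:
    """Label every frame of a hip-height trajectory (see module docstring).

    A flat trajectory (no detectable sit-stand range) yields all-static
    labels with a warning rather than an error.
    """
    fs = traj.fs
    h = traj.hip_height
    if smooth_hz > 0 and fs > 2 * smooth_hz:
        sos = sps.butter(4, smooth_hz, btype="lowpass", fs=fs, output="sos")
        h = sps.sosfiltfilt(sos, h)

    lo0, hi0 = np.percentile(h, [2, 98])
    noise = 1.4826 * np.median(np.abs(traj.hip_height - h)) + 1e-12
    if hi0 - lo0 < 10 * noise:
        warnings.warn("flat hip trajectory: returning all-static labels")
        labels = np.full(h.size, SITTING, dtype=object).astype(str)
        seq = StateSequence(traj.time_s, labels, [])
        return seq.tagged(strategy) if strategy else seq

    # refine plateau levels from long quiet runs, then apply the 2 % band
    min_len = max(1, int(MIN_PLATEAU_S * fs))
    rng0 = hi0 - lo0
    low_runs = _plateau_runs(h <= lo0 + band * rng0, min_len)
    high_runs = _plateau_runs(h >= hi0 - band * rng0, min_len)
    lo = np.median(np.concatenate([h[a:b] for a, b in low_runs])) if low_runs else lo0
    hi = np.median(np.concatenate([h[a:b] for a, b in high_runs])) if high_runs else hi0
    rng = hi - lo
    low_mask = h <= lo + band * rng
    high_mask = h >= hi - band * rng

    # alternating plateau intervals in temporal order
    plateaus = sorted(
        [(a, b, SITTING) for a, b in _plateau_runs(low_mask, min_len)]
        + [(a, b, STANDING) for a, b in _plateau_runs(high_mask, min_len)]
    )
    labels = np.empty(h.size, dtype=object)
    transitions: list[tuple[str, int, int]] = []
    if not plateaus:
        warnings.warn("flat hip trajectory (no plateaus): returning all-static labels")
        labels[:] = SITTING
        seq = StateSequence(traj.time_s, labels.astype(str), [])
        return seq.tagged(strategy) if strategy else seq

    labels[: plateaus[0][0]] = plateaus[0][2]
    for (a0, b0, s0), (a1, b1, s1) in zip(plateaus, plateaus[1:]):
        labels[a0:b0] = s0
        if s0 == s1:  # same-level plateaus separated by a dip: bridge
            labels[b0:a1] = s0
            continue
        state = SITST if s1 == STANDING else STTSI
        labels[b0:a1] = state
        transitions.append((state, b0, a1))
    a, b, s = plateaus[-1]
    labels[a:] = s

    seq = StateSequence(traj.time_s, labels.astype(str), transitions)
    return seq.tagged(strategy) if strategy else seq


def slice_state_segments(
    values: np.ndarray,
    seq: StateSequence,
    state: str,
    margin_s: float = 0.0,
) -> np.ndarray:
    """Concatenate the columns of ``values`` over all segments of ``state``.

    ``values`` is any (rows x T) array aligned with ``seq``; ``margin_s``
    extends each segment symmetrically (clipped to the recording), which
    is useful to retain preparatory activity around a transition.
    """
    fs = seq.fs
    m = int(round(margin_s * fs))
    T = np.asarray(values).shape[-1]
    parts = []
    for s, a, b in seq.transitions:
        if base_state(s) == base_state(state):
            parts.append(np.atleast_2d(values)[:, max(0, a - m) : min(T, b + m)])
    if not parts:
        raise ValueError(f"no segments of state {state!r} found")
    return np.concatenate(parts, axis=1)
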