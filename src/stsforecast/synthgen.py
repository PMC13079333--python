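"""Synthetic EMG / kinematics generator for STS motion analysis.

Produces trials with the statistical structure the downstream analysis
assumes: eight muscle activation envelopes driven by four latent muscle
synergies, a repeating ``Sitting -> SiTSt -> Standing -> StTSi`` cycle
with long static holds, a preparatory activation ramp that precedes hip
movement, a hip-height trajectory for ground-truth segmentation, and a
band-limited stochastic carrier so that the raw-EMG preprocessing chain
can be exercised end to end.

Latent synergies (columns of the default spatial matrix):

``E1``  ankle dorsiflexion (TA dominant, RF/ES secondary) — early sit-to-stand
``E2``  knee extension (VM/VL dominant, RF secondary)     — mid transition
``E3``  balance at seat contact (TA dominant, VM/RF secondary) — late
        stand-to-sit, lingering briefly after seat contact
``E4``  hip extension / plantarflexion (ST/SOL/Gmed)      — late sit-to-stand,
        early stand-to-sit, and tonic postural activity during quiet standing

Within each sit-to-stand the synergies peak in the order E1, E2, E4 and
within each stand-to-sit in the order E4, E2, E3.  The stabilization
strategy uses lower peak amplitudes with more prolonged activation than
the momentum-transfer strategy, and a slower hip trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .states import (
    MOMENTUM,
    SITST,
    SITTING,
    STABILIZATION,
    STANDING,
    STATES_4,
    STRATEGIES,
    STTSI,
    tag_strategy,
)

MUSCLE_NAMES = ("VM", "RF", "VL", "ST", "TA", "SOL", "Gmed", "ES")
SYNERGY_NAMES = ("E1", "E2", "E3", "E4")

#: steepness of the logistic hip ramp, in units of 1/duration
_RAMP_STEEPNESS = 12.0
#: fraction of the hip-height range that bounds a plateau ("quiet") sample
PLATEAU_BAND = 0.02


def default_spatial() -> np.ndarray:
    """Default 8 x 4 spatial synergy matrix (rows follow MUSCLE_NAMES).

    Dominant muscles carry weight 1.0, secondary contributors 0.5; each
    column is max-normalized to 1.  Memberships are chosen so that no
    synergy's muscle support contains another's, which keeps the
    factorization identifiable (otherwise one spatial pattern could be
    exchanged for a mixture of the others without changing the fit).
    """
    W = np.zeros((8, 4))
    idx = {m: i for i, m in enumerate(MUSCLE_NAMES)}
    # E1: ankle dorsiflexion
    W[idx["TA"], 0] = 1.0
    W[idx["RF"], 0] = 0.5
    W[idx["ES"], 0] = 0.5
    # E2: knee extension
    W[idx["VM"], 1] = 1.0
    W[idx["VL"], 1] = 1.0
    W[idx["RF"], 1] = 0.5
    # E3: balance toward seat contact
    W[idx["TA"], 2] = 1.0
    W[idx["VM"], 2] = 0.5
    W[idx["RF"], 2] = 0.5
    # E4: hip extension + plantarflexion
    W[idx["ST"], 3] = 1.0
    W[idx["SOL"], 3] = 1.0
    W[idx["Gmed"], 3] = 1.0
    W[idx["ES"], 3] = 0.5
    return W


@dataclass
class SynthConfig:
    """Configuration of the synthetic STS generator.

    Durations are in seconds, rates in Hz, amplitudes on the unit-max
    activation scale.  ``amplitude_scale`` / ``width_scale`` encode the
    strategy contrast (stabilization: lower, longer activations).
    """

    muscle_names: tuple[str, ...] = MUSCLE_NAMES
    true_spatial: np.ndarray = field(default_factory=default_spatial)
    cycles_per_strategy: int = 10
    hold_duration_s: float = 5.0
    hold_jitter_s: float = 1.0
    transition_duration_s: dict = field(
        default_factory=lambda: {MOMENTUM: 1.2, STABILIZATION: 2.4}
    )
    prep_lead_s: float = 0.5
    prep_amplitude: float = 0.3
    amplitude_scale: dict = field(
        default_factory=lambda: {MOMENTUM: 1.0, STABILIZATION: 0.6}
    )
    width_scale: dict = field(
        default_factory=lambda: {MOMENTUM: 1.0, STABILIZATION: 1.6}
    )
    bump_width_s: float = 0.14
    bump_centers: tuple[float, float, float] = (0.2, 0.5, 0.8)
    bump_amplitudes: tuple[float, float, float] = (1.0, 1.0, 0.95)
    bump_jitter: float = 0.1
    standing_tonic: float = 0.05
    landing_hold_s: float = 0.8
    landing_amplitude: float = 0.3
    envelope_noise_sigma: float = 0.002
    envelope_baseline: float = 0.0
    emg_fs: float = 1000.0
    carrier_band_hz: tuple[float, float] = (20.0, 450.0)
    carrier_baseline_sigma: float = 0.01
    hip_sit_height: float = 0.45
    hip_stand_height: float = 0.85
    hip_noise_sigma: float = 0.002
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.true_spatial = np.asarray(self.true_spatial, dtype=float)
        K = len(self.muscle_names)
        if self.true_spatial.shape != (K, 4):
            raise ValueError(
                f"true_spatial must be {K} x 4, got {self.true_spatial.shape}"
            )
        if np.any(self.true_spatial < 0):
            raise ValueError("true_spatial must be non-negative")
        colmax = self.true_spatial.max(axis=0)
        if np.any(colmax <= 0) or not np.allclose(colmax, 1.0):
            raise ValueError("each true_spatial column must be max-normalized to 1")
        if self.prep_lead_s <= 0:
            raise ValueError("prep_lead_s must be positive")
        if self.hold_duration_s < 5.0:
            raise ValueError("hold_duration_s must be at least 5 s")
        if self.cycles_per_strategy < 1:
            raise ValueError("cycles_per_strategy must be at least 1")
        for strat in STRATEGIES:
            if self.transition_duration_s[strat] <= 0:
                raise ValueError("transition durations must be positive")
        if self.emg_fs < 2 * self.carrier_band_hz[1]:
            raise ValueError("emg_fs must exceed twice the carrier band edge")


@dataclass
class TransitionEvent:
    """Ground-truth timing of one labelled transition segment."""

    state: str  # 'SiTSt' or 'StTSi'
    ramp_start_s: float  # start of the hip ramp support
    onset_s: float  # labelled onset (2 % departure from the plateau)
    offset_s: float  # labelled offset (2 % arrival at the new plateau)
    onset_idx: int
    offset_idx: int


@dataclass
class SynthTrial:
    """One generated recording under a single movement strategy."""

    raw_emg: np.ndarray  # (8, T) at fs
    true_envelopes: np.ndarray  # (8, T), non-negative
    true_temporal: np.ndarray  # (4, T), non-negative
    hip_height: np.ndarray  # (T,)
    true_states: np.ndarray  # (T,) 4-class labels
    time_s: np.ndarray  # (T,)
    fs: float
    strategy: str
    transitions: list[TransitionEvent]
    config: SynthConfig

    @property
    def true_states_6(self) -> np.ndarray:
        return np.array(
            [tag_strategy(s, self.strategy) for s in self.true_states], dtype=object
        ).astype(str)


def _logistic_ramp(t: np.ndarray, start: float, duration: float) -> np.ndarray:
    """Logistic ramp rescaled to run exactly from 0 at ``start`` to 1."""
    a = _RAMP_STEEPNESS / 2.0
    x = _RAMP_STEEPNESS * ((t - start) / duration - 0.5)
    lo = 1.0 / (1.0 + np.exp(a))
    hi = 1.0 / (1.0 + np.exp(-a))
    return (1.0 / (1.0 + np.exp(-x)) - lo) / (hi - lo)


def _ramp_crossing(start: float, duration: float, level: float) -> float:
    """Time at which the normalized logistic ramp crosses ``level``."""
    a = _RAMP_STEEPNESS / 2.0
    lo = 1.0 / (1.0 + np.exp(a))
    hi = 1.0 / (1.0 + np.exp(-a))
    s = lo + level * (hi - lo)
    x = np.log(s / (1.0 - s))
    return start + duration * (x / _RAMP_STEEPNESS + 0.5)


def synthesize_raw_emg(
    envelope: np.ndarray,
    fs: float,
    rng: np.random.Generator,
    band_hz: tuple[float, float] = (20.0, 450.0),
    baseline_sigma: float = 0.01,
    order: int = 4,
) -> np.ndarray:
    """Amplitude-modulate a band-limited stochastic carrier by ``envelope``.

    The construction is the inverse of the offline preprocessing chain:
    band-pass filtering, rectification and 4 Hz smoothing of the output
    recovers (a scaled copy of) the envelope.  A small additive
    band-limited baseline noise floor models sensor noise.
    """
    envelope = np.asarray(envelope, dtype=float)
    if np.any(envelope < 0):
        raise ValueError("envelope must be non-negative")
    if fs < 2 * band_hz[1]:
        raise ValueError("fs must exceed twice the upper band edge")
    sos = sps.butter(order, band_hz, btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfilt(sos, rng.standard_normal(envelope.shape[-1]))
    carrier /= carrier.std()
    baseline = sps.sosfilt(sos, rng.standard_normal(envelope.shape[-1]))
    baseline /= baseline.std()
    return carrier * envelope + baseline_sigma * baseline


def _add_gaussian_bump(
    row: np.ndarray, t: np.ndarray, fs: float, center: float, sigma: float, amp: float
) -> None:
    i0 = max(0, int((center - 4 * sigma) * fs))
    i1 = min(len(t), int((center + 4 * sigma) * fs) + 1)
    tt = t[i0:i1]
    row[i0:i1] += amp * np.exp(-0.5 * ((tt - center) / sigma) ** 2)


def _add_prep_ramp(
    row: np.ndarray, t: np.ndarray, fs: float, onset: float, lead: float, amp: float
) -> None:
    """Half-cosine preparatory ramp ending exactly at the labelled onset."""
    i0 = max(0, int((onset - lead) * fs))
    i1 = min(len(t), int(onset * fs) + 1)
    tt = t[i0:i1]
    phase = np.clip((tt - (onset - lead)) / lead, 0.0, 1.0)
    row[i0:i1] = np.maximum(row[i0:i1], amp * 0.5 * (1.0 - np.cos(np.pi * phase)))


def generate_trial(config: SynthConfig, strategy: str) -> SynthTrial:
    """Generate one full recording (``cycles_per_strategy`` STS cycles).

    The recording alternates jittered static holds (>= ``hold_duration_s``)
    with hip-ramp transitions; ground-truth state boundaries are placed at
    the 2 % departure/arrival points of the noiseless hip ramp, matching
    the plateau criterion used by the segmentation stage.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    cfg = config
    fs = cfg.emg_fs
    rng = np.random.default_rng([cfg.rng_seed, STRATEGIES.index(strategy), 2026])

    D = cfg.transition_duration_s[strategy]
    amp_scale = cfg.amplitude_scale[strategy]
    width = cfg.bump_width_s * cfg.width_scale[strategy]

    # ----- timeline --------------------------------------------------
    hold = lambda: cfg.hold_duration_s + rng.uniform(0.0, cfg.hold_jitter_s)
    cursor = 0.0
    ramps: list[tuple[str, float]] = []  # (state, ramp_start_s)
    for _ in range(cfg.cycles_per_strategy):
        cursor += hold()  # Sitting
        ramps.append((SITST, cursor))
        cursor += D
        cursor += hold()  # Standing
        ramps.append((STTSI, cursor))
        cursor += D
    cursor += hold()  # trailing Sitting hold
    T = int(round(cursor * fs))
    t = np.arange(T) / fs

    # ----- hip height and ground-truth labels ------------------------
    sit, stand = cfg.hip_sit_height, cfg.hip_stand_height
    R = stand - sit
    hip = np.full(T, sit)
    labels = np.full(T, SITTING, dtype=object)
    transitions: list[TransitionEvent] = []
    for state, start in ramps:
        i0, i1 = int(start * fs), min(T, int((start + D) * fs) + 1)
        ramp = _logistic_ramp(t[i0:i1], start, D)
        if state == SITST:
            hip[i0:i1] = sit + R * ramp
            hip[i1:] = stand
        else:
            hip[i0:i1] = stand - R * ramp
            hip[i1:] = sit
        onset_s = _ramp_crossing(start, D, PLATEAU_BAND)
        offset_s = _ramp_crossing(start, D, 1.0 - PLATEAU_BAND)
        onset_idx, offset_idx = int(onset_s * fs), int(offset_s * fs)
        labels[onset_idx:offset_idx] = state
        labels[offset_idx:] = STANDING if state == SITST else SITTING
        transitions.append(
            TransitionEvent(state, start, onset_s, offset_s, onset_idx, offset_idx)
        )
    hip = hip + cfg.hip_noise_sigma * rng.standard_normal(T)

    # ----- temporal synergy patterns ---------------------------------
    H = np.zeros((4, T))
    orders = {SITST: (0, 1, 3), STTSI: (3, 1, 2)}
    for ev in transitions:
        L = ev.offset_s - ev.onset_s
        order = orders[ev.state]
        for j, syn in enumerate(order):
            center = ev.onset_s + cfg.bump_centers[j] * L
            amp = (
                cfg.bump_amplitudes[j]
                * amp_scale
                * (1.0 + cfg.bump_jitter * rng.uniform(-1.0, 1.0))
            )
            _add_gaussian_bump(H[syn], t, fs, center, width, amp)
        # preparatory ramp of the first synergy, before the hip departs
        _add_prep_ramp(
            H[order[0]], t, fs, ev.onset_s, cfg.prep_lead_s, cfg.prep_amplitude * amp_scale
        )
        # post-landing balance: the seat-contact synergy stays active for a
        # short while after a stand-to-sit ends (trunk stabilization)
        if ev.state == STTSI and cfg.landing_hold_s > 0:
            i0 = min(T - 1, int(ev.offset_s * fs))
            i1 = min(T, int((ev.offset_s + cfg.landing_hold_s) * fs))
            phase = np.clip(
                (t[i0:i1] - ev.offset_s) / cfg.landing_hold_s, 0.0, 1.0
            )
            decay = cfg.landing_amplitude * amp_scale * 0.5 * (1.0 + np.cos(np.pi * phase))
            H[2, i0:i1] = np.maximum(H[2, i0:i1], decay)
    # tonic postural activity of the hip-extension synergy while standing
    if cfg.standing_tonic > 0:
        edge = 0.2  # s, raised-cosine shoulders
        for ev_up, ev_down in zip(transitions[0::2], transitions[1::2]):
            i0, i1 = ev_up.offset_idx, ev_down.onset_idx
            tt = t[i0:i1]
            prof = np.ones(i1 - i0)
            rise = tt < tt[0] + edge
            fall = tt > tt[-1] - edge
            prof[rise] = 0.5 * (1 - np.cos(np.pi * (tt[rise] - tt[0]) / edge))
            prof[fall] = 0.5 * (1 - np.cos(np.pi * (tt[-1] - tt[fall]) / edge))
            H[3, i0:i1] = np.maximum(H[3, i0:i1], cfg.standing_tonic * prof)

    # ----- envelopes and raw EMG -------------------------------------
    A = cfg.true_spatial @ H + cfg.envelope_baseline
    if cfg.envelope_noise_sigma > 0:
        A = A + cfg.envelope_noise_sigma * rng.standard_normal(A.shape)
        A = np.clip(A, 0.0, None)
    raw = np.empty_like(A)
    for i in range(A.shape[0]):
        raw[i] = synthesize_raw_emg(
            A[i], fs, rng, cfg.carrier_band_hz, cfg.carrier_baseline_sigma
        )

    return SynthTrial(
        raw_emg=raw,
        true_envelopes=A,
        true_temporal=H,
        hip_height=hip,
        true_states=labels.astype(str),
        time_s=t,
        fs=fs,
        strategy=strategy,
        transitions=transitions,
        config=cfg,
    )


def generate_corpus(config: SynthConfig) -> dict[str, SynthTrial]:
    """One trial per strategy (the default two-motion x two-strategy corpus)."""
    return {strategy: generate_trial(config, strategy) for strategy in STRATEGIES}
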