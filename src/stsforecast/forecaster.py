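"""Anticipatory motion-state forecasting from temporal synergy patterns.

The classifier predicts the motion state a fixed horizon ahead (default
300 ms) from the recent history of the four temporal synergy activations
sampled at 100 Hz.  Four LSTM branches read the same history at
different temporal resolutions (average pooling with strides 1, 2, 4, 8);
their final hidden states are concatenated and classified by a fully
connected block (stage 1).  A second, buffered linear stage (stage 2)
reads the last 15 stage-1 posteriors and the current one and emits the
final, temporally plausible state.

Two lookback conventions are supported for the pooled branches:

``long`` (default)
    each branch keeps ``window_steps`` pooled steps, so the stride-s
    branch summarizes ``s * window_steps`` raw frames (1, 2, 4 and 8 s
    of context at the defaults) — coarser strides reach further back.
``compact``
    every branch reads the same ``window_steps`` raw frames and pooling
    shortens the sequence (``window_steps // s`` steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import logging

import numpy as np

from ._recurrent import MultiResolutionNet, NetConfig, SGD, Adam, weighted_nll
from .segmentation import StateSequence
from .states import STATES_6, legal_successors

logger = logging.getLogger("stsforecast")

__all__ = [
    "ForecastConfig",
    "WindowedDataset",
    "WindowCorpus",
    "ForecastModel",
    "StreamPredictor",
    "build_windows",
    "chronological_split",
    "train_forecaster",
    "apply_transition_filter",
]


@dataclass
class ForecastConfig:
    """Hyperparameters of the forecaster.

    The ``full`` profile is the full-scale training schedule (1000
    epochs, batch 5000, 128 hidden units, learning rate 0.02 linearly
    decayed to 0.001).  The ``scaled_down`` profile is the desk-scale
    counterpart used by the test suite: 100 epochs, 32 hidden units,
    batch 512 and training windows subsampled by a stride of 8 frames.
    """

    horizon_ms: float = 300.0
    window_steps: int = 100
    strides: tuple[int, ...] = (1, 2, 4, 8)
    hidden: int = 128
    fc1_units: int = 128
    buffer_len: int = 15
    classes: tuple[str, ...] = STATES_6
    epochs: int = 1000
    batch_size: int = 5000
    lr_start: float = 0.01
    lr_end: float = 0.001
    optimizer: str = "adam"
    momentum: float = 0.9
    clip_norm: float = 5.0
    class_weighting: str = "inverse_frequency"
    lookback_mode: str = "long"
    train_stride: int = 1
    input_fs: float = 100.0
    val_every: int = 5
    fc2_epochs: int = 300
    fc2_lr: float = 0.01
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon_ms <= 0:
            raise ValueError("horizon_ms must be positive")
        if self.buffer_len < 1:
            raise ValueError("buffer_len must be at least 1")
        strides = tuple(int(s) for s in self.strides)
        if any(s <= 0 for s in strides) or list(strides) != sorted(strides):
            raise ValueError("strides must be positive and sorted")
        if self.window_steps < max(strides):
            raise ValueError("window_steps must be >= the largest stride")
        if self.lookback_mode not in ("long", "compact"):
            raise ValueError("lookback_mode must be 'long' or 'compact'")
        self.strides = strides
        self.classes = tuple(self.classes)

    @classmethod
    def scaled_down(cls, **overrides) -> "ForecastConfig":
        base = dict(
            epochs=100,
            batch_size=512,
            hidden=32,
            fc1_units=64,
            train_stride=8,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def horizon_frames(self) -> int:
        return int(round(self.horizon_ms / 1000.0 * self.input_fs))

    def branch_steps(self, stride: int) -> int:
        if self.lookback_mode == "long":
            return self.window_steps
        return max(1, self.window_steps // stride)

    @property
    def lookback(self) -> int:
        """Raw frames of history a sample consumes (largest branch span)."""
        return max(self.branch_steps(s) * s for s in self.strides)


# ----------------------------------------------------------------------
# windowed data


def _pooled(cs: np.ndarray, t_arr: np.ndarray, stride: int, steps: int) -> np.ndarray:
    """Average-pooled windows ending at each ``t`` (inclusive).

    ``cs`` is the (T+1, n) cumulative sum of the input sequence; block j
    of the output covers raw frames ``(t - (steps-j)*s, t - (steps-1-j)*s]``
    so the newest block ends exactly at ``t``.
    """
    j = np.arange(steps)
    ends = t_arr[:, None] + 1 - (steps - 1 - j) * stride
    starts = ends - stride
    return (cs[ends] - cs[starts]) / stride


@dataclass
class WindowedDataset:
    """Sliding multi-resolution windows over one continuous recording.

    ``H`` is (n_synergies, T) at ``config.input_fs``; the sample anchored
    at frame ``t`` has input ``H[:, : t+1]`` (pooled per branch) and
    target ``labels[t + horizon_frames]``.
    """

    H: np.ndarray
    labels: np.ndarray  # (T,) int-encoded target classes
    classes: tuple[str, ...]
    config: ForecastConfig
    name: str = ""
    _cumsum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.H.shape[1] != self.labels.size:
            raise ValueError("H and labels must have equal length")
        self._cumsum = np.concatenate(
            [np.zeros((1, self.H.shape[0])), np.cumsum(self.H.T, axis=0)], axis=0
        )

    @property
    def n_frames(self) -> int:
        return self.H.shape[1]

    @property
    def first_valid(self) -> int:
        return self.config.lookback - 1

    @property
    def valid_indices(self) -> np.ndarray:
        """Anchors with a full lookback and an in-range target."""
        lo = self.first_valid
        hi = self.n_frames - self.config.horizon_frames
        return np.arange(lo, hi)

    def inputs(self, t_arr: np.ndarray) -> list[np.ndarray]:
        t_arr = np.asarray(t_arr, dtype=int)
        return [
            _pooled(self._cumsum, t_arr, s, self.config.branch_steps(s))
            for s in self.config.strides
        ]

    def targets(self, t_arr: np.ndarray) -> np.ndarray:
        return self.labels[np.asarray(t_arr, dtype=int) + self.config.horizon_frames]


def encode_labels(labels: Iterable[str], classes: tuple[str, ...]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([lut[l] for l in labels], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"label {exc} not in class vocabulary {classes}") from exc


def build_windows(
    H: np.ndarray, S: StateSequence, config: ForecastConfig, name: str = ""
) -> WindowedDataset:
    """Windowed dataset for one recording; ``S`` must be aligned with ``H``."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    if H.shape[1] != len(S.labels):
        raise ValueError("H and state sequence are misaligned")
    return WindowedDataset(
        H, encode_labels(S.labels, config.classes), config.classes, config, name=name
    )


def chronological_split(
    S: StateSequence, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
) -> tuple[int, int]:
    """Frame boundaries of a chronological train/val/test partition.

    Cut points are snapped to the midpoint of the nearest static hold
    (Sitting or Standing) so that no split boundary falls inside or
    adjacent to a transition.  Returns ``(b1, b2)``: train = [0, b1),
    val = [b1, b2), test = [b2, T).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    T = len(S.labels)
    # candidate cut points: midpoints of static holds between transitions
    cands = []
    trans = sorted(S.transitions, key=lambda x: x[1])
    for (_, _, b0), (_, a1, _) in zip(trans, trans[1:]):
        if a1 > b0:
            cands.append((b0 + a1) // 2)
    if not cands:
        b1 = int(fractions[0] * T)
        return b1, b1 + int(fractions[1] * T)
    cands = np.asarray(sorted(cands))
    b2 = int(cands[np.argmin(np.abs(cands - (fractions[0] + fractions[1]) * T))])
    earlier = cands[cands < b2]
    if len(earlier) == 0:
        raise ValueError("recording too short for the requested split")
    b1 = int(earlier[np.argmin(np.abs(earlier - fractions[0] * T))])
    return b1, b2


@dataclass
class WindowCorpus:
    """Windowed streams plus per-stream chronological split indices."""

    streams: list[WindowedDataset]
    train: list[np.ndarray]
    val: list[np.ndarray]
    test: list[np.ndarray]

    @classmethod
    def from_streams(
        cls,
        streams: list[WindowedDataset],
        splits: list[tuple[int, int]],
    ) -> "WindowCorpus":
        train, val, test = [], [], []
        for ds, (b1, b2) in zip(streams, splits):
            idx = ds.valid_indices
            hf = ds.config.horizon_frames
            tgt = idx + hf
            train.append(idx[tgt < b1])
            val.append(idx[(tgt >= b1) & (tgt < b2)])
            test.append(idx[tgt >= b2])
        return cls(streams, train, val, test)


# ----------------------------------------------------------------------
# model


@dataclass
class ForecastModel:
    """Trained two-stage forecaster plus everything needed to run online."""

    net: MultiResolutionNet
    config: ForecastConfig
    classes: tuple[str, ...]
    class_weights: np.ndarray
    fallback_label: str
    W_spatial: np.ndarray | None = None
    activation_scale: np.ndarray | None = None
    best_val_accuracy: float = float("nan")
    training_log: dict = field(default_factory=dict)

    # -- batch prediction ---------------------------------------------

    def stage1_log_probs(
        self, ds: WindowedDataset, t_arr: np.ndarray, chunk: int = 2048
    ) -> np.ndarray:
        out = np.empty((len(t_arr), len(self.classes)))
        for i in range(0, len(t_arr), chunk):
            xs = ds.inputs(t_arr[i : i + chunk])
            logp, _ = self.net.stage1_forward(xs)
            out[i : i + chunk] = logp
        return out

    def _fc2_features(
        self, logp_by_frame: dict[int, np.ndarray], t_arr: np.ndarray
    ) -> np.ndarray:
        C = len(self.classes)
        L = self.config.buffer_len
        uniform = np.full(C, -np.log(C))
        feats = np.empty((len(t_arr), (L + 1) * C))
        for row, t in enumerate(t_arr):
            parts = [
                logp_by_frame.get(t - k, uniform) for k in range(L, 0, -1)
            ]  # oldest -> newest
            parts.append(logp_by_frame[t])
            feats[row] = np.concatenate(parts)
        return feats

    def predict_batch(
        self,
        ds: WindowedDataset,
        t_arr: np.ndarray | None = None,
        hard_filter: bool = False,
        return_log_probs: bool = False,
    ):
        """Predict the future state for each anchor frame in ``t_arr``.

        Stage-1 posteriors for the ``buffer_len`` frames preceding each
        anchor are computed as needed; frames without a full lookback
        contribute a uniform posterior to the buffer (matching the
        warm-start behaviour of the streaming predictor).
        """
        if t_arr is None:
            t_arr = ds.valid_indices
        t_arr = np.asarray(t_arr, dtype=int)
        L = self.config.buffer_len
        need = np.unique(
            np.concatenate([t_arr - k for k in range(L + 1)])
        )
        need = need[(need >= ds.first_valid) & (need < ds.n_frames)]
        logp = self.stage1_log_probs(ds, need)
        by_frame = {int(t): logp[i] for i, t in enumerate(need)}
        feats = self._fc2_features(by_frame, t_arr)
        logp2 = self.net.fc2_forward(feats)
        pred_idx = np.asarray(logp2).argmax(axis=1)
        labels = np.array([self.classes[i] for i in pred_idx])
        if hard_filter:
            labels = _hard_filter(labels)
        if return_log_probs:
            s1 = np.vstack([by_frame[int(t)] for t in t_arr])
            return labels, np.asarray(logp2), s1
        return labels

    def stream_predictor(self, hard_filter: bool = False) -> "StreamPredictor":
        return StreamPredictor(self, hard_filter=hard_filter)


def _hard_filter(labels: np.ndarray) -> np.ndarray:
    """Replace automaton-violating emissions by the previous kept label."""
    out = labels.copy()
    prev = out[0]
    for i in range(1, len(out)):
        if out[i] != prev and out[i] not in legal_successors(prev):
            out[i] = prev
        prev = out[i]
    return out


def apply_transition_filter(
    model: ForecastModel,
    buffer_log_probs: np.ndarray,
    current_log_probs: np.ndarray,
    prev_label: str | None = None,
    hard_filter: bool = False,
) -> str:
    """Stage-2 mapping from (posterior buffer, current posterior) to a label.

    ``buffer_log_probs`` is (buffer_len, C), oldest first.  With
    ``hard_filter`` any emission that would violate the cyclic automaton
    relative to ``prev_label`` is replaced by ``prev_label``.
    """
    buf = np.asarray(buffer_log_probs, dtype=float)
    if buf.shape != (model.config.buffer_len, len(model.classes)):
        raise ValueError("buffer has wrong shape")
    feats = np.concatenate([buf.ravel(), np.asarray(current_log_probs)])[None, :]
    label = model.classes[int(model.net.fc2_forward(feats).argmax(axis=1)[0])]
    if hard_filter and prev_label is not None:
        if label != prev_label and label not in legal_successors(prev_label):
            return prev_label
    return label


class StreamPredictor:
    """Strictly causal step-by-step predictor (online twin of batch mode)."""

    def __init__(self, model: ForecastModel, hard_filter: bool = False):
        self.model = model
        self.hard_filter = hard_filter
        cfg = model.config
        self._hist: list[np.ndarray] = []
        C = len(model.classes)
        self._buffer = [np.full(C, -np.log(C)) for _ in range(cfg.buffer_len)]
        self._prev_label: str | None = None
        self.n_steps = 0

    def step(self, h_step: np.ndarray) -> tuple[str, np.ndarray, bool]:
        """Consume one frame of temporal synergy activation.

        Returns ``(label, stage1_log_probs, warmup)``; during warm-up
        (lookback not yet filled) the fallback label and a uniform
        posterior are emitted.
        """
        cfg = self.model.config
        h_step = np.asarray(h_step, dtype=float).ravel()
        self._hist.append(h_step)
        if len(self._hist) > cfg.lookback:
            self._hist.pop(0)
        self.n_steps += 1
        C = len(self.model.classes)
        if len(self._hist) < cfg.lookback:
            return self.model.fallback_label, np.full(C, -np.log(C)), True
        hist = np.asarray(self._hist)  # (lookback, n)
        cs = np.concatenate([np.zeros((1, hist.shape[1])), np.cumsum(hist, axis=0)])
        t = np.array([cfg.lookback - 1])
        xs = [_pooled(cs, t, s, cfg.branch_steps(s)) for s in cfg.strides]
        logp1, _ = self.model.net.stage1_forward(xs)
        logp1 = np.asarray(logp1[0], dtype=float)
        feats = np.concatenate([np.concatenate(self._buffer), logp1])[None, :]
        logp2 = self.model.net.fc2_forward(feats)[0]
        label = self.model.classes[int(np.argmax(logp2))]
        self._buffer.pop(0)
        self._buffer.append(logp1)
        if self.hard_filter and self._prev_label is not None:
            if label != self._prev_label and label not in legal_successors(
                self._prev_label
            ):
                label = self._prev_label
        self._prev_label = label
        return label, logp1, False


# ----------------------------------------------------------------------
# training


def _class_weights(y: np.ndarray, n_classes: int, mode: str) -> np.ndarray:
    counts = np.bincount(y, minlength=n_classes).astype(float)
    if mode == "none":
        return np.ones(n_classes)
    if mode != "inverse_frequency":
        raise ValueError(f"unknown class weighting {mode!r}")
    present = counts > 0
    w = np.zeros(n_classes)
    w[present] = counts[present].sum() / (present.sum() * counts[present])
    return w


def _gather_batch(corpus: WindowCorpus, pairs: np.ndarray):
    """Materialize a minibatch given (stream, anchor) index pairs."""
    xs_parts: list[list[np.ndarray]] = None
    ys = []
    for si in np.unique(pairs[:, 0]):
        ds = corpus.streams[si]
        ts = pairs[pairs[:, 0] == si, 1]
        xs = ds.inputs(ts)
        if xs_parts is None:
            xs_parts = [[x] for x in xs]
        else:
            for acc, x in zip(xs_parts, xs):
                acc.append(x)
        ys.append(ds.targets(ts))
    xs = [np.concatenate(acc, axis=0) for acc in xs_parts]
    return xs, np.concatenate(ys)


def _split_accuracy(model: ForecastModel, corpus: WindowCorpus, which: list[np.ndarray],
                    max_samples: int = 1500) -> float:
    """Frame-wise accuracy of stage-1 argmax over the given split.

    Large splits are subsampled evenly (the estimate is used only for
    epoch-level model selection).
    """
    total = sum(len(idx) for idx in which)
    step = max(1, int(np.ceil(total / max_samples)))
    hit = tot = 0
    for ds, idx in zip(corpus.streams, which):
        idx = idx[::step]
        if len(idx) == 0:
            continue
        logp = model.stage1_log_probs(ds, idx)
        pred = logp.argmax(axis=1)
        hit += int((pred == ds.targets(idx)).sum())
        tot += len(idx)
    return hit / tot if tot else float("nan")


def train_forecaster(corpus: WindowCorpus, config: ForecastConfig) -> ForecastModel:
    """Two-stage training (see module docstring).

    Stage 1 minimizes class-weighted NLL over multi-resolution windows;
    the parameters with the best validation accuracy are kept.  Stage 2
    freezes stage 1 and fits the buffered transition layer on
    teacher-forced stage-1 posterior histories from the training split.
    """
    rng = np.random.default_rng([config.seed, 13])
    pairs = np.array(
        [
            (si, t)
            for si, idx in enumerate(corpus.train)
            for t in idx[:: config.train_stride]
        ],
        dtype=int,
    )
    if len(pairs) == 0:
        raise ValueError("empty training split")
    y_all = np.concatenate(
        [
            corpus.streams[si].targets(idx[:: config.train_stride])
            for si, idx in enumerate(corpus.train)
            if len(idx)
        ]
    )
    n_classes = len(config.classes)
    if len(np.unique(y_all)) < 2:
        raise ValueError("training data contains fewer than two classes")
    weights = _class_weights(y_all, n_classes, config.class_weighting)
    counts = np.bincount(y_all, minlength=n_classes)
    fallback = config.classes[int(np.argmax(counts))]

    net = MultiResolutionNet(
        NetConfig(
            n_inputs=corpus.streams[0].H.shape[0],
            strides=config.strides,
            hidden=config.hidden,
            fc1_units=config.fc1_units,
            n_classes=n_classes,
            buffer_len=config.buffer_len,
            dtype=config.dtype,
        ),
        seed=config.seed,
    )
    stage1_params = [k for k in net.params if not k.startswith(("W2", "b2"))]
    if config.optimizer == "sgd":
        opt = SGD({k: net.params[k] for k in stage1_params},
                  momentum=config.momentum, clip_norm=config.clip_norm)
    elif config.optimizer == "adam":
        opt = Adam({k: net.params[k] for k in stage1_params},
                   clip_norm=config.clip_norm)
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    model = ForecastModel(
        net=net,
        config=config,
        classes=config.classes,
        class_weights=weights,
        fallback_label=fallback,
    )

    best_state, best_acc = net.state_dict(), -1.0
    log = {"epoch": [], "loss": [], "val_accuracy": []}
    denom = max(config.epochs - 1, 1)
    for epoch in range(config.epochs):
        lr = config.lr_start + (config.lr_end - config.lr_start) * epoch / denom
        order = rng.permutation(len(pairs))
        losses = []
        for i in range(0, len(order), config.batch_size):
            batch = pairs[order[i : i + config.batch_size]]
            xs, y = _gather_batch(corpus, batch)
            logp, cache = net.stage1_forward(xs, need_cache=True)
            loss, dlogits = weighted_nll(logp, y, weights)
            grads = net.stage1_backward(cache, dlogits)
            opt.step(grads, lr)
            if not np.isfinite(loss):
                raise FloatingPointError("NaN loss during stage-1 training")
            losses.append(loss)
        if (epoch + 1) % config.val_every == 0 or epoch == config.epochs - 1:
            vacc = _split_accuracy(model, corpus, corpus.val)
            log["epoch"].append(epoch)
            log["loss"].append(float(np.mean(losses)))
            log["val_accuracy"].append(vacc)
            if vacc >= best_acc:
                best_acc = vacc
                best_state = net.state_dict()
            logger.info(
                "epoch %d/%d: loss %.4f, val accuracy %.3f (best %.3f)",
                epoch + 1, config.epochs, log["loss"][-1], vacc, best_acc,
            )
    net.load_state_dict(best_state)

    # ---- stage 2: buffered transition layer -------------------------
    feats_parts, y2_parts = [], []
    for si, (ds, idx) in enumerate(zip(corpus.streams, corpus.train)):
        if len(idx) == 0:
            continue
        anchors = idx[:: config.train_stride]
        L = config.buffer_len
        need = np.unique(np.concatenate([anchors - k for k in range(L + 1)]))
        need = need[(need >= ds.first_valid) & (need < ds.n_frames)]
        logp = model.stage1_log_probs(ds, need)
        by_frame = {int(t): logp[i] for i, t in enumerate(need)}
        feats_parts.append(model._fc2_features(by_frame, anchors))
        y2_parts.append(ds.targets(anchors))
    feats = np.concatenate(feats_parts, axis=0)
    y2 = np.concatenate(y2_parts)
    fc2_opt = Adam({k: net.params[k] for k in ("W2", "b2")}, clip_norm=np.inf)
    for _ in range(config.fc2_epochs):
        logp2 = net.fc2_forward(feats)
        loss2, dlog = weighted_nll(logp2, y2, weights)
        grads2 = net.fc2_backward(feats, dlog)
        fc2_opt.step(grads2, config.fc2_lr)
    log["fc2_final_loss"] = float(loss2)

    model.best_val_accuracy = best_acc
    model.training_log = log
    return model
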