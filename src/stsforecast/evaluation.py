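"""Performance measures for motion-state prediction.

Frame-wise accuracy is the fraction of frames whose predicted label
matches the ground truth (Kronecker delta), in percent.  Class metrics
are one-vs-rest precision / recall / F1.  Transition timing error is
the signed offset (ms) between each ground-truth transition onset and
the nearest predicted onset of the same transition type within a +/-1 s
search window (positive: prediction late).  The frame-wise false
detection rate (FDR) is the fraction of ground-truth hold-state frames
predicted as the following transition state.  Confusion matrices are
row-normalized to percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import base_state, is_transition


def _as_labels(x) -> np.ndarray:
    if hasattr(x, "labels"):
        x = x.labels
    return np.asarray(x).astype(str)


def accuracy(pred, truth) -> float:
    """Frame-wise accuracy in percent."""
    p, t = _as_labels(pred), _as_labels(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must have equal length")
    if p.size == 0:
        raise ValueError("accuracy undefined for empty sequences")
    return 100.0 * float(np.mean(p == t))


def class_metrics(pred, truth, classes=None) -> pd.DataFrame:
    """One-vs-rest precision / recall / F1 per class.

    Classes absent from both sequences get NaN metrics (undefined, not
    zero); F1 is 0 when precision + recall = 0.
    """
    p, t = _as_labels(pred), _as_labels(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must have equal length")
    if classes is None:
        classes = sorted(set(p) | set(t))
    rows = []
    for c in classes:
        tp = int(np.sum((p == c) & (t == c)))
        fp = int(np.sum((p == c) & (t != c)))
        fn = int(np.sum((p != c) & (t == c)))
        if tp + fp + fn == 0:
            rows.append((c, np.nan, np.nan, np.nan, 0))
            continue
        prec = tp / (tp + fp) if tp + fp else np.nan
        rec = tp / (tp + fn) if tp + fn else np.nan
        if np.isnan(prec) or np.isnan(rec) or prec + rec == 0:
            f1 = 0.0 if not (np.isnan(prec) and np.isnan(rec)) else np.nan
        else:
            f1 = 2 * prec * rec / (prec + rec)
        rows.append((c, prec, rec, f1, tp + fn))
    return pd.DataFrame(
        rows, columns=["class", "precision", "recall", "f1", "support"]
    ).set_index("class")


def transition_onsets(labels) -> list[tuple[str, int]]:
    """(state, frame) for every entry into a transition state."""
    lab = _as_labels(labels)
    out = []
    for i in range(1, len(lab)):
        if lab[i] != lab[i - 1] and is_transition(lab[i]):
            out.append((str(lab[i]), i))
    if len(lab) and is_transition(lab[0]):
        out.insert(0, (str(lab[0]), 0))
    return out


@dataclass
class TimingResult:
    errors_ms: list[float]
    matched: list[tuple[str, int, int]]  # (state, truth_frame, pred_frame)
    misses: int

    @property
    def mean_ms(self) -> float:
        return float(np.mean(self.errors_ms)) if self.errors_ms else float("nan")

    @property
    def mean_abs_ms(self) -> float:
        return (
            float(np.mean(np.abs(self.errors_ms))) if self.errors_ms else float("nan")
        )

    @property
    def sd_ms(self) -> float:
        return float(np.std(self.errors_ms)) if self.errors_ms else float("nan")


def transition_timing_error(
    pred, truth, fs: float, window_s: float = 1.0
) -> TimingResult:
    """Signed onset timing errors (ms), one per matched truth transition.

    Each ground-truth onset is matched to the nearest unused predicted
    onset of the same transition type within ``window_s``; unmatched
    transitions are counted as misses and excluded from the mean.
    """
    p_on = transition_onsets(pred)
    t_on = transition_onsets(truth)
    max_d = window_s * fs
    used = set()
    errors, matched, misses = [], [], 0
    for state, tf in t_on:
        best, best_d = None, np.inf
        for k, (ps, pf) in enumerate(p_on):
            if k in used or ps != state:
                continue
            d = abs(pf - tf)
            if d < best_d:
                best, best_d = k, d
        if best is None or best_d > max_d:
            misses += 1
            continue
        used.add(best)
        pf = p_on[best][1]
        errors.append((pf - tf) / fs * 1000.0)
        matched.append((state, tf, pf))
    return TimingResult(errors, matched, misses)


def false_detection_rate(pred, truth, from_state: str, transition_state: str) -> float:
    """Percent of ``from_state`` truth frames predicted as the transition."""
    p, t = _as_labels(pred), _as_labels(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must have equal length")
    denom = int(np.sum(t == from_state))
    if denom == 0:
        raise ValueError(f"no ground-truth frames of state {from_state!r}")
    false = int(np.sum((t == from_state) & (p == transition_state)))
    return 100.0 * false / denom


def confusion_matrix(pred, truth, classes=None, normalize: bool = True) -> pd.DataFrame:
    """Confusion counts (rows: truth, cols: prediction); row-normalized
    to percentages by default.  Empty rows are NaN when normalized."""
    p, t = _as_labels(pred), _as_labels(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must have equal length")
    if classes is None:
        classes = sorted(set(p) | set(t))
    classes = list(classes)
    lut = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)))
    for a, b in zip(t, p):
        M[lut[a], lut[b]] += 1
    if normalize:
        sums = M.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            M = 100.0 * M / sums
    return pd.DataFrame(M, index=classes, columns=classes)


@dataclass
class EvalReport:
    """Bundle of all prediction-quality measures for one evaluation run."""

    accuracy_percent: float
    metrics: pd.DataFrame
    confusion_percent: pd.DataFrame
    timing: TimingResult
    fdr: pd.DataFrame
    n_samples: int
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"samples evaluated : {self.n_samples}",
            f"accuracy          : {self.accuracy_percent:.2f} %",
            f"timing error      : {self.timing.mean_ms:+.1f} ms "
            f"(|mean| {self.timing.mean_abs_ms:.1f} ms, sd {self.timing.sd_ms:.1f} ms, "
            f"misses {self.timing.misses})",
        ]
        return "\n".join(lines)


def evaluate_predictions(
    pred, truth, fs: float, classes=None, fdr_pairs=None
) -> EvalReport:
    """All measures on one aligned (prediction, truth) label pair."""
    p, t = _as_labels(pred), _as_labels(truth)
    fdr_pairs = fdr_pairs or [
        ("Sitting", s) for s in sorted(set(t)) if base_state(s) == "SiTSt"
    ] + [("Standing", s) for s in sorted(set(t)) if base_state(s) == "StTSi"]
    fdr_rows = []
    for frm, trans in fdr_pairs:
        try:
            rate = false_detection_rate(p, t, frm, trans)
        except ValueError:
            rate = np.nan
        fdr_rows.append((frm, trans, rate))
    return EvalReport(
        accuracy_percent=accuracy(p, t),
        metrics=class_metrics(p, t, classes),
        confusion_percent=confusion_matrix(p, t, classes),
        timing=transition_timing_error(p, t, fs),
        fdr=pd.DataFrame(fdr_rows, columns=["from_state", "transition", "fdr_percent"]),
        n_samples=len(p),
    )
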