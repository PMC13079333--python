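"""End-to-end orchestration: simulate -> preprocess -> segment -> synergy
-> windows -> train -> stream-predict -> evaluate.

The global seed is propagated to every stochastic stage (generator, NMF
restarts, network initialization and minibatch shuffling).  Per-muscle
normalization scales and the spatial synergy matrix are fitted on the
chronological training split only and then applied to the full streams,
so no information flows backwards from the held-out segments.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import evaluation, io, synergy
from .config import PipelineConfig, config_hash, save_config
from .forecaster import (
    ForecastModel,
    WindowCorpus,
    build_windows,
    chronological_split,
    train_forecaster,
)
from .preprocess import (
    ActivationMatrix,
    EmgRecording,
    bandpass_rectify_smooth,
    downsample_pool,
    normalize_per_muscle,
)
from .segmentation import MarkerTrajectory, StateSequence, segment_states
from .states import STRATEGIES
from .synthgen import SynthTrial, generate_trial

logger = logging.getLogger("stsforecast")


@dataclass
class PipelineResult:
    """Artifacts of one full pipeline run."""

    report: evaluation.EvalReport
    per_strategy: dict[str, evaluation.EvalReport]
    order: synergy.OrderSelection | None
    W: np.ndarray
    model: ForecastModel
    splits: dict[str, tuple[int, int]]
    config: PipelineConfig
    out_dir: Path | None = None


def _activation_stream(cfg: PipelineConfig, trial: SynthTrial) -> np.ndarray:
    """Un-normalized activation envelopes at ``analysis_fs`` (K x T')."""
    if cfg.activation_source == "envelopes":
        env = trial.true_envelopes
    else:
        rec = EmgRecording(
            trial.raw_emg, trial.fs, trial.config.muscle_names, strategy=trial.strategy
        )
        env = bandpass_rectify_smooth(rec, normalize=False).values
    return downsample_pool(env, trial.fs, cfg.analysis_fs)


def _segment(cfg: PipelineConfig, trial: SynthTrial) -> StateSequence:
    hip = downsample_pool(trial.hip_height, trial.fs, cfg.analysis_fs)
    t = np.arange(hip.size) / cfg.analysis_fs
    return segment_states(MarkerTrajectory(t, hip), strategy=trial.strategy)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    cfg = config
    logger.info("pipeline start (seed=%d, config=%s)", cfg.seed, config_hash(cfg))
    # propagate the global seed into every stochastic stage
    synth_cfg = dataclasses.replace(cfg.synth, rng_seed=cfg.seed)
    fc_cfg = dataclasses.replace(cfg.forecast, seed=cfg.seed)

    # ---- simulate ----------------------------------------------------
    if not cfg.simulate:
        raise NotImplementedError(
            "only the simulated-corpus pipeline is wired end to end; "
            "use the library functions directly for external recordings"
        )
    trials = {s: generate_trial(synth_cfg, s) for s in STRATEGIES}

    # ---- preprocess + segment ---------------------------------------
    envs = {s: _activation_stream(cfg, tr) for s, tr in trials.items()}
    seqs = {s: _segment(cfg, tr) for s, tr in trials.items()}
    for s in STRATEGIES:
        n = min(envs[s].shape[1], len(seqs[s].labels))
        envs[s] = envs[s][:, :n]
        seqs[s] = StateSequence(
            seqs[s].time_s[:n], seqs[s].labels[:n], seqs[s].transitions, seqs[s].strategy
        )
    splits = {s: chronological_split(seqs[s].to_four_class(), cfg.split_fractions)
              for s in STRATEGIES}

    # ---- normalization and synergy model on the training split ------
    train_parts = [envs[s][:, : splits[s][0]] for s in STRATEGIES]
    _, scale = normalize_per_muscle(np.concatenate(train_parts, axis=1))
    muscle_names = tuple(synth_cfg.muscle_names)
    A_train = ActivationMatrix(
        np.concatenate(train_parts, axis=1) / scale[:, None],
        cfg.analysis_fs,
        muscle_names,
        scale=scale,
    )
    order = None
    if cfg.n_synergies == "auto":
        order = synergy.select_order(
            A_train,
            restarts=cfg.nmf.restarts,
            seed=cfg.seed,
            vaf_threshold=cfg.nmf.vaf_threshold,
            mse_threshold=cfg.nmf.mse_threshold,
            max_iter=cfg.nmf.max_iter,
        )
        n_syn = order.n
        model_n = order.models.get(n_syn)
        logger.info("order selection: n=%d (criteria %s)", n_syn,
                    "met" if order.satisfied else "NOT met")
    else:
        n_syn = int(cfg.n_synergies)
        model_n = None
    if model_n is None:
        model_n = synergy.fit_nmf(
            A_train, n_syn, restarts=cfg.nmf.restarts, seed=cfg.seed,
            max_iter=cfg.nmf.max_iter,
        )
    W = model_n.W

    # ---- temporal patterns under fixed W, windows, training ---------
    streams, stream_splits = [], []
    for s in STRATEGIES:
        A_full = envs[s] / scale[:, None]
        H = synergy.estimate_temporal(A_full, W)
        streams.append(build_windows(H, seqs[s], fc_cfg, name=s))
        stream_splits.append(splits[s])
    corpus = WindowCorpus.from_streams(streams, stream_splits)
    model = train_forecaster(corpus, fc_cfg)
    model.W_spatial = W
    model.activation_scale = scale

    # ---- held-out prediction and evaluation -------------------------
    per_strategy: dict[str, evaluation.EvalReport] = {}
    all_pred, all_truth = [], []
    all_timing_errors, all_matched, all_misses = [], [], 0
    hf = fc_cfg.horizon_frames
    for si, s in enumerate(STRATEGIES):
        ds, idx = corpus.streams[si], corpus.test[si]
        pred = model.predict_batch(ds, idx, hard_filter=cfg.hard_filter)
        truth = np.asarray(seqs[s].labels)[idx + hf]
        rep = evaluation.evaluate_predictions(
            pred, truth, cfg.analysis_fs, classes=list(fc_cfg.classes)
        )
        per_strategy[s] = rep
        all_pred.append(pred)
        all_truth.append(truth)
        all_timing_errors.extend(rep.timing.errors_ms)
        all_matched.extend(rep.timing.matched)
        all_misses += rep.timing.misses
    pred = np.concatenate(all_pred)
    truth = np.concatenate(all_truth)
    report = evaluation.EvalReport(
        accuracy_percent=evaluation.accuracy(pred, truth),
        metrics=evaluation.class_metrics(pred, truth, list(fc_cfg.classes)),
        confusion_percent=evaluation.confusion_matrix(pred, truth, list(fc_cfg.classes)),
        timing=evaluation.TimingResult(all_timing_errors, all_matched, all_misses),
        fdr=evaluation.evaluate_predictions(
            pred, truth, cfg.analysis_fs, classes=list(fc_cfg.classes)
        ).fdr,
        n_samples=len(pred),
        extras={"per_strategy_accuracy": {
            s: per_strategy[s].accuracy_percent for s in STRATEGIES}},
    )
    logger.info("held-out accuracy %.2f %%, |timing| %.1f ms",
                report.accuracy_percent, report.timing.mean_abs_ms)

    # ---- persist -----------------------------------------------------
    out_dir = None
    if cfg.save_artifacts:
        out_dir = Path(cfg.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_config(cfg, out_dir / "config.yaml")
        syn_names = [f"Syn{i + 1}" for i in range(W.shape[1])]
        io.write_matrix(out_dir / "spatial_patterns.csv", W, muscle_names, syn_names)
        io.save_model(model, out_dir / "model")
        for s in STRATEGIES:
            io.write_trial(trials[s], out_dir, f"trial_{s}")
        with open(out_dir / "report.txt", "w") as fh:
            fh.write(report.summary() + "\n\nPer-class metrics\n")
            fh.write(report.metrics.to_string() + "\n\nConfusion (% by row)\n")
            fh.write(report.confusion_percent.round(2).to_string() + "\n")
        report.confusion_percent.to_csv(out_dir / "confusion_percent.csv")
        report.metrics.to_csv(out_dir / "class_metrics.csv")

    return PipelineResult(
        report=report,
        per_strategy=per_strategy,
        order=order,
        W=W,
        model=model,
        splits=splits,
        config=cfg,
        out_dir=out_dir,
    )
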