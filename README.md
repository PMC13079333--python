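# stsforecast

Muscle-synergy analysis and anticipatory motion-state forecasting for
sit-to-stand / stand-to-sit (STS) transitions from surface EMG.

Standing up and sitting down are the two most safety-critical
transitions of daily living, and assistive devices (actuated chairs,
exoskeletons) must begin acting *before* the movement is externally
visible.  Muscle activation precedes motion, so EMG carries the needed
lead time — but raw eight-channel EMG is high-dimensional and varies
with the movement strategy (fast *momentum-transfer* vs slow
*stabilization* execution).  This package implements a complete chain
for researchers in neuromuscular biomechanics and assistive robotics:

1. **Activation envelopes** — zero-phase Butterworth band-pass
   (20–450 Hz), rectification, 4 Hz low-pass, per-muscle unit-max
   normalization; plus a strictly causal scalar Kalman alternative for
   real-time use.
2. **Ground-truth segmentation** of the motion states
   S = {Sitting, SiTSt, Standing, StTSi} from the vertical hip-marker
   trajectory.
3. **Muscle synergies** — non-negative matrix factorization
   A ≈ W·H (spatial patterns W: muscles × n, temporal patterns
   H: n × time) over concatenated trials (CNMF), with the model order
   chosen as the smallest n (1 ≤ n ≤ K) satisfying VAF ≥ 90 % and
   MSE ≤ 10⁻⁵; cosine-similarity matching of spatial patterns; and
   per-frame non-negative least squares Ĥ(t) = A(t) \ W for sequential
   estimation under fixed W.
4. **Anticipatory forecasting** of S(t + Δt) (default Δt = 300 ms) from
   the temporal patterns H at 100 Hz: four LSTM branches over
   average-pooled input (strides 1, 2, 4, 8; 100 steps each), a fully
   connected classifier, and a buffered second stage over the last 15
   posteriors that suppresses physically impossible state jumps.  The
   recurrent network and its training loop are implemented directly in
   numpy (gradients verified by finite differences) — no deep-learning
   runtime required.
5. **Evaluation** — frame-wise accuracy, per-class precision/recall/F1,
   signed transition-onset timing error, frame-wise false detection
   rate, and row-normalized confusion matrices.

Because participant recordings are not distributed, the package
includes a tested synthetic-data generator that reproduces the
structure the analysis assumes: eight-muscle envelopes driven by four
latent synergies with strategy-dependent amplitude/duration/timing, a
repeating Sitting → SiTSt → Standing → StTSi cycle with ≥ 5 s holds,
preparatory activation beginning 500 ms before hip movement, and the
hip-height trajectory used for segmentation.  See `docs/methods.md` for
the model, its assumptions, and what the synthetic corpus can and
cannot demonstrate.

## Worked example

```python
from stsforecast import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1)     # default synthetic corpus, 300 ms horizon
result = run_pipeline(cfg)
print(result.order.n)            # model order chosen by the VAF/MSE criterion
print(result.report.summary())
```

prints

```
4
samples evaluated : 3465
accuracy          : 99.54 %
timing error      : +2.5 ms (|mean| 22.5 ms, sd 29.5 ms, misses 0)
```

Reading: on the default two-strategy corpus the order criterion selects
four synergies (three per individual motion — each motion uses three of
the four).  A scaled-down forecaster (100 epochs, 32 hidden units per
branch) trained on the chronological 80 % split predicts the motion
state 300 ms ahead on the held-out 10 % split with 99.5 % frame
accuracy; the four held-out transitions are detected 22.5 ms (mean
absolute) from their true onsets with no missed transition.  The same
run writes the spatial patterns, per-class metrics, confusion matrix
and a model checkpoint under `cfg.out_dir`.

The command-line interface exposes each stage separately
(`stsforecast simulate | preprocess | segment | synergy | train |
predict | evaluate | run-all`); `stsforecast run-all --seed 1` is the
CLI twin of the snippet above.

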