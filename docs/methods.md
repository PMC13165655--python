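# Methods

`edgebp` benchmarks compact 1D convolutional networks for cuffless blood
pressure estimation from single-channel photoplethysmography (PPG), with
full-integer INT8 post-training quantization and deployment-feasibility
accounting as first-class evaluation axes. This note documents the models,
the synthetic data, the numerical choices, and what the package's tests do
and do not demonstrate.

## Problem and pipeline

The regression task maps an 8.192 s window of normalized PPG (1024 samples
at 125 Hz) to the systolic and diastolic arterial pressures (SBP, DBP, in
mmHg) observed in the simultaneously recorded arterial blood pressure (ABP)
waveform over that window: SBP is the window maximum, DBP the window
minimum. The conditioning chain is:

1. **Record selection** — keep records at least eight minutes long
   (60,000 samples), with finite, non-constant channels, and with no ABP
   excursion above 200 mmHg (strictly). Both thresholds are parameters;
   desk-scale experiments on shorter synthetic records pass the actual
   record duration as the minimum.
2. **Detrending** — least-squares removal of the best-fit line over the
   full record (a moving-average high-pass is available behind a flag).
3. **Min–max normalization** to [0, 1], per record.
4. **Segmentation** — 1024-sample windows with 75% overlap (hop 256);
   window count per record is floor((N − 1024)/256) + 1.
5. **Splitting** — window-level random 70/30 train/test partition, removal
   of test windows whose PPG vectors are bitwise identical to any
   training-pool window (the training side is left intact), then an 80/20
   train/validation split with a fixed shuffle seed of 42. Counts use
   round-half-up. The window-level split deliberately mirrors the
   leakage-prone protocol common in this literature; a subject-wise
   splitter is provided as a non-default mode.

## Synthetic cohort

No real waveforms ship with the package; a generator produces paired
PPG+ABP records with known per-beat ground truth.

**Population laws.** Per-record SBP targets follow a truncated normal on
[78.25, 199.87] mmHg centred at 139.01 (scale 24); DBP targets follow a
shifted log-normal 50 + LogNormal(ln 11.49, 0.52) truncated to
[50.00, 158.02], giving a median near 61.5 and positive skew. Pairs with
DBP > SBP − 10 are rejected and redrawn. These reproduce the support,
medians and skew direction of the public cuff-less dataset the evaluation
emulates; the shape parameters were fixed once and are not fitted.

**Beat model.** Each beat's ABP is dbp + (sbp − dbp)·g(t), with g a
systolic Gaussian lobe plus a dicrotic Gaussian lobe, rescaled to
min 0 / max 1 — so the noise-free ABP attains each beat's systolic and
diastolic targets *exactly*, and window labels have exact ground truth by
construction regardless of morphological realism. The PPG is a
low-pass-filtered (2nd-order Butterworth, 8 Hz, zero-phase on a periodic
extension), lag-shifted (0.2 s default) copy normalized to unit amplitude.
Baseline wander (0.25 Hz sinusoid, amplitude 0.05) and white noise
(SD 0.02 of unit pulse amplitude) corrupt the PPG only; a slow 0.01 Hz
sinusoidal drift (±5 mmHg) and 3% heart-rate jitter vary the beats within
a record.

**Morphology–pressure coupling.** Because the pipeline min–max normalizes
each record, PPG amplitude carries no pressure information. The generator
therefore couples waveform *shape* to the targets: higher SBP gives a
faster heart rate, a narrower systolic upstroke and a weaker dicrotic
wave; the dicrotic delay encodes DBP. The coupling is deterministic and
far sharper than the subject-dependent, confounded relation in real PPG.
Consequences: models trained on this cohort reach error dispersions
(SD ≈ 2–4 mmHg at desk scale) that say nothing about real-data accuracy;
what the synthetic protocol *does* exercise faithfully is the numerical
machinery — windowing and labeling, training dynamics, and especially the
float-vs-integer comparison, whose rounding and range-compression effects
do not depend on the data being real.

**Invalid-record injection.** Deterministic counts (round, not Bernoulli):
round(fraction_short·n) records are generated short of the eight-minute
boundary and round(fraction_high_abp·n) records get one mid-record beat
with a systolic target above 200 mmHg, so filter tests assert exact
counts.

## Architectures

Five families, all over a (1024, 1) input with a two-unit linear head
(raw mmHg; no label scaling), ReLU after every convolution, no
normalization layers anywhere (which also keeps the integer engine free of
folding logic):

| family | structure | params |
|---|---|---|
| `baseline_cnn` | 4 same-padding convs (k=5; 8→24→34→68 filters), max-pool 4 after each, flatten, dense 62, dense 2 | 33,826 |
| `residual_cnn` | stem conv (k=5, 42) + pool 4; four residual stages (42,104,132,172), two convs per block, identity shortcuts, 1×1 projection at channel changes, pool 4 between stages; flatten head | 554,498 |
| `residual_cnn_slim` | same layout, reduced filters (28,46,62,92), global-average-pooling head | 140,034 |
| `mobilenet_1d` | stem conv (k=3, 8, stride 2); four depthwise (stride 2) + pointwise stages (16,34,66,104); GAP head | 10,738 |
| `micro_tcn` | stem conv (k=3, 26, stride 4); five residual blocks of dilated causal convs (k=7, 24 channels, dilations 1,2,4,8,16); GAP head | 41,698 |

The published record gives the structural families and their exact
parameter totals but not the layer widths; the configurations above were
found by a one-time constrained search over kernel sizes, stage widths and
dense width that lands exactly on the printed totals, and are frozen in
`src/edgebp/configs/*.yaml`. Because dilated causal convolutions are
stride-1 by contract, the TCN concentrates its downsampling in a stride-4
stem rather than per-stage strides.

## Training

The trainer is a self-contained numpy implementation (batched forward and
backward passes for every layer kind, Adam/AdamW). Protocols:

* `baseline_cnn`: Adam (lr 1e-3), MSE, **400 fixed epochs**, no early
  stopping, batch 128, seed 42.
* all others: AdamW (lr 8e-4, weight decay 1e-4), Huber loss (δ = 1.0,
  mean reduction over both outputs and all samples), early stopping with
  best-validation-weight restoration (patience 30), reduce-on-plateau
  (factor 0.5, patience 10, floor 1e-6), batch 128, seed 42.

The published patience values are ranges (30–35 and 10–12); the lower
ends are fixed as defaults and overridable per architecture. A **fast
profile** for desk-scale runs caps the early-stopping architectures at 60
epochs (patience 12 / plateau 5) and changes no optimizer hyperparameter.
The baseline keeps its full 400 epochs even in the fast profile: with no
early stopping, the fixed-epoch schedule is the training regime itself —
prolonged MSE training is what drives its weights and activation ranges
into the wide-dynamic-range state whose quantization behaviour the
benchmark studies — so shortening it would change the phenomenon, not just
the budget. Training runs in float32; exported models are float64 and are
parity-checked against the single-window reference executor.

## Full-integer INT8 quantization

Post-training, no retraining or fine-tuning:

* **Weights**: symmetric INT8, per output channel for convolutions,
  per tensor for dense kernels — the granularity split used by the
  reference full-integer converters. Scale = max|w|/127 (so −128 is never
  produced); biases INT32 at scale s_in·s_w.
* **Activations**: per-tensor asymmetric INT8 from plain min/max over a
  representative set of 512 training windows; ranges are widened to
  include zero and the zero point nudged so real 0 is exactly
  representable.
* **ReLU** is fused into the producing layer: calibration records
  post-activation ranges, and clamping at the output zero point realizes
  the nonlinearity. Max-pool runs directly on integers; GAP is an integer
  sum with rounded division at unchanged scale; residual adds requantize
  both addends to the output edge's scale before a saturating add.
* **Requantization**: M = s_in·s_w/s_out decomposed as a 31-bit mantissa
  with a rounding right shift; rounding is half away from zero everywhere;
  a float-multiplier mode exists for debugging and agrees within 1 LSB.
* Integer matrix accumulations are evaluated through float64 BLAS, which
  is exact for these magnitudes (all products and partial sums are far
  below 2^53), then requantized in genuine int64 arithmetic; a test
  perturbs every stored float scale in its last ulp and asserts the
  integer outputs are bitwise unchanged.

Degenerate zero-range edges receive a minimal positive scale (1e-8) and
are logged. The exact calibration statistic and rounding mode of
third-party converters are not published; small numeric differences from
any particular toolchain's INT8 models are expected.

## Evaluation

Signed error e = reference − estimate; ME = mean(e); SD = sample standard
deviation with the n−1 denominator; MAE = mean|e|; each for SBP and DBP
separately. |ME| ≤ 5 mmHg (inclusive) and SD < 8 mmHg (strict) are
attached to reports as *reference benchmarks* for retrospective
comparison — they are not clinical validation, and reports carry that
disclaimer verbatim. FP32↔INT8 consistency uses the Pearson correlation
of the paired predictions per output. Drift is reported as INT8-minus-
float deltas of ME/SD/MAE. A physiological check counts DBP > SBP
violations. Histogram tables (true/predicted distributions, error
distributions) are exported as binned CSV rather than rendered plots.

## Feasibility arithmetic

`weights_bytes` counts 1 byte per INT8 kernel element, 4 per INT32 bias,
plus a documented qparams table (one float32 scale per weight channel and
per activation edge, one zero-point byte each). `activation_peak_bytes`
runs a liveness analysis over the graph's topological schedule: a tensor
is live from production until its last consumer executes; the peak is the
maximum summed size of simultaneously live INT8 tensors. This is a
different (and simpler) scheduler than any vendor toolchain's, so vendor
RAM figures will differ. The duty cycle is 100·latency_ms/(1000·window_s)
with the 8.192 s acquisition window; latency is a user-supplied input
(165.8 ms is the documented example), never a measurement.

## Desk-scale problem sizes

The shipped tests and the acceptance script train on synthetic cohorts of
48–100 two-minute records (≈2,600–5,500 windows), chosen so the full
two-model protocol (baseline at 400 epochs, slim at the fast profile)
completes on one CPU in minutes. The cohort's record duration is passed as
the minimum-duration filter in these runs. Observed desk-scale behaviour:
the slim residual model keeps FP32↔INT8 Pearson correlations above 0.99
for both outputs, and the baseline's systolic |ΔME| under quantization
exceeds the slim model's — the architecture-dependent drift ordering that
motivates quantization-aware model selection.

## Known limitations

* The synthetic morphology–pressure coupling is deterministic; real PPG
  is confounded by vascular compliance, contact pressure and motion.
  Passing tests demonstrate numerical correctness of the pipeline, not
  clinical accuracy.
* Single seed per training run (reproducibility over statistical
  robustness), as in the emulated protocol.
* The integer engine is bit-faithful but not performance-optimized, and
  no MCU code generation or on-device measurement is attempted.
* Serialized model sizes depend on this package's container format and are
  not comparable to third-party flatbuffer sizes.
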