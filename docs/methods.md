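# Methods

## Problem

Children with cerebral palsy (CP) walk with prolonged stance and shortened
swing; ankle exoskeletons that assist them need a phase-aware controller,
which in turn needs reliable recognition of the current gait phase from
wearable sensors under the high, non-stationary noise of pathological
gait. `gaitphase` implements a hybrid recognizer for the four canonical
phases of one stride —

| label | phase | interval |
|---|---|---|
| 0 | HS, heel strike | heel strike → toe strike |
| 1 | FC, full contact | toe strike → heel off |
| 2 | HO, heel off (push-off) | heel off → toe off |
| 3 | SW, swing | toe off → next heel strike |

— from a 12-channel ankle IMU stream (two six-axis units, 100 Hz), with
ground-truth phase boundaries derived from a 2-channel plantar-pressure
insole (heel + first metatarsal, 50 Hz) on the right foot.

## Pipeline

1. **Filtering.** The IMU stream is low-passed with a zero-phase 6th-order
   Butterworth filter. The default cutoff is 20 Hz: gait energy lives well
   below that, and a cutoff at or above the 50 Hz Nyquist frequency of a
   100 Hz stream is not realizable, so the Nyquist precondition is
   enforced. Zero-phase (forward–backward) application keeps detected
   event indices un-shifted at the cost of squaring the magnitude
   response.
2. **Event detection.** Each pressure channel is binarized at a fraction
   (default 0.5) of its own maximum; rising/falling heel edges give heel
   strike / heel off, metatarsal edges give toe strike / toe off. Edge
   indices are mapped to the IMU timeline by the integer rate ratio (×2).
   The merged event sequence must follow the cyclic order HS → TS → HO →
   TO; partial cycles at either end are trimmed, interior violations are
   an error naming the offending sample.
3. **Labeling.** Half-open intervals between consecutive events receive
   the phase label of the opening event; samples outside any complete
   interval are −1 and never reach the classifier.
4. **Normalization.** Per-channel z-score by default (min–max optional),
   always fitted on the training cohort only and applied frozen to
   held-out subjects. Constant channels get scale 1 to avoid division by
   ~0.
5. **Windowing.** Sliding windows of Lw = 50 frames, stride 1, each
   labeled by its **terminal** sample. The alternative reading — label =
   first sample *after* the window — is available via `label_offset=1`.
   Windows with undefined labels are dropped.
6. **Feature extraction (SDA).** A 12→40→8→40→12 autoencoder with ReLU
   activations. Corruption is dropout (p = 0.2) after each 40-unit
   expansion activation, active during training only; this is the
   denoising mechanism — no explicit input masking is applied. Training
   minimizes the batch-mean squared reconstruction error end to end with
   Adam (lr 1e-4). The classifier consumes the 12-D *reconstruction*
   (decoder output); the 8-D bottleneck code is exposed via
   `extract_features(..., use_code=True)`. The decoder output activation
   is ReLU, consistent with the rest of the stack; since z-scored inputs
   have negative support the reconstruction is a rectified approximation,
   which is harmless for classification (the features only need to be
   phase-discriminative) — a `linear` output option exists when faithful
   reconstruction matters.
7. **Classification (LSTM).** Two stacked LSTM layers of 50 units over
   the 50-frame feature windows; only the final hidden state feeds a
   4-way softmax head (many-to-one). Cross-entropy is minimized with Adam
   (lr 5e-5, ε = 1e-8, batch 64 by default). By default the autoencoder
   is frozen during this stage (two-phase training); `freeze_sda=False`
   backpropagates the classification loss into the autoencoder (joint
   fine-tuning, dropout off).

The forward pass, backpropagation through time and Adam are implemented
directly in numpy (float32). Gates use the standard (input, forget, cell,
output) parameterization; weights start uniform in ±1/√50 with
forget-gate biases at 1 for healthy gradient flow; ties in the softmax
argmax resolve to the smallest class index. With a fixed seed and thread
count, simulation, training and evaluation are bit-reproducible; all
randomness flows from `numpy.random.default_rng(seed)`.

Two learning rates appear because the two stages are separate
optimizations: 1e-4 for reconstruction pretraining, 5e-5 for the
classifier. Both, like every other hyperparameter, sit on
`TrainConfig`.

## Synthetic cohort

No public recordings of exoskeleton-assisted CP gait exist, so the study
conditions are emulated by `gaitphase.synth`:

- **Cohort.** Six subjects (five train, one held out), stance-dominated
  mean phase fractions (HS 0.10, FC 0.40, HO 0.15, SW 0.35) with small
  per-subject perturbations; cadence uniform in 0.8–1.0 strides/s;
  per-channel gains uniform in 0.85–1.15 (inter-subject heterogeneity);
  per-stride phase durations vary with CV 0.05; additive white IMU noise
  with s.d. 0.1 against unit-order waveforms (≈20 dB, "moderate").
- **Waveforms.** Each (channel, phase) pair has a distinct smooth
  trajectory (offset + two phase-locked sinusoids) drawn from a fixed
  deterministic coefficient table. These are fixture constants that make
  phases mutually discriminative; they claim nothing about real CP
  kinematics.
- **Pressure.** Nominal 1.0 during contact, 0.0 otherwise, plus small
  positive noise (s.d. 0.02) clipped at zero — binarization at half the
  channel maximum is unambiguous by construction, so the event-detection
  round trip (binarize → detect → label) reproduces the generative truth
  exactly. Phase boundaries are snapped to even IMU indices so every
  event is visible on the 50 Hz pressure grid; recordings start with a
  4-sample unlabeled lead-in (so the first heel strike produces an edge)
  and end on the heel strike closing the last cycle.

What the generator does **not** model: drift and orientation error of real
IMUs, pressure-sensor hysteresis and partial contact, double support
asymmetries, involuntary movements, spasticity-driven waveform
distortion, or any validated CP biomechanics. Passing tests therefore
demonstrate the correctness and noise behavior of the *pipeline*, not
clinical-grade accuracy on real CP gait.

## Evaluation

- **Metrics.** Overall accuracy = trace of the 4×4 confusion matrix over
  the sample count; per-phase accuracy = per-class recall (row-normalized
  diagonal). Rows are truth, columns predictions, order HS, FC, HO, SW.
- **Five-fold CV.** Random window-level split (seeded) into five folds of
  sizes within 1 of n/5; each fold validates once against a pipeline
  retrained from scratch with identical hyperparameters. Because stride-1
  windows overlap, window-level splitting leaks temporal context between
  folds; a contiguous `block` mode is provided as the hygienic
  alternative.
- **External validation.** Leave-one-subject-out: normalizer, SDA and
  LSTM see the training cohort only.
- **Noise robustness.** Additive white Gaussian noise at SNR ∈ {5, 10,
  15, 20, 25, 30} dB, where SNR_dB = 10·log10(P_signal/P_noise). Noise
  variance is calibrated per channel against the empirical mean-square of
  the clean data, and is injected into the normalized model inputs (what
  the classifier actually sees); a raw-signal mode exists by applying
  `inject_awgn` to a recording instead. Labels are never perturbed. The
  sweep reports per-phase recall and overall accuracy per level plus a
  no-noise row.

## Problem sizes

The scaled experiment used by the test suite and `scripts/acceptance.py`
runs six subjects × 200 strides, windows subsampled with step 10
(training and evaluation), SDA and LSTM trained 30 epochs each; the CV
leg uses step 30 and 8 epochs; SVM/RF baselines cap training at 6000
windows. These sizes were chosen once so the full protocol runs in
minutes on a single CPU core while keeping thousands of held-out windows
per report; the stride-1 window construction itself is unchanged (step
`s` only thins which window *starts* are kept). Full-scale defaults
(stride 1, 100 epochs) remain the library defaults on `TrainConfig`.

## Numerical choices and edge cases

- Probabilities are computed in float64 with a max-shifted softmax; a
  zero probability at the true class clamps at 1e-12 inside the log.
- Non-finite training loss aborts with a diagnostic rather than
  continuing silently.
- A zero-power channel cannot define an SNR; AWGN leaves it unchanged
  with a warning.
- Degenerate (constant) channels normalize to 0 (scale forced to 1).
- Empty event sets label everything −1; zero-length phases are legal in
  `label_phases` (half-open intervals), though the generator never emits
  them.
- `n_strides = 0` yields a valid empty recording.

## Known limitations

- Synthetic realism is deliberately minimal (see above); reported
  accuracies characterize the pipeline under its own generative model.
- The SVM/RF baselines use conventional defaults (RBF C=1; 200 trees) —
  no hyperparameter search is performed, so baseline gaps are indicative
  only.
- Event detection assumes clean binarized pressure; heavily corrupted
  pressure that produces interleaved edges is rejected, not repaired.
- Single-threaded bit-reproducibility is the guarantee; changing BLAS
  thread counts may change results in the last float digits.
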