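# gaitphase

Gait-phase recognition for children with cerebral palsy (CP) from
wearable sensors: a stacked denoising autoencoder (SDA) feeding a
two-layer LSTM classifies each moment of walking into the four canonical
phases of the stride — heel strike (HS), full contact (FC), heel off
(HO) and swing (SW). It is aimed at rehabilitation-engineering work
(e.g. phase-aware ankle-exoskeleton control), where the input is a
12-channel ankle IMU stream at 100 Hz and ground-truth phase boundaries
come from a two-channel plantar-pressure insole at 50 Hz.

Because no such clinical recordings are publicly available, the package
ships a synthetic multi-subject gait generator with CP-like,
stance-dominated phase structure and exact ground truth, so the entire
pipeline is testable end to end.

## Model

Windows of Lw = 50 normalized IMU frames (stride 1, label = terminal
sample) are passed frame-by-frame through a 12→40→8→40→12 ReLU
autoencoder trained to minimize

    L_SDA = (1/N) Σᵢ ‖xᵢ − x̂ᵢ‖²

with dropout (p = 0.2) as the stochastic corruption. The 12-D
reconstructions then feed a two-layer, 50-unit LSTM; only the final
hidden state h_T reaches the softmax head

    P(y = k | h_T) = exp(w_k·h_T + b_k) / Σⱼ exp(w_j·h_T + b_j),

trained by categorical cross-entropy with Adam
(θ ← θ − η·m̂/(√v̂ + ε), η = 5·10⁻⁵, ε = 10⁻⁸). Evaluation covers
five-fold cross-validation, leave-one-subject-out external validation,
SVM / random-forest / plain-LSTM baselines, and an additive white
Gaussian noise sweep calibrated by SNR_dB = 10·log₁₀(P_signal/P_noise).
The autoencoder, LSTM, backpropagation through time and Adam are
implemented in numpy; see `docs/methods.md` for the full account.

## Worked example

```python
import gaitphase as gp

# six synthetic subjects, five for training, one held out
cohort = gp.simulate_cohort(gp.default_cohort(6, base_seed=1), 200)
cfg = gp.TrainConfig(epochs=30, sda_epochs=30, rng_seed=1)
loso = gp.external_validate(cohort[:5], cohort[5], config=cfg, window_step=10)

print(f"held-out overall accuracy: {loso.report.overall_accuracy:.3f}")
print("per-phase recall (HS FC HO SW):",
      [round(r, 3) for r in loso.report.per_class_recall])
print(gp.robustness_sweep(loso.results, loso.test_windows, seed=1).round(3))
```

prints (about five minutes on one CPU core):

```
held-out overall accuracy: 0.974
per-phase recall (HS FC HO SW): [0.959, 0.956, 0.972, 1.0]
   snr_db     HS     FC     HO     SW    All
0     5.0  0.945  0.976  0.947  0.986  0.972
1    10.0  0.968  0.980  0.978  0.999  0.985
2    15.0  0.963  0.969  0.989  1.000  0.982
3    20.0  0.972  0.960  0.981  1.000  0.978
4    25.0  0.950  0.962  0.975  1.000  0.976
5    30.0  0.954  0.957  0.978  1.000  0.975
6     NaN  0.959  0.956  0.972  1.000  0.974
```

The last table is the robustness sweep: each row is the held-out
per-phase recall and overall accuracy after injecting white noise at the
given SNR into the model's inputs (the `NaN` row is the clean baseline).
Accuracy stays high because the synthetic waveforms are strongly
phase-discriminative; on real pathological gait the same protocol would
probe genuine robustness margins.

A command-line interface mirrors the library:

```sh
gaitphase simulate   --seed 1 --outdir run
gaitphase preprocess --seed 1 --outdir run
gaitphase train      --seed 1 --outdir run
gaitphase evaluate   --seed 1 --outdir run
gaitphase robustness --seed 1 --outdir run
```

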