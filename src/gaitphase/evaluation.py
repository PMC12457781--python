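"""Evaluation: confusion-matrix metrics, five-fold cross-validation,
leave-one-subject-out external validation, and the SNR-calibrated AWGN
robustness sweep.

Overall accuracy is the trace of the K x K confusion matrix divided by the
sample count; per-phase accuracy is per-class recall (the diagonal of the
row-normalized confusion matrix). Noise robustness is probed by injecting
additive white Gaussian noise into the model's test inputs at a requested
signal-to-noise ratio,

    SNR_dB = 10 * log10(P_signal / P_noise),

with the noise variance calibrated per channel against the empirical clean
signal power, and labels left unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .classifier import TrainConfig
from .model import SdaLstmModel, SdaLstmResults, build_windows
from .preprocess import N_CLASSES, WindowSet

__all__ = [
    "EvalReport",
    "NoiseSpec",
    "evaluate",
    "make_folds",
    "crossval_5fold",
    "external_validate",
    "ExternalValidation",
    "snr_to_power_ratio",
    "inject_awgn",
    "robustness_sweep",
    "SNR_LEVELS_DB",
]

#: The six SNR levels of the robustness protocol, in dB.
SNR_LEVELS_DB = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)

PHASE_NAMES = ("HS", "FC", "HO", "SW")


@dataclass
class EvalReport:
    """K x K confusion counts with overall accuracy and per-class recall.

    Rows are ground truth, columns predictions, class order HS, FC, HO, SW.
    ``per_class_recall[i]`` is NaN when class i never occurs in the truth.
    """

    confusion: np.ndarray
    n_samples: int
    overall_accuracy: float
    per_class_recall: np.ndarray

    @classmethod
    def from_labels(cls, true_labels, predicted_labels, K: int = N_CLASSES) -> "EvalReport":
        t = np.asarray(true_labels, dtype=np.int64).ravel()
        p = np.asarray(predicted_labels, dtype=np.int64).ravel()
        if t.shape != p.shape:
            raise ValueError(f"label vectors differ in length: {t.shape[0]} vs {p.shape[0]}")
        if t.size < 1:
            raise ValueError("need at least one label pair")
        if np.any((t < 0) | (t >= K)) or np.any((p < 0) | (p >= K)):
            raise ValueError(f"labels must lie in 0..{K - 1}")
        conf = np.zeros((K, K), dtype=np.int64)
        np.add.at(conf, (t, p), 1)
        n = int(conf.sum())
        oa = float(np.trace(conf)) / n
        row = conf.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            recall = np.where(row > 0, np.diag(conf) / row, np.nan)
        return cls(confusion=conf, n_samples=n, overall_accuracy=oa, per_class_recall=recall)

    def normalized(self) -> np.ndarray:
        """Row-normalized confusion matrix (NaN rows for absent classes)."""
        row = self.confusion.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, self.confusion / row, np.nan)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "n_samples": self.n_samples,
            "overall_accuracy": self.overall_accuracy,
            "per_class_recall": [None if np.isnan(r) else float(r) for r in self.per_class_recall],
            "class_order": list(PHASE_NAMES),
        }


def evaluate(true_labels, predicted_labels) -> EvalReport:
    """Confusion counts, overall accuracy and per-phase recall."""
    return EvalReport.from_labels(true_labels, predicted_labels)


def make_folds(n: int, n_folds: int = 5, seed: int = 0, mode: str = "window") -> list:
    """Partition indices 0..n-1 into `n_folds` folds.

    ``window`` mode shuffles indices before splitting (random window-level
    split); ``block`` mode splits contiguous segments, which avoids the
    train/validation leakage that overlapping stride-1 windows otherwise
    cause. Fold sizes differ by at most 1.
    """
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} windows for {n_folds}-fold CV, got {n}")
    if mode == "window":
        idx = np.random.default_rng(seed).permutation(n)
    elif mode == "block":
        idx = np.arange(n)
    else:
        raise ValueError("mode must be 'window' or 'block'")
    return [np.sort(f) for f in np.array_split(idx, n_folds)]


def crossval_5fold(
    windows: WindowSet,
    config: TrainConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
    mode: str = "window",
):
    """Five-fold cross-validation of the SDA-LSTM pipeline on one cohort.

    The folds partition the window set; each serves as validation exactly
    once while the pipeline (autoencoder + classifier) is retrained from
    scratch on the remaining folds with identical hyperparameters. Returns
    ``(reports, folds)``.
    """
    config = config or TrainConfig()
    folds = make_folds(len(windows), n_folds=n_folds, seed=seed, mode=mode)
    reports = []
    for k, val_idx in enumerate(folds):
        mask = np.ones(len(windows), dtype=bool)
        mask[val_idx] = False
        train_ws = windows.select(np.flatnonzero(mask))
        val_ws = windows.select(val_idx)
        res = SdaLstmModel(train_ws, config=replace(config, rng_seed=config.rng_seed + k)).fit()
        reports.append(evaluate(val_ws.labels, res.predict(val_ws)))
    return reports, folds


@dataclass
class ExternalValidation:
    """Outcome of a leave-one-subject-out run: report + fitted pipeline."""

    report: EvalReport
    results: SdaLstmResults
    test_windows: WindowSet
    train_windows: WindowSet


def external_validate(
    train_recordings,
    held_out,
    config: TrainConfig | None = None,
    Lw: int = 50,
    window_step: int = 1,
    cutoff: float | None = 20.0,
    norm_method: str = "zscore",
) -> ExternalValidation:
    """Cross-subject validation: fit on a training cohort, test on an
    unseen subject.

    Normalization statistics, the autoencoder and the classifier are all
    fitted on the training cohort only; the held-out recording is
    preprocessed with those frozen statistics. Any subject-id overlap
    between the cohorts is rejected.
    """
    train_ids = {r.subject_id for r in train_recordings}
    if held_out.subject_id in train_ids:
        raise ValueError(
            f"held-out subject {held_out.subject_id!r} also appears in the training cohort"
        )
    config = config or TrainConfig()
    train_ws, stats, streams = build_windows(
        train_recordings, Lw=Lw, window_step=window_step, cutoff=cutoff, norm_method=norm_method
    )
    test_ws, _, _ = build_windows(
        held_out, stats=stats, Lw=Lw, window_step=window_step, cutoff=cutoff, norm_method=norm_method
    )
    frames = np.concatenate(streams, axis=0).astype(np.float32)
    model = SdaLstmModel(train_ws, config=config, pretrain_frames=frames, norm_stats=stats)
    res = model.fit()
    report = evaluate(test_ws.labels, res.predict(test_ws))
    return ExternalValidation(report=report, results=res, test_windows=test_ws, train_windows=train_ws)


@dataclass(frozen=True)
class NoiseSpec:
    """AWGN level (SNR in dB, any real) and the seed of its realization."""

    snr_db: float
    rng_seed: int = 0


def snr_to_power_ratio(snr_db: float) -> float:
    """Signal-to-noise power ratio P_signal / P_noise = 10^(SNR_dB / 10)."""
    return float(10.0 ** (np.asarray(snr_db, dtype=float) / 10.0))


def inject_awgn(data, spec: NoiseSpec):
    """Return a noisy copy of windows or a recording at the requested SNR.

    Noise is zero-mean Gaussian per channel with variance equal to the
    channel's empirical mean-square signal power divided by the SNR power
    ratio. Labels and events are left untouched. A zero-power channel is
    left unchanged with a warning. Seeded: equal specs give equal noise.
    """
    ratio = snr_to_power_ratio(spec.snr_db)
    rng = np.random.default_rng(spec.rng_seed)

    def _noisy(x):
        x = np.asarray(x)
        power = np.mean(np.square(x.astype(np.float64)), axis=tuple(range(x.ndim - 1)))
        sd = np.sqrt(power / ratio)
        dead = power <= 0
        if np.any(dead):
            warnings.warn(f"{int(dead.sum())} zero-power channel(s) left unchanged by AWGN")
            sd = np.where(dead, 0.0, sd)
        return (x + sd * rng.standard_normal(x.shape)).astype(x.dtype)

    if isinstance(data, WindowSet):
        return WindowSet(
            _noisy(data.windows), data.labels.copy(), data.subject_ids.copy(), data.Lw, data.stride
        )
    # GaitRecording: perturb the IMU stream only
    out = replace(data) if hasattr(data, "__dataclass_fields__") else data
    out.imu = _noisy(data.imu)
    return out


def robustness_sweep(
    results: SdaLstmResults,
    test_windows: WindowSet,
    levels=SNR_LEVELS_DB,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate a trained pipeline on AWGN-corrupted copies of the test set.

    One row per SNR level (noise injected into the normalized model inputs,
    labels unchanged) plus a no-noise row. Columns: ``snr_db`` (NaN for the
    clean row), per-phase recalls ``HS FC HO SW``, and overall accuracy
    ``All``, all as fractions in [0, 1].
    """
    levels = list(levels)
    if not levels:
        raise ValueError("need at least one SNR level")
    rows = []
    for i, snr in enumerate(levels):
        noisy = inject_awgn(test_windows, NoiseSpec(snr_db=float(snr), rng_seed=seed + i))
        rep = evaluate(noisy.labels, results.predict(noisy))
        rows.append({"snr_db": float(snr), **dict(zip(PHASE_NAMES, rep.per_class_recall)), "All": rep.overall_accuracy})
    clean = evaluate(test_windows.labels, results.predict(test_windows))
    rows.append({"snr_db": np.nan, **dict(zip(PHASE_NAMES, clean.per_class_recall)), "All": clean.overall_accuracy})
    return pd.DataFrame(rows)
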