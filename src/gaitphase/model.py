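"""Model/Results interface for the SDA-LSTM gait-phase classifier.

`SdaLstmModel` is constructed from a labeled :class:`~gaitphase.preprocess.WindowSet`
(or directly from recordings via :meth:`SdaLstmModel.from_recordings`) and a
:class:`~gaitphase.classifier.TrainConfig`. Its :meth:`~SdaLstmModel.fit`
runs the two-stage training procedure — autoencoder pretraining on the
normalized frames, then LSTM training on the extracted features — and
returns an :class:`SdaLstmResults` carrying the fitted weights, the
training histories, and prediction/evaluation/summary methods.

The companion helper :func:`build_windows` assembles the standard
preprocessing chain for a recording: zero-phase low-pass filtering of the
IMU stream, pressure-driven event detection and phase labeling,
normalization with training-cohort statistics, and sliding-window
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classifier as _clf
from . import sda as _sda
from .classifier import LstmParams, TrainConfig
from .preprocess import (
    NormStats,
    WindowSet,
    apply_normalizer,
    binarize_pressure,
    detect_events,
    fit_normalizer,
    label_phases,
    lowpass_filter,
    make_windows,
)
from .sda import SdaParams

__all__ = ["SdaLstmModel", "SdaLstmResults", "build_windows", "preprocess_recording"]


def preprocess_recording(recording, cutoff: float | None = 20.0, norm_method: str = "zscore"):
    """Filter a recording and derive its per-sample phase labels.

    Returns ``(imu_filtered, labels)``. Labels come from the pressure
    stream (binarize -> detect events -> label phases), not from the
    recording's stored ground truth, so the same chain applies to real and
    synthetic data alike.
    """
    imu = recording.imu
    if cutoff is not None and imu.shape[0] > 18:
        imu = lowpass_filter(imu, recording.fs_imu, cutoff=cutoff)
    binary = binarize_pressure(recording.pressure)
    events = detect_events(binary, upsample_factor=int(round(recording.fs_imu / recording.fs_pressure)))
    labels = label_phases(events, imu.shape[0])
    return imu, labels


def build_windows(
    recordings,
    stats: NormStats | None = None,
    Lw: int = 50,
    window_step: int = 1,
    cutoff: float | None = 20.0,
    norm_method: str = "zscore",
    label_offset: int = 0,
):
    """Run the preprocessing chain over recordings and pool the windows.

    If `stats` is None, normalization statistics are fitted on the pooled
    filtered IMU streams of `recordings` (training mode); otherwise the
    given statistics are applied unchanged (held-out mode). Returns
    ``(WindowSet, NormStats, streams)`` where `streams` is the list of
    normalized per-recording streams (useful for autoencoder pretraining
    on non-redundant frames).
    """
    if not isinstance(recordings, (list, tuple)):
        recordings = [recordings]
    filtered, labels = [], []
    for rec in recordings:
        imu_f, lab = preprocess_recording(rec, cutoff=cutoff, norm_method=norm_method)
        filtered.append(imu_f)
        labels.append(lab)
    if stats is None:
        stats = fit_normalizer(np.concatenate(filtered, axis=0), method=norm_method)
    streams = [apply_normalizer(f, stats) for f in filtered]
    parts = []
    for rec, stream, lab in zip(recordings, streams, labels):
        if stream.shape[0] < Lw:
            continue
        parts.append(make_windows(stream, lab, Lw=Lw, s=window_step, subject_id=rec.subject_id, label_offset=label_offset))
    if not parts:
        raise ValueError("no recording long enough to produce windows")
    return WindowSet.concatenate(parts), stats, streams


class SdaLstmModel:
    """SDA-LSTM gait-phase model over labeled sliding windows.

    Parameters
    ----------
    windows : WindowSet
        Labeled training windows (normalized 12-D frames).
    config : TrainConfig, optional
        Training hyperparameters; full-scale defaults if omitted.
    pretrain_frames : (M, 12) array, optional
        Frames for autoencoder pretraining. Defaults to the frames of
        `windows`; passing the underlying normalized streams avoids the
        heavy duplication that stride-1 windows introduce.
    norm_stats : NormStats, optional
        Carried through to the results for held-out preprocessing.
    """

    def __init__(self, windows: WindowSet, config: TrainConfig | None = None,
                 pretrain_frames: np.ndarray | None = None, norm_stats: NormStats | None = None):
        if len(windows) == 0:
            raise ValueError("empty training window set")
        self.windows = windows
        self.config = config or TrainConfig()
        self.pretrain_frames = (
            np.asarray(pretrain_frames, dtype=np.float32)
            if pretrain_frames is not None
            else windows.windows.reshape(-1, windows.D)
        )
        self.norm_stats = norm_stats

    @classmethod
    def from_recordings(cls, recordings, config: TrainConfig | None = None,
                        Lw: int = 50, window_step: int = 1, cutoff: float | None = 20.0,
                        norm_method: str = "zscore") -> "SdaLstmModel":
        """Build the model straight from recordings (fits the normalizer)."""
        windows, stats, streams = build_windows(
            recordings, Lw=Lw, window_step=window_step, cutoff=cutoff, norm_method=norm_method
        )
        frames = np.concatenate(streams, axis=0).astype(np.float32)
        return cls(windows, config=config, pretrain_frames=frames, norm_stats=stats)

    def fit(self) -> "SdaLstmResults":
        """Two-stage fit: pretrain the autoencoder, then train the LSTM."""
        sda_params, sda_history = _sda.pretrain(self.pretrain_frames, self.config)
        lstm_params, lstm_history = _clf.train(self.windows, self.config, sda_params=sda_params)
        return SdaLstmResults(
            model=self,
            sda_params=sda_params,
            lstm_params=lstm_params,
            sda_history=sda_history,
            lstm_history=lstm_history,
        )


@dataclass
class SdaLstmResults:
    """Fitted SDA-LSTM model: weights, training histories, diagnostics."""

    model: SdaLstmModel
    sda_params: SdaParams
    lstm_params: LstmParams
    sda_history: list
    lstm_history: list

    @property
    def norm_stats(self) -> NormStats | None:
        return self.model.norm_stats

    def extract(self, windows: WindowSet) -> WindowSet:
        return _sda.extract_features(windows, self.sda_params)

    def predict(self, windows: WindowSet) -> np.ndarray:
        """Phase labels for new windows (frozen extractor + LSTM argmax)."""
        return _clf.predict(self.extract(windows), self.lstm_params)

    def predict_proba(self, windows: WindowSet) -> np.ndarray:
        return _clf.predict_proba(self.extract(windows), self.lstm_params)

    def evaluate(self, windows: WindowSet):
        """Confusion-matrix report of this model on labeled windows."""
        from .evaluation import evaluate as _evaluate

        return _evaluate(windows.labels, self.predict(windows))

    def history_frame(self):
        """Training history (epoch, loss, accuracy) as a DataFrame."""
        import pandas as pd

        return pd.DataFrame(self.lstm_history)

    def summary(self) -> str:
        cfg = self.model.config
        n_params = sum(v.size for v in self.lstm_params.as_dict().values()) + sum(
            v.size for v in self.sda_params.as_dict().values()
        )
        lines = [
            "SDA-LSTM gait-phase model",
            "=" * 54,
            f"training windows      : {len(self.model.windows)}  (Lw={self.model.windows.Lw}, D={self.model.windows.D})",
            f"pretraining frames    : {self.model.pretrain_frames.shape[0]}",
            f"total parameters      : {n_params}",
            f"autoencoder           : 12-40-8-40-12, dropout p={self.sda_params.dropout_p}",
            f"classifier            : 2-layer LSTM x 50 units, softmax K=4",
            f"epochs (SDA / LSTM)   : {cfg.sda_epochs} / {cfg.epochs}",
            f"learning rates        : SDA {cfg.lr_sda:g}, classifier {cfg.lr_classifier:g} (Adam, eps={cfg.eps:g})",
            f"final SDA loss        : {self.sda_history[-1]:.6f}",
            f"final train loss      : {self.lstm_history[-1]['loss']:.6f}",
            f"final train accuracy  : {self.lstm_history[-1]['accuracy']:.4f}",
            f"seed                  : {cfg.rng_seed}",
        ]
        return "\n".join(lines)
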