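"""Signal preprocessing: filtering, gait-event detection, phase labeling,
normalization and sliding-window construction.

The labeling chain is pressure-driven: the two plantar-pressure channels
(heel, first metatarsal) are binarized at a fraction of each channel's
maximum, their edges yield the four critical gait events

    heel strike -> toe strike -> heel off -> toe off -> heel strike ...

on the 50 Hz pressure grid, event indices are mapped onto the 100 Hz IMU
timeline, and half-open intervals between consecutive events receive phase
labels 0 (HS), 1 (FC), 2 (HO), 3 (SW). Samples outside any complete
interval are labeled -1 and later dropped at the windowing stage.

All indices are 0-based; all intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import signal as _sig

__all__ = [
    "EventKind",
    "GaitEventSet",
    "NormStats",
    "WindowSet",
    "lowpass_filter",
    "binarize_pressure",
    "detect_events",
    "label_phases",
    "fit_normalizer",
    "apply_normalizer",
    "make_windows",
]

N_CLASSES = 4


class EventKind(IntEnum):
    """The four critical gait events, in cyclic order."""

    HEEL_STRIKE = 0
    TOE_STRIKE = 1
    HEEL_OFF = 2
    TOE_OFF = 3

    @property
    def successor(self) -> "EventKind":
        return EventKind((self + 1) % 4)


@dataclass
class GaitEventSet:
    """Ordered gait events as (sample_index, kind) on the IMU timeline.

    Indices are strictly increasing and kinds follow the cyclic order
    HEEL_STRIKE -> TOE_STRIKE -> HEEL_OFF -> TOE_OFF -> ..., possibly
    truncated at either end.
    """

    events: list = field(default_factory=list)

    def __post_init__(self):
        evts = [(int(i), EventKind(k)) for i, k in self.events]
        for (i0, k0), (i1, k1) in zip(evts, evts[1:]):
            if i1 <= i0:
                raise ValueError(f"event indices must strictly increase (got {i0} then {i1})")
            if k1 != k0.successor:
                raise ValueError(
                    f"events out of cyclic order at sample {i1}: {k0.name} followed by {k1.name}"
                )
        self.events = evts

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def indices(self, kind: EventKind | None = None) -> np.ndarray:
        if kind is None:
            return np.array([i for i, _ in self.events], dtype=np.int64)
        return np.array([i for i, k in self.events if k == kind], dtype=np.int64)


@dataclass
class NormStats:
    """Per-channel location/scale fitted on training data only."""

    loc: np.ndarray
    scale: np.ndarray
    method: str = "zscore"

    def __post_init__(self):
        self.loc = np.asarray(self.loc, dtype=float).ravel()
        self.scale = np.asarray(self.scale, dtype=float).ravel()
        if self.loc.shape != self.scale.shape:
            raise ValueError("loc and scale must have the same length")
        if np.any(self.scale <= 0):
            raise ValueError("scale must be strictly positive")

    def to_dict(self) -> dict:
        return {"loc": self.loc.tolist(), "scale": self.scale.tolist(), "method": self.method}

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(np.array(d["loc"]), np.array(d["scale"]), d["method"])


@dataclass
class WindowSet:
    """Sliding windows X_i in R^{Lw x D} with one label per window.

    ``windows`` is (n, Lw, D) float32, ``labels`` length-n int64 in {0..3},
    ``subject_ids`` length-n array of the source subject per window.
    """

    windows: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    Lw: int
    stride: int = 1

    def __post_init__(self):
        self.windows = np.ascontiguousarray(self.windows, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids)
        n = self.windows.shape[0]
        if self.windows.ndim != 3 or self.windows.shape[1] != self.Lw:
            raise ValueError("windows must be (n, Lw, D)")
        if self.labels.shape != (n,) or self.subject_ids.shape != (n,):
            raise ValueError("labels/subject_ids must have one entry per window")

    @property
    def D(self) -> int:
        return self.windows.shape[2]

    def __len__(self) -> int:
        return self.windows.shape[0]

    def select(self, idx) -> "WindowSet":
        return WindowSet(self.windows[idx], self.labels[idx], self.subject_ids[idx], self.Lw, self.stride)

    @classmethod
    def concatenate(cls, parts: list["WindowSet"]) -> "WindowSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        Lw = parts[0].Lw
        if any(p.Lw != Lw for p in parts):
            raise ValueError("window lengths differ")
        return cls(
            np.concatenate([p.windows for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.subject_ids for p in parts]),
            Lw,
            parts[0].stride,
        )


def lowpass_filter(x: np.ndarray, fs: float, cutoff: float = 20.0, order: int = 6) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter, applied column-wise.

    The filter is applied forward-backward (``sosfiltfilt``) so gait-event
    indices are not phase-shifted; DC gain is exactly 1. `order` is the
    order of the underlying Butterworth design.
    """
    x = np.asarray(x, dtype=float)
    if cutoff <= 0 or cutoff >= fs / 2:
        raise ValueError(
            f"cutoff must lie in (0, fs/2) = (0, {fs / 2}) Hz to satisfy the Nyquist bound; got {cutoff}"
        )
    if x.shape[0] <= 3 * order:
        raise ValueError("signal too short for the filter order")
    sos = _sig.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, x, axis=0)


def binarize_pressure(pressure: np.ndarray, threshold_frac: float = 0.5) -> np.ndarray:
    """Binarize each pressure channel at a fraction of its own maximum.

    Output is 1 where value > threshold_frac * channel max, else 0; an
    all-zero channel stays all zero.
    """
    pressure = np.asarray(pressure, dtype=float)
    if np.any(pressure < 0):
        raise ValueError("pressure must be non-negative")
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must lie in (0, 1)")
    thresh = threshold_frac * pressure.max(axis=0, keepdims=True)
    return (pressure > thresh).astype(np.int8)


def _trim_to_cyclic(merged: list) -> list:
    """Trim end events so the kind sequence follows the cyclic order.

    `merged` is a list of (index, kind) sorted by index. A break interior to
    the sequence cannot be repaired and raises.
    """

    def first_break(ev):
        for j, ((_, k0), (_, k1)) in enumerate(zip(ev, ev[1:])):
            if k1 != k0.successor:
                return j
        return None

    ev = list(merged)
    while len(ev) >= 2 and first_break(ev) == 0:
        ev = ev[1:]
    while len(ev) >= 2 and first_break(ev) == len(ev) - 2:
        ev = ev[:-1]
    b = first_break(ev)
    if b is not None:
        idx = ev[b + 1][0]
        raise ValueError(
            f"pressure edges cannot form the cyclic event order: "
            f"{ev[b][1].name} followed by {ev[b + 1][1].name} at sample {idx}"
        )
    return ev


def detect_events(binary_pressure: np.ndarray, upsample_factor: int = 2) -> GaitEventSet:
    """Detect the four gait events from binarized heel/metatarsal pressure.

    Column 0 is the heel channel, column 1 the first metatarsal. A 0->1 heel
    edge is a HEEL_STRIKE, 1->0 a HEEL_OFF; metatarsal edges give TOE_STRIKE
    and TOE_OFF. Edge indices are multiplied by `upsample_factor` to land on
    the IMU timeline. End events that cannot fit the cyclic order are
    trimmed; an interior violation raises.
    """
    b = np.asarray(binary_pressure)
    if b.ndim != 2 or b.shape[1] != 2:
        raise ValueError("binary_pressure must be Tp x 2 (heel, metatarsal)")
    if b.shape[0] == 0:
        return GaitEventSet([])
    d = np.diff(b.astype(np.int8), axis=0)
    events = []
    for col, (on_kind, off_kind) in enumerate(
        [(EventKind.HEEL_STRIKE, EventKind.HEEL_OFF), (EventKind.TOE_STRIKE, EventKind.TOE_OFF)]
    ):
        for i in np.flatnonzero(d[:, col] == 1):
            events.append((int(i + 1) * upsample_factor, on_kind))
        for i in np.flatnonzero(d[:, col] == -1):
            events.append((int(i + 1) * upsample_factor, off_kind))
    events.sort(key=lambda e: (e[0], e[1]))
    return GaitEventSet(_trim_to_cyclic(events))


def label_phases(events: GaitEventSet, T: int) -> np.ndarray:
    """Assign per-sample phase labels from consecutive gait events.

    Half-open rules: [HEEL_STRIKE, TOE_STRIKE) -> 0, [TOE_STRIKE, HEEL_OFF)
    -> 1, [HEEL_OFF, TOE_OFF) -> 2, [TOE_OFF, next HEEL_STRIKE) -> 3.
    Samples outside any complete interval get -1. An empty event set yields
    all -1.
    """
    labels = np.full(T, -1, dtype=np.int64)
    evts = list(events)
    if any(i >= T for i, _ in evts):
        raise ValueError("event index beyond the end of the stream")
    for (i0, k0), (i1, _) in zip(evts, evts[1:]):
        labels[i0:i1] = int(k0)  # phase id == kind id of the opening event
    return labels


def fit_normalizer(imu: np.ndarray, method: str = "zscore") -> NormStats:
    """Fit per-channel normalization statistics on training data.

    ``zscore`` uses channel mean/s.d.; ``minmax`` maps the fitted range onto
    [0, 1]. A degenerate (constant) channel gets scale 1 and location equal
    to the constant, so it normalizes to 0.
    """
    imu = np.asarray(imu, dtype=float)
    if imu.ndim != 2 or imu.shape[0] < 2:
        raise ValueError("need a T x C matrix with T >= 2 to fit a normalizer")
    if method == "zscore":
        loc = imu.mean(axis=0)
        scale = imu.std(axis=0)
    elif method == "minmax":
        loc = imu.min(axis=0)
        scale = imu.max(axis=0) - loc
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    # guard degenerate (constant) channels against float-epsilon spreads
    degenerate = scale <= 1e-12 * np.maximum(1.0, np.abs(loc))
    scale = np.where(degenerate, 1.0, scale)
    return NormStats(loc, scale, method)


def apply_normalizer(imu: np.ndarray, stats: NormStats) -> np.ndarray:
    imu = np.asarray(imu, dtype=float)
    if imu.shape[1] != stats.loc.shape[0]:
        raise ValueError("channel count does not match the fitted statistics")
    return (imu - stats.loc[None, :]) / stats.scale[None, :]


def make_windows(
    imu_norm: np.ndarray,
    labels: np.ndarray,
    Lw: int = 50,
    s: int = 1,
    subject_id: str = "",
    label_offset: int = 0,
) -> WindowSet:
    """Cut a labeled stream into stride-`s` sliding windows of length `Lw`.

    Window i covers samples [i, i + Lw) and carries the label of its
    terminal sample (``label_offset=0``); ``label_offset=1`` selects the
    first sample after the window instead. Windows whose label is -1 (or
    whose label index falls off the stream) are dropped.
    """
    imu_norm = np.asarray(imu_norm, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    T = imu_norm.shape[0]
    if Lw < 1 or s < 1:
        raise ValueError("Lw and s must be >= 1")
    if label_offset not in (0, 1):
        raise ValueError("label_offset must be 0 (terminal sample) or 1 (next sample)")
    if T < Lw:
        raise ValueError(f"stream shorter than window: T={T} < Lw={Lw}")
    if labels.shape != (T,):
        raise ValueError("labels must align with the stream")

    starts = np.arange(0, T - Lw + 1, s)
    label_idx = starts + Lw - 1 + label_offset
    ok = label_idx < T
    starts, label_idx = starts[ok], label_idx[ok]
    win_labels = labels[label_idx]
    keep = win_labels >= 0
    starts, win_labels = starts[keep], win_labels[keep]

    view = np.lib.stride_tricks.sliding_window_view(imu_norm, Lw, axis=0)  # (T-Lw+1, C, Lw)
    windows = view[starts].transpose(0, 2, 1).astype(np.float32)
    subj = np.array([subject_id] * len(starts), dtype="U32")
    return WindowSet(windows, win_labels, subj, Lw, s)
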