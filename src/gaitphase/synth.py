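"""Synthetic multi-subject gait data: ankle IMU + plantar-pressure streams.

No public recordings exist for over-ground walking of children with mild
cerebral palsy wearing an ankle exoskeleton, so this module generates
surrogate trials with the statistical structure the recognition pipeline
assumes: a 12-channel IMU stream at 100 Hz whose mean trajectory is
phase-locked to the gait cycle, a 2-channel (heel, first-metatarsal)
plantar-pressure stream at 50 Hz that is "on" exactly during foot contact,
and exact ground-truth gait events and phase labels.

The four phases of one stride are

    0  HS  heel strike      [heel strike, toe strike)
    1  FC  full contact     [toe strike, heel off)
    2  HO  heel off         [heel off, toe off)
    3  SW  swing            [toe off, next heel strike)

The default cohort is stance-dominated (prolonged stance, shortened swing),
the hallmark asymmetry of CP gait, without claiming biomechanical fidelity:
waveform shapes are fixture constants chosen only to make phases mutually
discriminative.

Phase boundaries are forced onto even IMU sample indices so that the 50 Hz
pressure stream (even-indexed IMU timestamps, exact 2:1 decimation)
represents every event exactly and the event-detection round trip is
lossless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import EventKind, GaitEventSet, label_phases

__all__ = [
    "SubjectProfile",
    "GaitRecording",
    "simulate_subject",
    "simulate_cohort",
    "default_cohort",
    "DEFAULT_PHASE_FRACTIONS",
]

FS_IMU = 100.0
FS_PRESSURE = 50.0
N_IMU_CHANNELS = 12
N_PHASES = 4

#: Stance-dominated mean phase fractions (HS, FC, HO, SW) for CP-like gait.
DEFAULT_PHASE_FRACTIONS = (0.10, 0.40, 0.15, 0.35)

_LEAD_IN = 4  # unlabeled samples before the first heel strike (even)
_PRESSURE_NOISE_SD = 0.02  # small positive sensor noise, clipped at 0


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters for one synthetic subject.

    Parameters
    ----------
    subject_id : str
        Unique identifier.
    cadence_hz : float
        Strides per second (> 0). Children with mild CP walk slowly;
        defaults in :func:`default_cohort` sit near 0.9 strides/s.
    phase_fractions : tuple of 4 floats
        Mean fraction of the gait cycle spent in HS, FC, HO, SW.
        Each > 0, summing to 1.
    phase_cv : float
        Coefficient of variation of per-stride phase durations (>= 0).
    imu_noise_sd : float
        Additive white noise s.d. per IMU channel, in signal units (>= 0).
    amplitude_scale : tuple of 12 floats
        Per-channel multiplicative gains (> 0); models sensor placement
        and morphology differences between subjects.
    rng_seed : int
        Seed for this subject's noise and stride-timing randomness.
    """

    subject_id: str
    cadence_hz: float = 0.9
    phase_fractions: tuple = DEFAULT_PHASE_FRACTIONS
    phase_cv: float = 0.05
    imu_noise_sd: float = 0.1
    amplitude_scale: tuple = (1.0,) * N_IMU_CHANNELS
    rng_seed: int = 0

    def __post_init__(self):
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        if not self.cadence_hz > 0:
            raise ValueError(f"cadence_hz must be > 0, got {self.cadence_hz}")
        pf = np.asarray(self.phase_fractions, dtype=float)
        if pf.shape != (N_PHASES,):
            raise ValueError("phase_fractions must have exactly 4 entries")
        if np.any(pf <= 0):
            raise ValueError("phase_fractions must all be > 0")
        if abs(pf.sum() - 1.0) > 1e-9:
            raise ValueError(f"phase_fractions must sum to 1, got {pf.sum()!r}")
        if self.phase_cv < 0:
            raise ValueError("phase_cv must be >= 0")
        if self.imu_noise_sd < 0:
            raise ValueError("imu_noise_sd must be >= 0")
        amp = np.asarray(self.amplitude_scale, dtype=float)
        if amp.shape != (N_IMU_CHANNELS,):
            raise ValueError("amplitude_scale must have exactly 12 entries")
        if np.any(amp <= 0):
            raise ValueError("amplitude_scale entries must be > 0")
        object.__setattr__(self, "phase_fractions", tuple(pf))
        object.__setattr__(self, "amplitude_scale", tuple(amp))

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "cadence_hz": self.cadence_hz,
            "phase_fractions": list(self.phase_fractions),
            "phase_cv": self.phase_cv,
            "imu_noise_sd": self.imu_noise_sd,
            "amplitude_scale": list(self.amplitude_scale),
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectProfile":
        d = dict(d)
        for k in ("phase_fractions", "amplitude_scale"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GaitRecording:
    """One subject trial: synchronized IMU and plantar-pressure streams.

    ``imu`` is T x 12 at 100 Hz (2 IMUs x [accel x,y,z; gyro x,y,z]);
    ``pressure`` is Tp x 2 at 50 Hz (heel, first metatarsal), sampled at the
    even IMU indices. ``truth_labels``/``truth_events`` are the generative
    ground truth when the recording is synthetic, else None.
    """

    subject_id: str
    imu: np.ndarray
    pressure: np.ndarray
    fs_imu: float = FS_IMU
    fs_pressure: float = FS_PRESSURE
    truth_labels: np.ndarray | None = None
    truth_events: GaitEventSet | None = None

    def __post_init__(self):
        self.imu = np.asarray(self.imu, dtype=float).reshape(-1, N_IMU_CHANNELS)
        self.pressure = np.asarray(self.pressure, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.imu)):
            raise ValueError("IMU stream contains non-finite values")
        if not np.all(np.isfinite(self.pressure)):
            raise ValueError("pressure stream contains non-finite values")
        if np.any(self.pressure < 0):
            raise ValueError("pressure must be non-negative")
        T, Tp = self.imu.shape[0], self.pressure.shape[0]
        if abs(T - 2 * Tp) > 1:
            raise ValueError(
                f"IMU ({T} samples @100 Hz) and pressure ({Tp} @50 Hz) streams "
                "do not cover the same interval"
            )
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels, dtype=np.int64)
            if self.truth_labels.shape != (T,):
                raise ValueError("truth_labels length must equal the IMU length")

    @property
    def n_samples(self) -> int:
        return self.imu.shape[0]


# ---------------------------------------------------------------------------
# Phase-locked waveform bank (fixture constants).
#
# Each (channel, phase) pair gets a distinct smooth trajectory over the
# phase-local time tau in [0, 1): an offset plus two sinusoidal components.
# The tables are deterministic functions of the indices; they encode no claim
# about real CP kinematics, only that phases are mutually discriminative on
# every channel.
# ---------------------------------------------------------------------------

def _waveform_tables():
    c = np.arange(N_IMU_CHANNELS)[:, None]
    p = np.arange(N_PHASES)[None, :]
    off = ((3 * c + 5 * p) % 7 - 3.0) / 2.0          # offsets in [-1.5, 1.5]
    amp = 0.6 + ((c + 2 * p) % 5) * 0.2              # amplitudes 0.6..1.4
    freq = 1.0 + (c + p) % 3                         # 1, 2 or 3 cycles/phase
    phi = 2.0 * np.pi * ((2 * c + 3 * p) % 8) / 8.0
    return off, amp, freq, phi


_OFF, _AMP, _FREQ, _PHI = _waveform_tables()


def _phase_trajectory(channel: int, phase: int, tau: np.ndarray) -> np.ndarray:
    """Mean IMU trajectory of `channel` during `phase` at phase-time tau."""
    return (
        _OFF[channel, phase]
        + _AMP[channel, phase] * np.sin(2.0 * np.pi * _FREQ[channel, phase] * tau + _PHI[channel, phase])
        + 0.5 * _AMP[channel, phase] * np.sin(np.pi * tau)
    )


def _empty_recording(profile: SubjectProfile) -> GaitRecording:
    return GaitRecording(
        subject_id=profile.subject_id,
        imu=np.zeros((0, N_IMU_CHANNELS)),
        pressure=np.zeros((0, 2)),
        truth_labels=np.zeros(0, dtype=np.int64),
        truth_events=GaitEventSet([]),
    )


def simulate_subject(profile: SubjectProfile, n_strides: int) -> GaitRecording:
    """Simulate one subject walking `n_strides` complete gait cycles.

    Per-stride phase durations are drawn around ``profile.phase_fractions``
    with coefficient of variation ``profile.phase_cv``, then snapped to even
    IMU sample indices (so every gait event is visible on the 50 Hz pressure
    grid). The recording starts with a short unlabeled lead-in and ends on
    the heel strike that closes the last cycle, so all ``n_strides`` cycles
    are fully labeled and every event produces a pressure edge.

    Identical inputs (including ``profile.rng_seed``) give bit-identical
    output.
    """
    if n_strides < 0:
        raise ValueError("n_strides must be >= 0")
    if n_strides == 0:
        return _empty_recording(profile)

    rng = np.random.default_rng(profile.rng_seed)
    fracs = np.asarray(profile.phase_fractions)
    stride_mean = FS_IMU / profile.cadence_hz  # samples per stride

    # Continuous per-phase durations, then cumulative boundaries snapped to
    # even sample indices (monotone, phases >= 2 samples).
    factors = 1.0 + profile.phase_cv * rng.standard_normal((n_strides, N_PHASES))
    durations = fracs[None, :] * stride_mean * np.clip(factors, 0.2, None)
    cum = np.concatenate(([0.0], np.cumsum(durations.ravel())))
    bounds = np.empty(cum.shape[0], dtype=np.int64)
    bounds[0] = _LEAD_IN
    for k in range(1, cum.shape[0]):
        bounds[k] = max(bounds[k - 1] + 2, _LEAD_IN + 2 * int(round(cum[k] / 2.0)))

    T = int(bounds[-1]) + 1  # final sample is the closing heel strike

    # Ground-truth events: HS, TS, HO, TO per stride plus the closing HS.
    kinds = [EventKind.HEEL_STRIKE, EventKind.TOE_STRIKE, EventKind.HEEL_OFF, EventKind.TOE_OFF]
    events = [
        (int(bounds[4 * s + p]), kinds[p]) for s in range(n_strides) for p in range(N_PHASES)
    ]
    events.append((int(bounds[-1]), EventKind.HEEL_STRIKE))
    event_set = GaitEventSet(events)
    labels = label_phases(event_set, T)

    # IMU: phase-locked mean trajectory per segment + white noise.
    amp = np.asarray(profile.amplitude_scale)
    imu = np.zeros((T, N_IMU_CHANNELS))
    seg_starts = bounds[:-1]
    seg_ends = bounds[1:]
    seg_phases = np.tile(np.arange(N_PHASES), n_strides)
    for a, b, ph in zip(seg_starts, seg_ends, seg_phases):
        tau = (np.arange(b - a) + 0.5) / (b - a)
        for c in range(N_IMU_CHANNELS):
            imu[a:b, c] = _phase_trajectory(c, ph, tau)
    # closing heel-strike sample continues the HS trajectory at tau = 0
    for c in range(N_IMU_CHANNELS):
        imu[T - 1, c] = _phase_trajectory(c, 0, np.array([0.0]))[0]
    imu *= amp[None, :]
    if profile.imu_noise_sd > 0:
        imu += profile.imu_noise_sd * rng.standard_normal(imu.shape)

    # Pressure at even IMU indices: heel on during [HS, HO), metatarsal on
    # during [TS, TO); the closing heel strike turns the heel channel on.
    Tp = (T + 1) // 2
    heel_on = np.zeros(T, dtype=bool)
    meta_on = np.zeros(T, dtype=bool)
    heel_on[(labels == 0) | (labels == 1)] = True
    meta_on[(labels == 1) | (labels == 2)] = True
    heel_on[T - 1] = True
    on = np.stack([heel_on[::2], meta_on[::2]], axis=1).astype(float)
    pressure = np.clip(on + _PRESSURE_NOISE_SD * rng.standard_normal((Tp, 2)), 0.0, None)

    return GaitRecording(
        subject_id=profile.subject_id,
        imu=imu,
        pressure=pressure,
        truth_labels=labels,
        truth_events=event_set,
    )


def simulate_cohort(profiles: list[SubjectProfile], n_strides: int) -> list[GaitRecording]:
    """Simulate one recording per subject profile.

    Requires at least two profiles with distinct subject ids, so that
    cross-subject heterogeneity (differing gains and phase timing) exists in
    the cohort.
    """
    if len(profiles) < 2:
        raise ValueError("a cohort needs at least 2 subject profiles")
    ids = [p.subject_id for p in profiles]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject_ids in cohort: {dup}")
    return [simulate_subject(p, n_strides) for p in profiles]


def default_cohort(n_subjects: int = 6, base_seed: int = 0) -> list[SubjectProfile]:
    """Default cohort template: `n_subjects` heterogeneous CP-like profiles.

    All subjects share the stance-dominated mean phase structure
    (HS 0.10, FC 0.40, HO 0.15, SW 0.35) with small per-subject perturbation,
    cadence near 0.9 strides/s, per-channel gains in roughly [0.85, 1.15],
    and moderate IMU noise (s.d. 0.1 against unit-order waveforms).
    """
    rng = np.random.default_rng(base_seed)
    base = np.asarray(DEFAULT_PHASE_FRACTIONS)
    profiles = []
    for i in range(n_subjects):
        pf = base + rng.uniform(-0.015, 0.015, size=N_PHASES)
        pf = np.clip(pf, 0.05, None)
        pf = pf / pf.sum()
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                cadence_hz=float(rng.uniform(0.8, 1.0)),
                phase_fractions=tuple(pf),
                phase_cv=0.05,
                imu_noise_sd=0.1,
                amplitude_scale=tuple(rng.uniform(0.85, 1.15, size=N_IMU_CHANNELS)),
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return profiles
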