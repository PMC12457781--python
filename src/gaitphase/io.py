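"""File formats shared by the pipeline stages.

One CSV per subject trial with columns

    t, a1x a1y a1z g1x g1y g1z a2x a2y a2z g2x g2y g2z, heel_p, meta_p, label

on the 100 Hz IMU timeline; the 50 Hz pressure columns are populated only
at even rows (empty elsewhere) and ``label`` is -1 where no phase is
defined. A sidecar JSON records the generating profile and seed for
synthetic trials. Model checkpoints are .npz arrays with a JSON metadata
sidecar; run manifests record config, seeds and file lists for
reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import LstmParams
from .preprocess import GaitEventSet, NormStats, WindowSet
from .sda import SdaParams
from .synth import GaitRecording, SubjectProfile

__all__ = [
    "IMU_COLUMNS",
    "write_recording_csv",
    "read_recording_csv",
    "save_sda",
    "load_sda",
    "save_lstm",
    "load_lstm",
    "save_windows",
    "load_windows",
    "write_manifest",
    "config_hash",
]

IMU_COLUMNS = [
    "a1x", "a1y", "a1z", "g1x", "g1y", "g1z",
    "a2x", "a2y", "a2z", "g2x", "g2y", "g2z",
]
PRESSURE_COLUMNS = ["heel_p", "meta_p"]


def write_recording_csv(recording: GaitRecording, path, profile: SubjectProfile | None = None) -> None:
    """Write one subject trial to CSV (+ profile sidecar JSON if given)."""
    path = Path(path)
    T = recording.n_samples
    df = pd.DataFrame(recording.imu, columns=IMU_COLUMNS)
    df.insert(0, "t", np.arange(T) / recording.fs_imu)
    for j, col in enumerate(PRESSURE_COLUMNS):
        vals = np.full(T, np.nan)
        n_even = recording.pressure.shape[0]
        vals[: 2 * n_even : 2] = recording.pressure[:, j]
        df[col] = vals
    labels = recording.truth_labels if recording.truth_labels is not None else np.full(T, -1)
    df["label"] = labels
    df.to_csv(path, index=False, float_format="%.6g")
    if profile is not None:
        sidecar = {"profile": profile.to_dict(), "n_samples": T}
        if recording.truth_events is not None:
            sidecar["events"] = [[int(i), int(k)] for i, k in recording.truth_events]
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording_csv(path, subject_id: str | None = None) -> GaitRecording:
    """Read a subject trial written by :func:`write_recording_csv`."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise ValueError(f"corrupt recording CSV {path}: {e}") from e
    missing = [c for c in ["t", *IMU_COLUMNS, *PRESSURE_COLUMNS, "label"] if c not in df.columns]
    if missing:
        raise ValueError(f"recording CSV {path} lacks columns {missing}")
    imu = df[IMU_COLUMNS].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(imu).any():
        bad = int(np.flatnonzero(np.isnan(imu).any(axis=1))[0])
        raise ValueError(f"corrupt recording CSV {path}: non-numeric IMU data at line {bad + 2}")
    press = df[PRESSURE_COLUMNS].to_numpy(dtype=float)[::2]
    if imu.shape[0] and np.isnan(press).any():
        bad = int(np.flatnonzero(np.isnan(press).any(axis=1))[0] * 2)
        raise ValueError(f"corrupt recording CSV {path}: missing pressure at line {bad + 2}")
    labels = df["label"].to_numpy(dtype=np.int64) if imu.shape[0] else np.zeros(0, np.int64)
    sid = subject_id or path.stem
    events = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        sid = subject_id or meta.get("profile", {}).get("subject_id", sid)
        if "events" in meta:
            events = GaitEventSet([(i, k) for i, k in meta["events"]])
    if imu.shape[0] == 0:
        press = np.zeros((0, 2))
    return GaitRecording(
        subject_id=sid, imu=imu, pressure=press, truth_labels=labels, truth_events=events
    )


def _save_params(path, arrays: dict, meta: dict) -> None:
    path = Path(path)
    np.savez(path, **arrays)
    meta_path = path.with_suffix(".json")
    meta_path.write_text(json.dumps({**meta, "shapes": {k: list(v.shape) for k, v in arrays.items()}}, indent=1))


def save_sda(params: SdaParams, path, meta: dict | None = None) -> None:
    _save_params(path, params.as_dict(), {
        "kind": "sda", "dropout_p": params.dropout_p,
        "output_activation": params.output_activation, **(meta or {}),
    })


def load_sda(path) -> SdaParams:
    meta = json.loads(Path(path).with_suffix(".json").read_text())
    with np.load(path) as z:
        return SdaParams(
            **{k: z[k] for k in ("W1", "b1", "Wb", "bb", "Wd", "bd", "W2", "b2")},
            dropout_p=meta.get("dropout_p", 0.2),
            output_activation=meta.get("output_activation", "relu"),
        )


def save_lstm(params: LstmParams, path, meta: dict | None = None) -> None:
    _save_params(path, params.as_dict(), {"kind": "lstm", "input_dim": params.input_dim, **(meta or {})})


def load_lstm(path) -> LstmParams:
    meta = json.loads(Path(path).with_suffix(".json").read_text())
    with np.load(path) as z:
        return LstmParams(
            **{k: z[k] for k in ("Wx0", "Wh0", "b0", "Wx1", "Wh1", "b1", "W_out", "b_out")},
            input_dim=meta.get("input_dim", 12),
        )


def save_windows(windows: WindowSet, path, stats: NormStats | None = None, sources=None) -> None:
    """Windows + labels as a compressed array container with a JSON manifest."""
    path = Path(path)
    np.savez_compressed(
        path, windows=windows.windows, labels=windows.labels,
        subject_ids=windows.subject_ids.astype("U32"),
    )
    manifest = {
        "Lw": windows.Lw, "stride": windows.stride, "D": windows.D, "n": len(windows),
        "normalization": stats.to_dict() if stats else None,
        "sources": [str(s) for s in (sources or [])],
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_windows(path):
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as z:
        ws = WindowSet(
            z["windows"], z["labels"], z["subject_ids"], manifest["Lw"], manifest["stride"]
        )
    stats = NormStats.from_dict(manifest["normalization"]) if manifest.get("normalization") else None
    return ws, stats


def config_hash(config_dict: dict) -> str:
    return hashlib.sha256(json.dumps(config_dict, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(path, config_dict: dict, files, seed: int) -> None:
    """Provenance manifest: config hash, seed, versions, produced files."""
    import gaitphase

    Path(path).write_text(json.dumps({
        "schema_version": 1,
        "gaitphase_version": gaitphase.__version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config": config_dict,
        "config_hash": config_hash(config_dict),
        "files": [str(f) for f in files],
    }, indent=1))
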