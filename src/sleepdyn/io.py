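"""Delimited-text I/O for recordings, series and cohort manifests.

All files are plain CSV with headers. Raw tri-axial recordings use columns
``t, ax, ay, az`` (units G, t in seconds); movement and derived series use
``t, value``. A cohort manifest has one row per recording with columns
``group, subject, night, path, seed, kind``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .preprocess import BinaryMovementSeries, MovementSeries, RawAccelRecording
from .synthetic import SyntheticCohort, recording_seed

KIND_RAW32 = "raw32"
KIND_MOVEMENT = "movement1hz"


def write_raw_recording(raw: RawAccelRecording, path) -> None:
    t = np.arange(raw.samples.shape[0]) / raw.sampling_rate
    df = pd.DataFrame({"t": t, "ax": raw.samples[:, 0],
                       "ay": raw.samples[:, 1], "az": raw.samples[:, 2]})
    df.to_csv(path, index=False)


def read_raw_recording(path, sampling_rate: float = 32.0) -> RawAccelRecording:
    df = pd.read_csv(path)
    for col in ("ax", "ay", "az"):
        if col not in df.columns:
            raise ParameterError(f"{path}: missing column {col!r}")
    return RawAccelRecording(samples=df[["ax", "ay", "az"]].to_numpy(),
                             sampling_rate=sampling_rate)


def write_series(values: np.ndarray, path, t0: int = 0) -> None:
    values = np.asarray(values, dtype=float)
    pd.DataFrame({"t": np.arange(t0, t0 + len(values)),
                  "value": values}).to_csv(path, index=False)


def read_series(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "value" not in df.columns:
        raise ParameterError(f"{path}: missing column 'value'")
    return df["value"].to_numpy(dtype=float)


def write_movement_series(series: MovementSeries, path) -> None:
    write_series(series.values, path)


def write_binary_series(series: BinaryMovementSeries, path) -> None:
    write_series(series.values, path)


def write_cohort(cohort: SyntheticCohort, out_dir) -> pd.DataFrame:
    """Write one series file per recording plus the manifest; returns the
    manifest frame."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for (group, subject, night), series in sorted(cohort.recordings.items()):
        name = f"{group}_s{subject:02d}_n{night}.csv"
        write_movement_series(series, out / name)
        rows.append({
            "group": group, "subject": subject, "night": night,
            "path": name,
            "seed": recording_seed(cohort.config.seed, group, subject, night),
            "kind": KIND_MOVEMENT,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"group", "subject", "night", "path", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"manifest missing columns: {sorted(missing)}")
    return df
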