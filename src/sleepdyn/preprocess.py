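"""Raw-accelerometry preprocessing.

Converts a tri-axial 32 Hz acceleration recording into the 1 Hz movement
magnitude series used by every downstream analysis:

1. block-average resample to 1 Hz,
2. zero-phase high-pass at 0.0028 Hz per axis (removes sustained gravity),
3. RMS combination of the three axes into one non-negative magnitude,
4. sleep-onset detection (first 10 min run below 0.1 G) and extraction of
   the 8 h analysis window,
5. median binarization into a movement presence/absence series.

Also provides the trailing moving-average primitive shared by the entropy,
FNN and group-statistics stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import (
    DegenerateSeriesError,
    InvalidLengthError,
    OnsetNotFoundError,
    ParameterError,
    ShortRecordingError,
)

WINDOW_SECONDS = 28_800  # 8 h at 1 Hz
ONSET_THRESHOLD_G = 0.1
ONSET_RUN_SECONDS = 600
HIGHPASS_CUTOFF_HZ = 0.0028


@dataclass
class RawAccelRecording:
    """Tri-axial acceleration trace for one subject-night.

    ``samples`` has shape (n, 3) with columns (ax, ay, az) in G.
    """

    samples: np.ndarray
    sampling_rate: float = 32.0
    subject_id: str = ""
    night_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ParameterError("samples must have shape (n, 3)")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")


@dataclass
class MovementSeries:
    """1 Hz non-negative movement magnitude series (G)."""

    values: np.ndarray
    sampling_rate: float = 1.0
    onset_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BinaryMovementSeries:
    """Median-thresholded movement presence series (values in {0, 1})."""

    values: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def _as_3d(series3d: np.ndarray) -> np.ndarray:
    arr = np.asarray(series3d, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ParameterError("expected a (n, 3) tri-axial array")
    return arr


def block_average_resample(raw: RawAccelRecording | np.ndarray,
                           sampling_rate: float | None = None) -> np.ndarray:
    """Resample tri-axial acceleration to 1 Hz by block averaging over 1 s.

    Each output sample is the arithmetic mean of one non-overlapping block of
    ``sampling_rate`` input samples per axis; a trailing partial block is
    dropped.
    """
    if isinstance(raw, RawAccelRecording):
        arr, rate = raw.samples, raw.sampling_rate
    else:
        arr = _as_3d(raw)
        rate = 32.0 if sampling_rate is None else sampling_rate
    block = int(round(rate))
    if block <= 0:
        raise ParameterError("sampling_rate must be positive")
    if arr.shape[0] < block:
        raise InvalidLengthError(
            f"need at least {block} samples for one 1-s block, got {arr.shape[0]}")
    n_blocks = arr.shape[0] // block
    return arr[: n_blocks * block].reshape(n_blocks, block, 3).mean(axis=1)


def highpass(series3d: np.ndarray, cutoff: float = HIGHPASS_CUTOFF_HZ,
             fs: float = 1.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth high-pass, applied independently per axis.

    Removes the sustained (gravitational) component; passband amplitudes
    (> 10x cutoff) are preserved within 1%.
    """
    arr = _as_3d(series3d)
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    # filtfilt needs enough samples for its edge padding
    padlen = 3 * (2 * order + 1)
    if arr.shape[0] <= padlen:
        raise InvalidLengthError(
            f"series of length {arr.shape[0]} too short for order-{order} "
            f"zero-phase filtering (needs > {padlen})")
    return signal.sosfiltfilt(sos, arr, axis=0)


def rms_combine(series3d: np.ndarray) -> np.ndarray:
    """Collapse three axes into one magnitude: sqrt((ax^2+ay^2+az^2)/3)."""
    arr = _as_3d(series3d)
    return np.sqrt(np.mean(arr * arr, axis=1))


def detect_sleep_onset(values: np.ndarray, threshold: float = ONSET_THRESHOLD_G,
                       run_length: int = ONSET_RUN_SECONDS) -> int:
    """First index i such that all samples in [i, i + run_length) < threshold."""
    x = np.asarray(values, dtype=float)
    if run_length < 1:
        raise ParameterError("run_length must be >= 1")
    if len(x) < run_length:
        raise OnsetNotFoundError(
            f"series shorter ({len(x)}) than the required quiescent run ({run_length})")
    below = (x < threshold).astype(np.int64)
    runsum = np.convolve(below, np.ones(run_length, dtype=np.int64), mode="valid")
    hits = np.nonzero(runsum == run_length)[0]
    if hits.size == 0:
        raise OnsetNotFoundError("no quiescent run found")
    return int(hits[0])


def extract_window(values: np.ndarray, onset: int,
                   duration: int = WINDOW_SECONDS) -> np.ndarray:
    """Contiguous slice of exactly ``duration`` samples starting at ``onset``."""
    x = np.asarray(values, dtype=float)
    if onset < 0:
        raise ParameterError("onset must be non-negative")
    if onset + duration > len(x):
        raise ShortRecordingError(
            f"recording has {len(x)} samples; window [{onset}, {onset + duration}) "
            "extends past its end")
    return x[onset: onset + duration].copy()


def binarize_median(values: np.ndarray) -> BinaryMovementSeries:
    """Binarize: 1 where the value strictly exceeds the per-recording median.

    Ties (values equal to the median) map to 0. A constant series yields all
    zeros with a warning.
    """
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise InvalidLengthError("cannot binarize an empty series")
    med = float(np.median(x))
    out = (x > med).astype(float)
    if np.all(x == x[0]):
        warnings.warn("constant series: median binarization yields all zeros",
                      stacklevel=2)
    return BinaryMovementSeries(values=out, threshold=med)


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Trailing moving average, valid mode.

    Output index j is the mean of input window [j, j + window); the result has
    length ``len(values) - window + 1``.
    """
    x = np.asarray(values, dtype=float)
    if window < 1:
        raise ParameterError("window must be >= 1")
    if window > len(x):
        raise InvalidLengthError(
            f"window {window} exceeds series length {len(x)}")
    if window == 1:
        return x.copy()
    c = np.concatenate(([0.0], np.cumsum(x)))
    return (c[window:] - c[:-window]) / window


def preprocess_recording(raw: RawAccelRecording,
                         duration: int = WINDOW_SECONDS,
                         onset_threshold: float = ONSET_THRESHOLD_G,
                         onset_run: int = ONSET_RUN_SECONDS) -> MovementSeries:
    """Full chain: resample -> high-pass -> RMS -> onset -> window."""
    at_1hz = block_average_resample(raw)
    filtered = highpass(at_1hz)
    magnitude = rms_combine(filtered)
    onset = detect_sleep_onset(magnitude, threshold=onset_threshold,
                               run_length=onset_run)
    window = extract_window(magnitude, onset, duration=duration)
    return MovementSeries(values=window, sampling_rate=1.0, onset_index=onset)
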