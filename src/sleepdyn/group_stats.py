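"""Cohort-level statistics on the time-resolved irregularity traces.

Implements the group-comparison layer: 60-min smoothing of expSampEn
tracks, pointwise two-sample Student's t-tests across subjects (one-tailed,
group B below group A, uncorrected for multiple comparisons), per-recording
high/low-irregularity representative values (90th/10th percentile of the
smoothed track), a one-tailed t-test on those representatives, and the
Spearman cross-measure correlation table. Nights are averaged within
subject before any between-group test, so the subject is the independent
unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSeriesError, InvalidLengthError, ParameterError
from .preprocess import moving_average

SMOOTH_WINDOW = 3600  # 60 min at 1 Hz
ALPHA_LEVEL = 0.05
Q_HIGH = 90.0
Q_LOW = 10.0


@dataclass
class PointwiseTestTrack:
    time: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    significant_lower_B: np.ndarray


@dataclass
class RepresentativeValues:
    p90: float
    p10: float
    scale: int


def smooth_60min(values: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Trailing 60-min moving average (valid mode)."""
    x = np.asarray(values, dtype=float)
    if len(x) < window:
        raise InvalidLengthError(
            f"series of length {len(x)} shorter than smoothing window {window}")
    return moving_average(x, window)


def pointwise_group_ttest(group_a: np.ndarray, group_b: np.ndarray,
                          time: np.ndarray | None = None,
                          alpha: float = ALPHA_LEVEL) -> PointwiseTestTrack:
    """Per-time-point equal-variance t-test across subjects.

    ``group_a``/``group_b`` are (n_subjects, T) arrays of smoothed tracks,
    one row per subject (nights already averaged). The one-tailed p-value
    tests the B < A direction; no multiple-comparison correction is
    applied.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ParameterError(
            f"time supports differ: {a.shape[1]} vs {b.shape[1]}")
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ParameterError("need at least 3 subjects per group")
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (ma - mb) / se, 0.0)
    p_one = stats.t.sf(t, df)  # B < A  <=>  t > 0
    if time is None:
        time = np.arange(a.shape[1])
    return PointwiseTestTrack(time=np.asarray(time), t_stat=t, p_value=p_one,
                              significant_lower_B=p_one < alpha)


def representative_values(smoothed_track: np.ndarray, scale: int = 0,
                          q_high: float = Q_HIGH,
                          q_low: float = Q_LOW) -> RepresentativeValues:
    """90th/10th percentile (linear interpolation) of a smoothed track."""
    x = np.asarray(smoothed_track, dtype=float)
    if len(x) == 0:
        raise InvalidLengthError("empty track")
    hi, lo = np.percentile(x, [q_high, q_low])
    return RepresentativeValues(p90=float(hi), p10=float(lo), scale=scale)


def representative_ttest(values_a, values_b,
                         one_tailed: bool = True) -> tuple[float, float]:
    """Two-sample equal-variance Student's t; one-tailed p in the A > B
    direction (the convention matching a printed pair T = 2.17, p = 0.019
    at 17 + 17 subjects)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ParameterError("need at least 3 values per group")
    t, p_two = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):
        raise DegenerateSeriesError("zero pooled variance in t-test")
    if one_tailed:
        df = len(a) + len(b) - 2
        p = float(stats.t.sf(t, df))
    else:
        p = float(p_two)
    return float(t), p


DEFAULT_PAIRS = (
    ("raw", "thr"),
    ("raw", "raw_exp"),
    ("thr", "thr_exp"),
    ("raw", "thr_exp"),
    ("raw_exp", "thr_exp"),
)


def spearman_table(recordings: list[dict], pairs=DEFAULT_PAIRS,
                   smoothing: int = SMOOTH_WINDOW) -> pd.DataFrame:
    """Mean +/- SD of per-recording Spearman correlations for each pair type.

    Each element of ``recordings`` maps channel names (e.g. 'raw', 'thr',
    'raw_exp', 'thr_exp') to 1-D arrays. All channels are smoothed over 60
    min and trailing-aligned (truncated at the head to the shorter length)
    before correlating. Constant channels yield a missing (NaN) entry.
    """
    rows = []
    for rec_i, channels in enumerate(recordings):
        smoothed = {}
        for name, series in channels.items():
            x = np.asarray(series, dtype=float)
            if len(x) >= smoothing:
                x = moving_average(x, smoothing)
            smoothed[name] = x
        for left, right in pairs:
            if left not in smoothed or right not in smoothed:
                continue
            a, b = smoothed[left], smoothed[right]
            m = min(len(a), len(b))
            a, b = a[-m:], b[-m:]  # trailing alignment: ends coincide in time
            if np.all(a == a[0]) or np.all(b == b[0]):
                r = np.nan
            else:
                r = stats.spearmanr(a, b).statistic
            rows.append({"recording": rec_i, "pair": f"{left}-{right}", "r": r})
    long = pd.DataFrame(rows)
    summary = (long.groupby("pair", sort=False)["r"]
               .agg(mean="mean", sd="std", n_missing=lambda s: int(s.isna().sum()))
               .reset_index())
    return summary
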