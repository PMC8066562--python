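"""Irregularity measures: ApEn, SampEn and the time-resolved expSampEn.

All three measures share one counting machinery. For a series x of length N
and template length m, consider the indices n = m .. N-1 (0-based). The
m-point "past" vector of n is (x[n-m], ..., x[n-1]) and the (m+1)-point
joint vector appends the current value x[n]. Two vectors are "close" when
their Chebyshev (maximum-coordinate) distance is at most the tolerance
r * SD(x). Writing

    B_n = #{ j : past_j close to past_n }        (self included)
    A_n = #{ j : joint_j close to joint_n }      (self included)

the conditional probability that the current value is close given a close
past is p(x_n | x_n^-) = A_n / B_n, and

    expSampEn_n = -log(A_n / B_n)                (one value per time point)
    ApEn        = mean_n expSampEn_n             (exactly, by construction)
    SampEn      = -log( sum(A_n - 1) / sum(B_n - 1) )   (self excluded)

Self-matches are included for ApEn/expSampEn (every A_n >= 1, so each
pointwise value is finite and non-negative, and the time average of
expSampEn is identically ApEn) and excluded for SampEn, which keeps its
standard, less-biased definition. Under these conventions ApEn equals the
classic Phi^m - Phi^{m+1} difference with both template sets restricted to
the common index range n = m .. N-1. Natural logarithms are used, so all
values are in nats.

The multiscale protocol first takes a trailing moving average over the time
scale (30, 100 or 300 s at 1 Hz), then recomputes the tolerance as r times
the SD of the *averaged* series before computing the measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import entropy_counts
from .errors import DegenerateSeriesError, InvalidLengthError, ParameterError
from .preprocess import moving_average

DEFAULT_M = 2
DEFAULT_R = 0.2
DEFAULT_SCALES = (30, 100, 300)


@dataclass
class EntropyParams:
    """Parameters of the entropy family.

    ``tolerance_abs`` is r times the population SD of the (scale-averaged)
    input, recomputed per scale; it may be supplied explicitly to bypass the
    SD-relative rule.
    """

    m: int = DEFAULT_M
    r: float = DEFAULT_R
    scale: int = 1
    tolerance_abs: float | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError("m must be >= 1")
        if self.r <= 0:
            raise ParameterError("r must be positive")
        if self.scale < 1:
            raise ParameterError("scale must be >= 1")


@dataclass
class ExpSampEnSeries:
    """Time-resolved irregularity trace at one time scale.

    ``values[k]`` is the pointwise entropy of the input sample at index
    ``k + time_offset`` (the *current* point of the template, i.e. the end).
    """

    values: np.ndarray
    time_offset: int
    params: EntropyParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def _tolerance(x: np.ndarray, params: EntropyParams) -> float:
    if params.tolerance_abs is not None:
        return float(params.tolerance_abs)
    sd = float(np.std(x))  # population SD (divisor N)
    if sd == 0.0:
        raise DegenerateSeriesError(
            "constant series: SD-relative tolerance is zero")
    return params.r * sd


def _counts(x: np.ndarray, params: EntropyParams):
    x = np.asarray(x, dtype=float)
    if len(x) <= params.m + 1:
        raise InvalidLengthError(
            f"need more than m + 1 = {params.m + 1} samples, got {len(x)}")
    r_abs = _tolerance(x, params)
    a, b = entropy_counts(x, params.m, r_abs)
    return a, b


def exp_sampen(x: np.ndarray, params: EntropyParams | None = None) -> ExpSampEnSeries:
    """Pointwise (expanded) sample entropy: -log p(x_n | x_n^-) per time point.

    Self-matches are included, so every value is finite and >= 0, and the
    time average equals :func:`apen` exactly.
    """
    params = params or EntropyParams()
    a, b = _counts(x, params)
    values = -np.log(a / b)
    # clip the -0.0 that full saturation produces
    values = np.maximum(values, 0.0)
    return ExpSampEnSeries(values=values, time_offset=params.m, params=params)


def apen(x: np.ndarray, params: EntropyParams | None = None) -> float:
    """Approximate entropy: mean over time of the pointwise entropy (nats)."""
    params = params or EntropyParams()
    a, b = _counts(x, params)
    return float(np.mean(-np.log(a / b)))


def sampen(x: np.ndarray, params: EntropyParams | None = None) -> float:
    """Sample entropy: -log of the ratio of total (m+1)- to m-point matches,
    self-matches excluded (nats).

    Raises :class:`DegenerateSeriesError` if there are no m-point matches;
    returns ``inf`` (with a warning) if m-matches exist but no (m+1)-matches.
    """
    params = params or EntropyParams()
    a, b = _counts(x, params)
    a_tot = int(a.sum()) - len(a)  # remove self-matches
    b_tot = int(b.sum()) - len(b)
    if b_tot == 0:
        raise DegenerateSeriesError(
            "no m-point template matches: SampEn undefined")
    if a_tot == 0:
        warnings.warn("no (m+1)-point matches: SampEn is infinite", stacklevel=2)
        return float("inf")
    return float(-np.log(a_tot / b_tot))


def multiscale_profile(x: np.ndarray,
                       scales=DEFAULT_SCALES,
                       m: int = DEFAULT_M,
                       r: float = DEFAULT_R) -> pd.DataFrame:
    """ApEn/SampEn/expSampEn after trailing moving averages over each scale.

    Returns a DataFrame with one row per scale and columns
    ``scale, apen, sampen, exp_sampen`` (the last holding
    :class:`ExpSampEnSeries` objects). The tolerance is r * SD of the
    scale-averaged series, recomputed per scale.
    """
    x = np.asarray(x, dtype=float)
    rows = []
    for scale in scales:
        scale = int(scale)
        if scale >= len(x):
            raise InvalidLengthError(
                f"scale {scale} not smaller than series length {len(x)}")
        averaged = moving_average(x, scale)
        params = EntropyParams(m=m, r=r, scale=scale)
        ese = exp_sampen(averaged, params)
        # pointwise index k of `averaged` maps to input index k + scale - 1
        ese.time_offset = ese.time_offset + scale - 1
        rows.append({
            "scale": scale,
            "apen": float(np.mean(ese.values)),
            "sampen": sampen(averaged, params),
            "exp_sampen": ese,
        })
    return pd.DataFrame(rows)
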