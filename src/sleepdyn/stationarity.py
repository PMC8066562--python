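"""Stationarity screen: first half versus whole-series distribution.

The whole series defines equal-probability (quantile) bins — or the natural
value categories when the series takes no more distinct values than bins,
as for binarized data with two bins. Observed counts come from the first
half of the series; expected counts are the whole-series bin proportions
scaled to the half length. A Pearson chi-square with n_bins - 1 degrees of
freedom rejects stationarity at the 0.05 level. Because the first half is
part of the reference distribution, the null distribution is slightly
conservative relative to an exact chi-square; the test is implemented as
described and its Monte-Carlo level is characterized in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateSeriesError,
    InvalidLengthError,
    UnreliableTestError,
)

ALPHA_LEVEL = 0.05
BINS_RAW = 5
BINS_BINARY = 2


@dataclass
class StationarityResult:
    statistic: float
    dof: int
    p_value: float
    rejected: bool
    n_bins: int


def _bin_counts(x: np.ndarray, first: np.ndarray, n_bins: int):
    """Whole-series and first-half counts in quantile (or categorical) bins."""
    uniq = np.unique(x)
    if uniq.size == 1:
        raise DegenerateSeriesError("constant series cannot be binned")
    if uniq.size <= n_bins:
        # natural categories (e.g. a binarized series with two bins)
        whole = np.array([(x == u).sum() for u in uniq], dtype=float)
        half = np.array([(first == u).sum() for u in uniq], dtype=float)
        return whole, half
    # order-statistic edges (no interpolation) keep the statistic exactly
    # invariant under strictly monotone transforms of the series
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1],
                        method="inverted_cdf")
    whole_idx = np.searchsorted(edges, x, side="right")
    half_idx = np.searchsorted(edges, first, side="right")
    whole = np.bincount(whole_idx, minlength=n_bins).astype(float)
    half = np.bincount(half_idx, minlength=n_bins).astype(float)
    return whole, half


def stationarity_chi2(x: np.ndarray, n_bins: int) -> StationarityResult:
    """Chi-square comparison of the first half against the entire series."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * n_bins * 5:
        raise InvalidLengthError(
            f"need at least {2 * n_bins * 5} samples for {n_bins} bins "
            f"(expected counts >= 5), got {n}")
    first = x[: n // 2]
    whole, half = _bin_counts(x, first, n_bins)
    k = len(whole)
    expected = len(first) * whole / n
    if np.any(expected < 1):
        raise UnreliableTestError(
            "expected count below 1 in some bin; chi-square unreliable")
    statistic = float(((half - expected) ** 2 / expected).sum())
    dof = k - 1
    p = float(stats.chi2.sf(statistic, dof))
    return StationarityResult(statistic=statistic, dof=dof, p_value=p,
                              rejected=p < ALPHA_LEVEL, n_bins=k)
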