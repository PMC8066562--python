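"""Detrended fluctuation analysis (first order).

The series is mean-removed and cumulatively summed into a profile; for each
window size n the profile is split into floor(N/n) non-overlapping windows
from the start and the same number from the end (so the tail beyond the last
full forward window still contributes), a least-squares line is removed from
each window, and F(n) is the RMS of the residuals over all covered points.
The scaling exponent alpha is the slope of an ordinary least-squares fit of
log10 F(n) on log10 n restricted to the fit range, by default 300-7200
samples (5 min to 2 h at 1 Hz). alpha ~ 0.5 indicates a temporally
uncorrelated series, alpha ~ 1 indicates 1/f long-range correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidLengthError, ParameterError

DEFAULT_FIT_RANGE = (300, 7200)


def default_scales(n_min: int = 300, n_max: int = 7200, num: int = 20) -> np.ndarray:
    """Log-spaced integer window sizes (duplicates removed)."""
    return np.unique(np.geomspace(n_min, n_max, num).round().astype(int))


@dataclass
class DfaResult:
    scales: np.ndarray
    fluctuation: np.ndarray
    alpha: float
    r_squared: float
    fit_range: tuple[int, int] = DEFAULT_FIT_RANGE


def _window_ssr(seg: np.ndarray) -> float:
    """Sum of squared residuals of one window around its least-squares line."""
    n = seg.shape[-1]
    t = np.arange(n, dtype=float)
    t_mean = (n - 1) / 2.0
    tc = t - t_mean
    denom = float(tc @ tc)
    y_mean = seg.mean(axis=-1, keepdims=True)
    slope = (seg - y_mean) @ tc / denom
    resid = seg - y_mean - slope[..., None] * tc
    return float((resid * resid).sum())


def dfa_fluctuation(x: np.ndarray, scales) -> np.ndarray:
    """F(n) per window size for the cumulative-sum profile of x."""
    x = np.asarray(x, dtype=float)
    scales = np.asarray(scales, dtype=int)
    if scales.size == 0:
        raise ParameterError("no scales given")
    if np.any(scales < 4):
        raise ParameterError("scales must be >= 4")
    n_samples = len(x)
    if n_samples < 4 * int(scales.max()):
        raise InvalidLengthError(
            f"series of length {n_samples} too short for max scale "
            f"{int(scales.max())} (need >= 4x)")
    profile = np.cumsum(x - x.mean())
    out = np.empty(len(scales), dtype=float)
    for i, n in enumerate(scales):
        n = int(n)
        k = n_samples // n
        fwd = profile[: k * n].reshape(k, n)
        bwd = profile[n_samples - k * n:].reshape(k, n)
        ssr = _window_ssr(fwd) + _window_ssr(bwd)
        out[i] = np.sqrt(ssr / (2 * k * n))
    return out


def fit_alpha(scales, fluctuations,
              fit_range: tuple[int, int] = DEFAULT_FIT_RANGE) -> tuple[float, float]:
    """OLS slope (alpha) and R^2 of log10 F on log10 n within the fit range."""
    scales = np.asarray(scales, dtype=float)
    flucts = np.asarray(fluctuations, dtype=float)
    lo, hi = fit_range
    mask = (scales >= lo) & (scales <= hi)
    if mask.sum() < 4:
        raise ParameterError(
            f"need >= 4 scales inside the fit range [{lo}, {hi}], "
            f"got {int(mask.sum())}")
    lx = np.log10(scales[mask])
    ly = np.log10(flucts[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(((ly - pred) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def dfa(x: np.ndarray, scales=None,
        fit_range: tuple[int, int] = DEFAULT_FIT_RANGE) -> DfaResult:
    """Convenience wrapper: fluctuation function plus fitted exponent."""
    if scales is None:
        scales = default_scales(fit_range[0], fit_range[1])
    fl = dfa_fluctuation(x, scales)
    alpha, r2 = fit_alpha(scales, fl, fit_range)
    return DfaResult(scales=np.asarray(scales, dtype=int), fluctuation=fl,
                     alpha=alpha, r_squared=r2, fit_range=fit_range)
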