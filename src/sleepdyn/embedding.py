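"""Determinism detection: delay selection, delay embedding, false nearest
neighbors.

The embedding delay tau is the 1/e decay time of the autocorrelation
function (median across recordings). Delay vectors

    y_i^(d) = (x_i, x_{i+tau}, ..., x_{i+(d-1)tau})

are tested for false neighbors with the two standard criteria: a pair whose
separation in the next coordinate is large relative to its distance in d
dimensions (ratio > A), or whose (d+1)-dimensional distance is large
relative to the series SD (> B). A deterministic attractor drives the
fraction of points failing either test to zero once d is large enough; for
a stochastic series it never converges to zero. Inputs are moving-averaged
over the delay before counting, the Theiler window equals the delay, and
A = 10, B = 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import fnn_dim_counts
from .errors import DegenerateSeriesError, InvalidLengthError, ParameterError
from .preprocess import moving_average

DEFAULT_A = 10.0
DEFAULT_B = 2.0
DEFAULT_D_MAX = 10


@dataclass
class EmbeddingParams:
    tau: int = 1
    d_max: int = DEFAULT_D_MAX
    threshold_A: float = DEFAULT_A
    threshold_B: float = DEFAULT_B
    theiler_window: int | None = None  # defaults to tau

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ParameterError("tau must be >= 1")
        if self.d_max < 1:
            raise ParameterError("d_max must be >= 1")
        if self.threshold_A <= 0 or self.threshold_B <= 0:
            raise ParameterError("thresholds A and B must be positive")
        if self.theiler_window is None:
            self.theiler_window = self.tau


@dataclass
class FnnCurve:
    dimensions: np.ndarray
    fraction_test1: np.ndarray
    fraction_test2: np.ndarray
    fraction_combined: np.ndarray
    n_pairs: np.ndarray
    zero_denominator: np.ndarray
    sigma: float


def autocorr_time(x: np.ndarray) -> int:
    """Smallest positive lag with normalized autocorrelation below 1/e.

    Uses the mean-removed, biased (divide-by-N) estimator computed via FFT.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10:
        raise InvalidLengthError("need at least 10 samples")
    xc = x - x.mean()
    var = float(xc @ xc)
    if var == 0.0:
        raise DegenerateSeriesError("constant series: autocorrelation undefined")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: n // 2 + 1]
    rho = acov / var  # biased estimator: implicit (1/N) in both num. and denom.
    below = np.nonzero(rho[1:] < 1.0 / np.e)[0]
    if below.size == 0:
        raise DegenerateSeriesError(
            "autocorrelation never decays below 1/e within N/2 lags")
    return int(below[0] + 1)


def median_delay(lags) -> int:
    """Median of per-recording autocorrelation times, rounded to an integer."""
    lags = np.asarray(list(lags), dtype=float)
    if lags.size == 0:
        raise ParameterError("empty collection of lags")
    return int(np.rint(np.median(lags)))


def delay_embed(x: np.ndarray, d: int, tau: int) -> np.ndarray:
    """Delay-coordinate matrix of shape (N - (d-1)*tau, d)."""
    x = np.asarray(x, dtype=float)
    if d < 1 or tau < 1:
        raise ParameterError("d and tau must be >= 1")
    n_vec = len(x) - (d - 1) * tau
    if n_vec < 1:
        raise InvalidLengthError(
            f"series of length {len(x)} too short for d={d}, tau={tau}")
    idx = np.arange(n_vec)[:, None] + tau * np.arange(d)[None, :]
    return x[idx]


def fnn_fractions(x: np.ndarray, params: EmbeddingParams) -> FnnCurve:
    """Fraction of false nearest neighbors per embedding dimension.

    The series is first moving-averaged over a window of tau samples; sigma
    is the population SD of that averaged series. For each d the nearest
    neighbor of every point (Euclidean metric, Theiler exclusion, smallest
    index on ties) is tested with both criteria; the combined fraction uses
    the OR of the two. Pairs at exactly zero distance are not counted as
    false by the ratio test (they stay eligible for the SD test) and are
    tallied in ``zero_denominator``.
    """
    x = np.asarray(x, dtype=float)
    tau = params.tau
    w = params.theiler_window if params.theiler_window is not None else tau
    averaged = moving_average(x, tau)
    sigma = float(np.std(averaged))
    if sigma == 0.0:
        raise DegenerateSeriesError("constant series after averaging")
    n = len(averaged)
    need = params.d_max * tau + w + 2
    if n < need:
        raise InvalidLengthError(
            f"series too short for d_max={params.d_max}, tau={tau} "
            f"(need >= {need} averaged samples, have {n})")
    dims = np.arange(1, params.d_max + 1)
    f1 = np.empty(len(dims))
    f2 = np.empty(len(dims))
    fc = np.empty(len(dims))
    npairs = np.empty(len(dims), dtype=int)
    zden = np.empty(len(dims), dtype=int)
    for i, d in enumerate(dims):
        c1, c2, cb, zd, valid = fnn_dim_counts(
            averaged, tau, int(d), w, params.threshold_A, params.threshold_B,
            sigma)
        if valid == 0:
            raise InvalidLengthError(
                f"no admissible neighbor pairs at d={d} (Theiler window too wide)")
        f1[i] = c1 / valid
        f2[i] = c2 / valid
        fc[i] = cb / valid
        npairs[i] = valid
        zden[i] = zd
    return FnnCurve(dimensions=dims, fraction_test1=f1, fraction_test2=f2,
                    fraction_combined=fc, n_pairs=npairs,
                    zero_denominator=zden, sigma=sigma)
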