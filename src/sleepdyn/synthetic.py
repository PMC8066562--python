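"""Synthetic actigraphy cohorts and canonical validation processes.

Real overnight actigraphy cannot be redistributed, so this module generates
movement-magnitude series with the features the analyses are built to
detect, plus the textbook processes (white/pink/fractional Gaussian noise,
the Henon map) used to validate each algorithm against its known limits.

A synthetic night is a two-state semi-Markov regime process (exponential
dwell times) alternating between a high-irregularity and a low-irregularity
movement state. Within a state, movement events occur as a renewal process
whose inter-event intervals are gamma distributed with a state-specific
coefficient of variation (CV) at a common mean rate, so the states differ
in the regularity of movement occurrence rather than in its amount. Event
magnitudes are lognormal (heavy-tailed) with their log-mean riding on a
slow fractional-Gaussian-noise modulation, which gives the magnitude
channel long-range temporal correlation and a multiplicative nonlinearity;
the sub-threshold baseline is a weakly correlated positive noise floor. The
group contrast is carried by the interval CV of the high-irregularity state
only: group B's lower CV makes its movement occurrence more regular there,
which is the effect the group statistics are meant to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DivergenceError, InvalidLengthError, ParameterError
from .preprocess import MovementSeries

GROUPS = ("A", "B")


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort generator.

    Defaults emulate an 8 h night sampled at 1 Hz for two groups of 17
    subjects with three nights each. ``interval_cv_high`` maps group label
    to the inter-event-interval CV of the high-irregularity state; the
    ASD-like effect is encoded by cv(B) <= cv(A).
    """

    n_subjects_per_group: int = 17
    nights_per_subject: int = 3
    series_length: int = 28_800
    state_dwell_mean: float = 5400.0  # seconds per irregularity state
    event_rate_high: float = 0.15     # movement events per second, high state
    event_rate_low: float = 0.15
    interval_cv_high: dict = field(default_factory=lambda: {"A": 1.0, "B": 0.3})
    interval_cv_low: float = 0.2
    magnitude_log_mean: float = math.log(0.05)  # lognormal location, G
    magnitude_log_sd: float = 0.8
    magnitude_mod_sd: float = 0.5     # slow log-magnitude modulation depth
    magnitude_mod_hurst: float = 0.9  # Hurst exponent of the modulation
    noise_floor: float = 0.001        # median baseline level, G
    noise_corr_time: float = 2.0      # seconds; baseline noise time constant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ParameterError("n_subjects_per_group must be >= 1")
        if self.nights_per_subject < 1:
            raise ParameterError("nights_per_subject must be >= 1")
        if self.series_length < 1:
            raise ParameterError("series_length must be >= 1")
        for name in ("state_dwell_mean", "event_rate_high", "event_rate_low",
                     "interval_cv_low", "magnitude_log_sd", "noise_floor",
                     "noise_corr_time"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.magnitude_mod_sd < 0:
            raise ParameterError("magnitude_mod_sd must be >= 0")
        if not 0 < self.magnitude_mod_hurst < 1:
            raise ParameterError("magnitude_mod_hurst must lie in (0, 1)")
        missing = [g for g in GROUPS if g not in self.interval_cv_high]
        if missing:
            raise ParameterError(f"interval_cv_high missing groups: {missing}")
        if any(v <= 0 for v in self.interval_cv_high.values()):
            raise ParameterError("interval CVs must be positive")
        if self.interval_cv_high["B"] > self.interval_cv_high["A"]:
            raise ParameterError(
                "interval_cv_high must satisfy cv(B) <= cv(A) "
                "(the group effect lowers B's irregularity)")


@dataclass
class SyntheticCohort:
    recordings: dict            # (group, subject, night) -> MovementSeries
    true_state_paths: dict      # (group, subject, night) -> int array (1=high)
    config: GeneratorConfig


def gen_gaussian_noise(n: int, seed: int) -> np.ndarray:
    """i.i.d. standard normal sequence."""
    if n < 2:
        raise InvalidLengthError("need n >= 2")
    return np.random.default_rng(seed).standard_normal(n)


def _fgn_autocov(h: float, n: int) -> np.ndarray:
    k = np.arange(n + 1, dtype=float)
    return 0.5 * (np.abs(k + 1) ** (2 * h) - 2 * k ** (2 * h)
                  + np.abs(k - 1) ** (2 * h))


def gen_fgn(hurst: float, n: int, seed: int) -> np.ndarray:
    """Fractional Gaussian noise by exact circulant embedding.

    The covariance of the length-2n circulant extension of the fGn
    autocovariance is diagonalized by the FFT; sampling in the spectral
    domain gives a draw with exactly the target covariance, so the DFA
    exponent of the output matches the Hurst input.
    """
    if not 0 < hurst < 1:
        raise ParameterError("hurst must lie in (0, 1)")
    if n < 2:
        raise InvalidLengthError("need n >= 2")
    rng = np.random.default_rng(seed)
    r = _fgn_autocov(hurst, n)
    c = np.concatenate([r[: n + 1], r[n - 1: 0: -1]])  # length 2n circulant row
    lam = np.fft.fft(c).real
    lam = np.clip(lam, 0.0, None)  # numerically tiny negatives
    m = 2 * n
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(lam) * z) / np.sqrt(2 * m)
    # Re and Im are independent draws with the target covariance; use Re
    return np.sqrt(2.0) * x.real[:n]


def gen_pink_noise(n: int, seed: int) -> np.ndarray:
    """Gaussian 1/f noise via spectral synthesis with random phases.

    Fourier amplitudes are set deterministically proportional to f^(-1/2)
    (so power ~ 1/f) and phases drawn uniformly; the output is standardized
    to zero mean and unit variance.
    """
    if n < 16:
        raise InvalidLengthError("need n >= 16 for spectral synthesis")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    phases = rng.uniform(0, 2 * np.pi, len(freqs))
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = amp[-1]  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=n)
    return (x - x.mean()) / x.std()


def gen_henon(n: int, x0: tuple[float, float] = (0.1, 0.1),
              a: float = 1.4, b: float = 0.3,
              transient: int = 100) -> np.ndarray:
    """x-coordinate orbit of the Henon map x(t+1) = 1 - a x(t)^2 + b x(t-1).

    The first ``transient`` iterations are discarded. Orbits leaving
    |x| > 1e10 raise :class:`DivergenceError`.
    """
    if n < 1:
        raise InvalidLengthError("need n >= 1")
    xp, xpp = float(x0[0]), float(x0[1])  # x(t), x(t-1)
    out = np.empty(n)
    total = n + transient
    for t in range(total):
        xn = 1.0 - a * xp * xp + b * xpp
        if abs(xn) > 1e10:
            raise DivergenceError(f"Henon orbit diverged at iteration {t}")
        xpp, xp = xp, xn
        if t >= transient:
            out[t - transient] = xn
    return out


def _segment_event_times(rng: np.random.Generator, start: float, stop: float,
                         rate: float, cv: float) -> np.ndarray:
    """Renewal event times in [start, stop): gamma inter-event intervals
    with mean 1/rate and coefficient of variation cv."""
    shape = 1.0 / (cv * cv)
    scale = (cv * cv) / rate  # shape * scale = 1 / rate
    duration = stop - start
    n_guess = max(8, int(rate * duration * 2 + 10 * math.sqrt(rate * duration + 1)))
    times = []
    t = start
    while True:
        intervals = rng.gamma(shape, scale, size=n_guess)
        arr = t + np.cumsum(intervals)
        inside = arr[arr < stop]
        times.append(inside)
        if len(inside) < n_guess:
            break
        t = arr[-1]
    return np.concatenate(times) if times else np.empty(0)


def gen_actigraphy_night(config: GeneratorConfig, group: str,
                         seed: int) -> tuple[MovementSeries, np.ndarray]:
    """One synthetic night: movement series plus the true state path.

    Returns ``(series, states)`` with ``states[t] = 1`` during the
    high-irregularity state.
    """
    if group not in GROUPS:
        raise ParameterError(f"unknown group label {group!r}; expected one of {GROUPS}")
    rng = np.random.default_rng(seed)
    n = config.series_length
    # --- semi-Markov regime path, exponential dwell times -----------------
    states = np.empty(n, dtype=np.int8)
    boundaries = []  # (start, stop, state)
    state = int(rng.integers(0, 2))
    t = 0.0
    while t < n:
        dwell = rng.exponential(config.state_dwell_mean)
        stop = min(t + dwell, n)
        boundaries.append((t, stop, state))
        states[int(t): int(math.ceil(stop))] = state
        state = 1 - state
        t = stop
    # --- slow long-memory modulation of event magnitudes ------------------
    # (log-magnitudes ride on a fractional-Gaussian-noise process, giving the
    # raw channel its 1/f-like long-range correlation and a multiplicative
    # nonlinearity; the binarized channel is rank-based and untouched by it)
    if config.magnitude_mod_sd > 0:
        mod = config.magnitude_mod_sd * gen_fgn(
            config.magnitude_mod_hurst, n, int(rng.integers(2 ** 31)))
        mod -= 0.5 * config.magnitude_mod_sd ** 2
    else:
        mod = np.zeros(n)
    # --- movement events per segment --------------------------------------
    values = np.zeros(n)
    cv_high = config.interval_cv_high[group]
    for start, stop, st in boundaries:
        if st == 1:
            rate, cv = config.event_rate_high, cv_high
        else:
            rate, cv = config.event_rate_low, config.interval_cv_low
        times = _segment_event_times(rng, start, stop, rate, cv)
        if times.size == 0:
            continue
        idx = times.astype(int)
        mags = np.exp(rng.normal(config.magnitude_log_mean + mod[idx],
                                 config.magnitude_log_sd))
        np.maximum.at(values, idx, mags)
    # --- slowly varying positive noise floor ------------------------------
    phi = math.exp(-1.0 / config.noise_corr_time)
    innov = rng.standard_normal(n) * math.sqrt(1 - phi * phi)
    z = np.empty(n)
    z[0] = rng.standard_normal()
    for i in range(1, n):
        z[i] = phi * z[i - 1] + innov[i]
    floor = config.noise_floor * np.exp(0.5 * z)
    values = values + floor
    return MovementSeries(values=values, sampling_rate=1.0), states


def recording_seed(config_seed: int, group: str, subject: int, night: int) -> int:
    """Deterministic per-recording seed (collision-free across the cohort)."""
    ss = np.random.SeedSequence([config_seed, GROUPS.index(group), subject, night])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def gen_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Full two-group cohort; bit-identical under the same config."""
    recordings = {}
    paths = {}
    for group in GROUPS:
        for subject in range(config.n_subjects_per_group):
            for night in range(config.nights_per_subject):
                seed = recording_seed(config.seed, group, subject, night)
                series, states = gen_actigraphy_night(config, group, seed)
                recordings[(group, subject, night)] = series
                paths[(group, subject, night)] = states
    return SyntheticCohort(recordings=recordings, true_state_paths=paths,
                           config=config)


def null_config(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of ``config`` with the group effect switched off."""
    cv = config.interval_cv_high["A"]
    return replace(config, interval_cv_high={"A": cv, "B": cv})


def to_triaxial_32hz(values: np.ndarray, seed: int,
                     gravity: float = 1.0) -> np.ndarray:
    """Thin 3-axis 32 Hz up-sampler for preprocess round-trip testing.

    Each 1 Hz magnitude is held for 32 samples, split equally across axes
    (so the RMS recombination returns the magnitude), with gravity on the
    z axis and a little wideband jitter.
    """
    v = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    n32 = len(v) * 32
    held = np.repeat(v, 32)
    out = np.empty((n32, 3))
    jitter = rng.standard_normal((n32, 3)) * 1e-4
    out[:, 0] = held + jitter[:, 0]
    out[:, 1] = held + jitter[:, 1]
    out[:, 2] = held + gravity + jitter[:, 2]
    return out
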