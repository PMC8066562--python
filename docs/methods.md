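# Methods

This note documents the models, conventions and numerical choices behind
`sleepdyn`, and what the synthetic-data tests do and do not establish about
real recordings.

## Analysis chain

A recording enters the pipeline as a tri-axial 32 Hz acceleration trace and
is reduced to a 1 Hz magnitude series: block averaging over 1 s windows,
zero-phase high-pass at 0.0028 Hz per axis (4th-order Butterworth run
forward and backward; the filter removes sustained gravitational offsets
while leaving the passband above ~0.03 Hz intact to within 1%), then RMS
combination `sqrt((ax^2+ay^2+az^2)/3)`. The analysis window is the 8 h
(28,800 samples) after the first 10 min run of magnitudes below 0.1 G,
anchored at the *start* of the quiescent run (the convention maximizes
usable data; the alternative end-anchoring shifts the window by 10 min).
The "movement presence" channel binarizes each recording at its own median
with a strict `>` rule, so ties map to 0 and the ones-fraction is at most
50%.

All moving averages in the package are trailing, valid-mode means: output
index `j` summarizes input window `[j, j+w)`. Series derived at different
depths of the chain are aligned at their *ends* when they are compared or
correlated.

## Irregularity measures

For template length `m` (default 2) and tolerance `r` (default 0.2), two
vectors are close when their Chebyshev distance is at most `r` times the
population SD of the (scale-averaged) series. With `B_n` the number of
indices whose `m`-point past vector is close to that of `n` (self
included), and `A_n` the same for the `(m+1)`-point joint vector:

- `expSampEn(n) = -log(A_n / B_n)` — a time series of pointwise
  unpredictability, finite and non-negative because self-matches keep every
  conditional probability at least `1/count`;
- `ApEn = mean_n expSampEn(n)` — the identity is exact by construction and
  asserted to 1e-10 in the tests;
- `SampEn = -log(sum(A_n - 1)/sum(B_n - 1))` — self-matches excluded, the
  standard, less biased estimator.

Natural logarithms throughout. The multiscale protocol takes a trailing
moving average over 30, 100 or 300 s and recomputes the tolerance from the
averaged series' SD. The O(N^2) template counting runs in a numba kernel
when numba imports, with a bit-identical chunked numpy fallback; both are
checked against explicit brute-force loops.

An important measured property of this family, which shaped the synthetic
generator (below): because the tolerance is proportional to each series'
own SD, a process whose irregularity carries amplitude (bursts, regime
shifts, slow rate modulation) *lowers* its own measured entropy — the
inflated tolerance makes the series look smooth relative to itself. High
expSampEn rewards fluctuation that is fast relative to the series' total
amplitude.

## Determinism screen (FNN)

The embedding delay is the 1/e decay time of the autocorrelation (biased,
mean-removed estimator), taken as the median across recordings and rounded
to an integer sample. Inputs are moving-averaged over the delay before
embedding. For each dimension `d` the nearest neighbor of every point
(Euclidean metric, Theiler exclusion `|i-j| <= tau`, ties to the smallest
index) is tested with the two standard criteria: next-coordinate separation
ratio > A = 10, and (d+1)-dimensional distance > B = 2 SDs. The combined
fraction uses the OR. Pairs at exactly zero distance — common for binarized
data — are not counted as false by the ratio test but stay eligible for the
SD test, and are reported as a diagnostic count.

A property worth knowing: on Gaussian white noise at N = 10,000 the
combined fraction does not stay above 0.2 at every dimension — it dips to
about 0.17 around d = 5-6 before rising again (neighbor distances in
moderate dimensions fall below both criteria more often than intuition
suggests). The stochastic signature is that the fraction never approaches
zero, and that is what distinguishes noise from the Henon map, which drops
below 0.05 from d = 2.

## Surrogates

IAAFT alternates a spectrum-substitution step (original Fourier amplitudes,
current phases) with a rank remap onto the original's sorted values,
starting from a seeded shuffle and stopping when the rank ordering is fixed
(a true fixed point of the iteration) or after 100 iterations. Ending on
the amplitude step makes the value distribution exact and the spectrum
approximate. Welch spectra use 2,048-sample Hann segments at 50% overlap.

Test size: the 20-surrogate lower-tail rank test (p = 1/21) holds its
nominal level for static monotone transforms of weakly correlated linear
processes (tanh of AR(1) with phi = 0.5: ~5% over 200 draws). For strongly
correlated inputs (phi >= 0.8) the iteration's residual spectrum whitening
biases surrogate SampEn upward and the test becomes anti-conservative —
a known limitation of amplitude-adjusted surrogates combined with
entropy statistics, worth keeping in mind when interpreting rejections on
real data.

## DFA

First-order detrending of the cumulative sum of the mean-removed series;
windows tile the profile from the start *and* from the end so the tail
contributes; `F(n)` is the RMS residual over all covered points; the
exponent is the OLS slope of `log10 F` on `log10 n` over 300-7,200 samples
(5 min to 2 h at 1 Hz), on a 20-point log-spaced grid. Recovery is
validated against white noise (alpha 0.5), spectrally synthesized 1/f noise
(alpha 1.0), and circulant-embedding fGn (alpha = H to within 0.05 for H in
0.6-0.9).

## Group statistics

Nights are averaged within subject before any between-group comparison, so
the subject is the independent unit. Pointwise comparisons of the 60-min
smoothed expSampEn tracks use equal-variance Student's t-tests, one-tailed
in the B-below-A direction, uncorrected for multiple comparisons (a
deliberate reproduction choice; it inflates familywise error and the
pointwise significance track should be read accordingly). Per-recording
representative values are the 90th/10th percentiles (linear interpolation)
of the smoothed track; their group comparison is the same one-tailed
t-test. The one-tailed convention is pinned by the analytic check
`t = 2.17, df = 32  ->  p = 0.019`.

## Synthetic cohort generator

The generator emulates what the analyses need to detect, not accelerometer
physics. A night is a two-state semi-Markov process (exponential dwells,
mean 5,400 s for 8 h nights) alternating high- and low-irregularity states.
Movement events form a gamma renewal process with a *common* mean rate
(0.15 events/s) in both states; the states differ only in the inter-event
interval CV (low state 0.2; high state 1.0 in group A vs 0.3 in group B —
the ASD-like contrast of more regular movement occurrence). Event
log-magnitudes are lognormal (location log 0.05 G, scale 0.8) and ride on a
slow fGn(H = 0.9) modulation of depth 1.0, giving the magnitude channel
long-range correlation and a multiplicative nonlinearity. The sub-threshold
baseline is a lognormal AR(1) floor (median 0.001 G, 2 s correlation time).

Why this shape: the group contrast must survive median binarization,
scale-averaging, and the SD-relative tolerance. Piloting showed that any
design placing the group's extra irregularity in amplitude-carrying
structure (state-dependent rates, clustered bursts, rate modulation)
reverses the measured direction through tolerance inflation, while interval
CV contrasts at the event scale, normalized by a fast common noise
background, carry through robustly up to the 100 s scale. At the 300 s
scale a ~45-event window is CLT-Gaussian for any interval CV and the
contrast vanishes; the generator therefore reproduces the group deficit at
30-100 s scales but not at 300 s, and the group difference it produces is
closer to a global shift than a purely state-specific one. This is recorded
as a fidelity limit: real recordings have multi-scale structure the renewal
model lacks.

Other known fidelity limits: the magnitude channel's DFA exponent is ~0.72
(the renewal shot noise floors it below the ~1.0 of real actigraphy) and
the binarized channel's is ~0.5 (its occurrence pattern must stay
short-memory for the group mechanism to work); inter-subject heterogeneity
is not modeled; movements are single-sample events without durations.
Passing cohort tests therefore show that the statistics recover a known
effect through the full chain under these conditions — not that the
generator is a faithful model of children's sleep movement.

For reduced-length runs (2 h series in the cohort-level tests) the two slow
time constants scale with the window: state dwell 1,800 s and smoothing 900
s, preserving the number of state alternations and of smoothed-track
degrees of freedom per night. Scales (30/100/300 s), m, r and the fit range
are never rescaled.

## Stationarity screen

Quantile bins from the whole series (order-statistic edges, so the
statistic is exactly invariant under monotone transforms; natural value
categories when there are no more distinct values than bins), observed
counts from the first half, expected counts from the whole-series
proportions, Pearson chi-square with k-1 dof at the 0.05 level. Because the
first half is part of its own reference distribution, `O - E` equals half
the difference between the two halves and the statistic is approximately
half a chi-square: the literal test is strongly conservative (measured
rejection ~0.1% for iid inputs at the nominal 5%). It is implemented as
described and used as a screen, not a calibrated test.

## Determinism and seeds

Every stochastic function takes an explicit seed; per-recording seeds
derive from the cohort seed through `numpy` `SeedSequence` spawning keyed
by (group, subject, night), so cohorts are bit-identical under the same
configuration and no global RNG state is used anywhere.
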