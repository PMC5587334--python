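# Methods

This note documents the models, numerical choices and limitations of
`strfkit` in the package's own terms.  Empirical statements below are the
ones the test suite and `scripts/acceptance.py` themselves compute.

## Stimulus model: dynamic moving ripple (DMR)

The stimulus is represented at the envelope level only: a frequency x time
matrix of dB deviations from the mean carrier level, sampled on the
analysis grid (default 50 Hz - 40 kHz in 0.05-octave steps, i.e. 193 bins,
at 1-ms resolution).  Carrier-level audio synthesis is deliberately out of
scope — every estimator in the package consumes the time-frequency
representation, and the analytic design envelope is used directly.

At any instant the envelope is a single ripple,

    E(x, t) = (m/2) * sin(2*pi*omega(t)*x + phi(t)),

with `x` the position in octaves above the lower edge, `omega(t)` the
spectral modulation (cycles/octave), `m` the modulation depth (default
40 dB) and `phi(t)` the accumulated phase, `dphi/dt = 2*pi*f_temp(t)` with
`f_temp` the temporal modulation (Hz; negative values are upward sweeps).

The generators of `omega` and `f_temp` are piecewise-linear interpolations
of i.i.d. uniform draws on [0, sm_max] and [-tm_max, +tm_max] at knot rates
of 1 Hz and 3 Hz respectively.  The knot construction is a stand-in for the
original generator, whose trajectory dynamics are not specified in detail;
marginals are therefore only approximately uniform (triangular-ish between
knots), which matters for none of the estimators here because they rely
only on long-term balance and broad modulation coverage.  Both properties
are verified by tests: the per-frequency time average vanishes with
duration, and the 2D modulation spectrum carries <1% of its energy outside
the design ranges (plus knot-rate smearing).

Phase is integrated by a left-Riemann cumulative sum at the sample
resolution; the initial phase is drawn uniformly on [0, 2*pi).  All
randomness in a call flows from one seeded generator.

## Neuron model: linear-nonlinear-Poisson (LNP)

Ground-truth filters are separable spectrotemporal Gabors: a spectral
Gaussian-times-cosine (center frequency, spectral modulation, bandwidth in
octaves) times a temporal Gaussian-times-cosine (best lag, temporal
modulation, bandwidth in seconds), peak-normalized to |value| = 1.  The
excitatory:inhibitory amplitude ratio (default 1.8, matching the
excitation-dominated character of cortical STRFs) is realized as a DC
offset of the spectral cosine.

Spiking follows

    rate(t) = c_k * max(0, r0 + g * (filter . envelope)(t)),

with baseline rate `r0`, gain `g`, causal convolution with zero-padded
history, and a per-trial factor `c_k` drawn from a unit-mean lognormal
whose SD is `trial_jitter_sd` (exactly 1 when the SD is 0; the estimation
segment always uses 1).  Spikes are drawn by time-binned thinning at the
envelope resolution — at most one spike per 1-ms bin, adequate below a few
hundred spikes/s; tests that need very high rates stay below the cap.
Because filter drive scales vary strongly with Gabor bandwidth,
`calibrate_gain` sets `g` so that the drive SD is a chosen fraction
(`modulation`, default 0.7) of the baseline rate, putting simulated units
at comparable signal-to-noise.

What the simulator does *not* emulate: spike-history dependence,
adaptation, non-Poisson count statistics, stimulus-dependent noise
correlations, and any nonlinearity beyond half-wave rectification.  Tests
passing on these units therefore certify the estimation and correction
machinery under a matched model, not performance on real cortical data.

## STA estimation

The raw STRF estimate is the mean mean-subtracted envelope window preceding
each spike, on a frequency x lag grid (lag 0 = spike time, ascending into
the past, default 200 ms window).  Mean subtraction uses the per-frequency
temporal mean of the estimation segment, removing any static spectral bias
of a finite DMR sample.  Spikes earlier than one window are dropped — their
history would mix segments.  Values are per-spike means, which makes merged
trains exact count-weighted means of their parts; the rate-relative-to-mean
display scaling is a separate accessor (`rate_scaled`).  All thresholding
compares STAs with matched spike counts, so the scaling choice cannot
affect any correction decision.  Binning is half-open with clamping at the
segment end.  No stimulus-covariance correction (whitening) is applied: the
DMR's long-term modulation balance is the design reason the plain STA is
used.

## Circular-shift nulls

Null STAs recompute the estimator after rotating all spike times by a
common random offset modulo the segment duration, preserving spike count
and ISI structure exactly while destroying stimulus alignment.  The
ensemble default is 200 shifts.  Shifts inside `build_null_ensemble` are
drawn on the stimulus sample grid (integer multiples of dt): the STA lives
on that grid, so finer offsets only jitter individual spikes within bins.
Grid-aligned shifts admit an exact fast path — one circular
cross-correlation of the envelope with the binned spike counts evaluates
every shifted STA by column gathering, with explicit correction for the few
spikes each shift moves into the dropped initial window.  The fast path is
verified against the literal shift-then-recompute path to 1e-10 in tests.

**Gain null.**  A normal distribution is fitted (maximum likelihood) to the
pooled pixels of all null STAs.  Cutoffs at significance `p` are two-sided
with total tail mass `p` (p/2 per tail), the convention under which an
N-pixel null STA retains N*p pixels in expectation — the analytic
false-positive count the acceptance script reproduces (~400 on a 200 x 200
grid at p < 0.01).

**Cluster-mass null.**  For each retained gain level, null STAs are
themselves gain-thresholded using cutoffs fitted on null data excluding the
tested STA, surviving sign-pure clusters are labeled, and a gamma
distribution (maximum likelihood, location fixed at 0) is fitted to the
collected masses; the cutoff at `p` is the (1-p) gamma quantile.  Two
sampling schemes are provided: `pooled` (default) fits the leave-one-out
pooled normal for each tested STA, with a configurable stride over tested
STAs for speed; `pairwise` fits on every j-th single null STA separately,
one sample per ordered (i, j) pair.  Grid cells with fewer than 20 null
masses (very conservative gain levels) are marked unavailable rather than
fitted.  Joint-variant nulls pool both signs; independent-variant nulls are
fitted per sign.

**Significance grid.**  Thirty levels `p_k = 10^(-9k/29)`, computed in
exponent space; `p_0 = 1` is the uncorrected STA.  For cluster analysis the
grid drops the raw level, the most liberal threshold (p ~ 0.49), and the
eight most conservative levels, leaving 20 gain levels (~0.24 down to
~1e-6.5) crossed with all 30 cluster levels.

## Correction

Correction only zeroes pixels; survivors keep their raw values.  Clusters
are connected components (default 8-connectivity, 4 available) computed
separately on positive and negative survivors, so clusters are sign-pure
and the independent excitatory/inhibitory variants are well defined.
Survival comparisons are `>=` (ties survive) — cutoffs are continuous
quantiles, so ties are measure-zero, but the rule is fixed for
reproducibility.  The four variants: joint gain, independent
excitatory/inhibitory gain, joint gain+cluster, independent
excitatory/inhibitory cluster.

## Prediction and validation

LN predictions convolve the corrected STRF with the mean-subtracted
validation envelope (zero-padded history) and half-wave rectify.  The first
window-length of samples is a convolution transient and is excluded from
correlations by default (configurable); accuracy is Pearson correlation
between the block-mean-rebinned prediction and a PSTH computed natively at
each bin size (1, 2, 5, 10, 20, 50, 100 ms), with 10 ms the headline
resolution.  A constant series (e.g. an all-zero prediction from an
over-thresholded STRF) yields an undefined correlation that propagates as
NaN — treated as minus infinity during threshold selection so selection can
never prefer an empty STRF — and is never silently coerced to 0.

Threshold selection splits the validation span into 1-s chunks randomly
assigned to equal-duration validation and test halves, repeated 10 times;
the argmax setting on the validation half is scored on the test half, with
exact ties broken toward the most conservative setting (smallest p, gain
levels before cluster levels).  Because predictions depend only on the
stimulus, per-setting predictions are computed once per unit and reused
across iterations; the grid sweep exploits nestedness of survivor sets
along each p-axis to update drives incrementally (verified against
correct-then-convolve per setting).  Fixed-setting policies use p = 0.01
(gain) and p_gain = 0.05 with p_clst = 1e-5 (cluster), the two fixed
configurations of interest; the cluster-mass null is fitted at gain level
0.05 on demand since that level is not on the 30-point grid.

The stimulus-driven variance slope is the ordinary least-squares slope of
prediction correlations on response correlations across units, where the
response correlation is the split-half PSTH correlation (TS) and the
prediction correlation is taken against one half-trial PSTH.  Note the
rigorous noise ceiling under this pairing: a deterministic prediction
satisfies E[r(pred, half-PSTH)] <= sqrt(TS); accuracy against a full-trial
PSTH may legitimately exceed TS itself for a well-matched model.

## Screening

The reliability index (RI) cuts the estimation segment into equal segments
(default 30), computes STRFs from two random disjoint halves of the
segments — each gain-corrected at p < 0.05 — and averages the pixel-vector
correlation over 200 iterations.  Cutoffs for a half-count STA are obtained
by rescaling the full-data null fit analytically (pixel SD scales as
1/sqrt(N) for a mean-scaled STA) instead of building a null ensemble per
iteration, which would multiply the cost by the iteration count for no
statistical benefit under the matched-count scaling law.  Trial similarity
(TS) correlates PSTHs (10-ms bins) from two random disjoint trial halves,
averaged over 100 iterations.  Both are screened against empirical nulls
from circularly shifted spikes (trials shifted independently for TS); a
unit passes at level alpha when the observed metric strictly exceeds the
empirical (1-alpha) null quantile (default 100 nulls at alpha = 0.01).

## Modulation analysis

The ripple transfer function is the folded 2D Fourier magnitude of an STRF.
Folding is energy-preserving: each quarter-plane cell holds the
root-sum-square of the FFT magnitudes over its symmetry-equivalent
full-plane cells, so total RTF power equals total FFT power exactly (the
fold combines upward and downward sweep energy; this is the power-domain
version of folding along the temporal midline).  tMTF and sMTF are column
and row sums.  The band-pass/low-pass rule operates on 10*log10 of
peak-normalized RTF power: band-pass requires a fall of at least 3 dB on
both sides of the peak; high-pass shapes are not expected for causal STRFs
and are folded into low-pass with a warning.  BMFs: the peak frequency for
band-pass MTFs; half the upper 3-dB cutoff (linearly interpolated in dB,
Nyquist when the MTF never falls 3 dB) for low-pass MTFs.  BMF changes
between correction choices are reported as absolute percent change relative
to the conventional (fixed p_gain < 0.01) estimate.

## Problem sizes and determinism

Default study conditions for simulated populations: 193 x 200 STA grid,
5-minute estimation segments, 30-s validation segments with 20 trials,
baseline 8 spikes/s, modulation index 0.7, 20% trial jitter, 200-shift null
ensembles with a stride of 8 over tested nulls for cluster-mass sampling.
Unit tests use coarser frequency grids (~0.2-0.8 octave steps) and shorter
segments; the acceptance checks run the full-resolution conditions.  Every
random procedure takes an explicit seed, simulation is bit-for-bit
reproducible under a fixed seed, and the pipeline writes a manifest with
the seed and a hash of the analysis parameters; reruns produce
byte-identical summaries.

## Known limitations

- The knot-based modulation trajectories approximate, but do not replicate,
  the original DMR generator's statistics; absolute drive levels per unit
  depend on how long the trajectory dwells near the unit's tuning, so
  short validation segments can under-sample a narrowly tuned filter.
- The gamma fit extrapolates deep tails (p = 1e-9) far beyond the sampled
  null masses; cutoffs there are model-based by construction.
- The analytic RI rescaling assumes independent spike draws; strong rate
  correlations at very high rates would make half-count cutoffs slightly
  conservative.
- Envelope-level simulation cannot expose artifacts of carrier synthesis,
  sound-level calibration, or cochlear preprocessing.
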