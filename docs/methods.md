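# Methods

This note records the models, estimators, and design choices behind
`cochleartune`, and what the synthetic verification does and does not
establish about real recordings.

## Synthetic ear model

**Stimuli.** Linear sweeps rendered at 50 kHz: probe 0.5→8 kHz over
2.05 s at 40 dB SPL, suppressor 0.54→8.04 kHz at 55 dB SPL, 25-ms
raised-cosine ramps, 40 repetitions per condition (even counts are
required so the odd/even noise-floor split has matched halves).

**Emission.** The emission is the probe passed through a delay-and-scale
operator evaluated at the instantaneous sweep frequency:
`e(t) = A(f(t)) · cos(φ_probe(t − τ(f(t))))`. To first order in the sweep
rate the extracted relative phase is φ(f) = −f·τ(f) cycles, so the
phase-gradient delay has the closed form **N(f) = f · d[f·τ(f)]/df** —
the generator's exact ground truth (`EmissionModel.true_n_sfoae`). The
residual sweep-rate term contributes k·τ²·(≲1), of order 0.01 cycles for
realistic delays, two orders below the measurement.

Default profiles emulate a small-bird ear: level 10 dB SPL, rolling off
at 30 dB/octave above 5.5 kHz (the emission descends into the noise floor
near 6 kHz); three Gaussian notches in dB on the log-frequency axis
(16–22 dB deep, widths 0.05–0.06 octaves) reproducing the deep spectral
notches of measured emission spectra; and a power-law delay
N(f) = n₀·(f/1 kHz)^0.548 with n₀ = 1.5 cycles, i.e. a 1.65 dB/octave
rise of 10·log₁₀(N). The suppressor is ideal by default
(`suppression_fraction = 1`): the combined condition carries none of the
emission. Repetition noise is white with RMS 1 mPa by default, which
after 40-fold averaging and the narrowband spectral fit leaves the noise
floor ~13 dB below a 10-dB-SPL emission — a realistic margin that makes
the exclusion rules do real work. Artifacts are 1-ms raised-cosine
clicks at Poisson times (default 0.05 /s, amplitude 25× the noise RMS),
sized to exercise the 20-ms excision rule.

**Nerve fibers.** Tuning curves are sampled at 28 points/octave
descending from 6 kHz (threshold tracking proceeds downward in real
experiments), dropped where the model threshold exceeds 80 dB SPL (the
highest level tested). Shapes are rounded-exponential
(W = (1+pg)e^(−pg), the standard auditory-filter form; ERB = 4·CF/p,
Q10 = p/(2·3.8897), so QERB/Q10 = 1.9449 for every roex fiber) or
log-symmetric V with straight flanks. Sharpness follows
Q10 = a·(CF/1 kHz)^b with defaults a = 3.0, b = 0.289 (0.87 dB/octave in
10·log₁₀ Q10) and 10% log-normal jitter; thresholds at CF follow a bowl
with its best point (~8 dB SPL) near 2.8 kHz plus 3 dB of scatter.

## Emission extraction

**Artifact rejection** excises 20 ms (a half-window each side) around
every sample whose deviation from the across-repetition mean exceeds the
threshold; overlapping windows merge. The default threshold is 6× the
median absolute deviation of the deviation ensemble — detection must run
on deviations, not raw waveforms, or the stimulus itself would trigger
it. Excised samples are flagged and ignored by the per-sample average
(zeroing them would bias the spectral fit); repetitions more than half
excised are dropped. Samples with no surviving repetition are linearly
interpolated and logged.

**Spectral estimation.** At each analysis time the residual is fit by
weighted least squares to a cos/sin pair following the probe's
instantaneous phase, Hann-weighted over a 20-ms window hopped by 5 ms
(≈10–160 stimulus cycles across the band — long enough for a stable fit,
short enough to resolve notch structure). Windows overlapping the
stimulus ramps or the signal edges are dropped. The complex amplitude is
assigned to the sweep frequency at the window center; phase is unwrapped
along the ascending grid *before* any masking so gaps cannot corrupt the
unwrapping. Levels are reported as dB SPL of the RMS pressure.

**Noise floor.** The three-condition residual is formed separately from
odd- and even-indexed repetitions; half their difference has the same
noise power as the full-average residual (equal split sizes) and no
emission, and is passed through the same spectral estimator. Unequal
odd/even counts are truncated to the smaller.

**Delay and exclusions.** N_SFOAE = −f·dφ/df by centered differences
(one-sided at the edges). Points are excluded when the level is less
than 10 dB above the *median* noise floor, or at the base of a magnitude
trough: a local minimum ≥10 dB below both flanking maxima excludes
points within ±1/24 octave of the minimum or within 3 dB of the minimum
level inside the notch (phase is unreliable where reflection components
cancel). In noise-only sessions ≥95% of points fail the SNR rule.

## Tuning-curve metrics

Order matters: curves are smoothed first (five-point triangular kernel
(1,2,3,2,1)/9, renormalized over in-range taps at the edges so no
thresholds are fabricated), then CF (global minimum; ties resolved by
the geometric mean of tied frequencies; a minimum at a grid end flags a
truncated tip), then Q10 (first crossings of minimum+10 dB moving
outward from CF, linearly interpolated in (log₂ f, dB); a flank that
never reaches +10 dB leaves the metric undefined rather than
extrapolated), then QERB (trapezoidal area of 10^((T_cf−T)/10) on the
linear-Hz axis over the measured span; ERB is defined in Hz).

A known limitation: at 28 points/octave the triangular smoothing raises
the measured tip and widens the 10-dB bandwidth, biasing Q10 downward by
~4% at Q10 ≈ 3 and up to ~10% for the sharpest fibers. Because the bias
grows with sharpness it also flattens the measured Q10-vs-CF slope by
roughly 0.06–0.09 dB/octave. This is a property of the processing chain
itself (any data processed this way carries it), which is why
ground-truth recovery is asserted only to within the population jitter
and why slope recovery is asserted on the generated population.

## Trends, ratio, prediction

The local-mean trend at grid frequency f₀ is the Gaussian-weighted mean
with weights exp(−log₂(f/f₀)²/(2σ²)); grid points with no datum within
3σ are undefined (NaN), never zero. Delay data are fit in the
group-delay domain (N·f, approximately normally distributed) and divided
by f₀ afterwards; Q metrics are averaged directly (no transform is
established for them). σ = 0.25 octaves for delay trends, 0.5 for Q
trends; the evaluation grid is log-spaced at 48 points/octave — finer
than both kernels, and halving the spacing changes the interpolated
ratio by <0.5%.

CIs are percentile bootstrap (2.5/97.5) over the sampling units — ears
for emission data, fibers for nerve data — with 1000 replicates, seeded.
A replicate is assembled from per-unit partial weighted sums, which is
algebraically identical to recomputing the trend on the resampled
points. Grid points undefined in >10% of replicates are marked
unreliable. Small-sample narrowness is a known property of the plain
percentile interval: with 22 resample units its expected coverage of a
95% target is ≈92–93% (the t-versus-z gap, compounded slightly by
finite-replicate quantile noise). We keep the plain percentile form
because it is the conventional choice for this analysis; users needing
strict nominal coverage at ~20 units should prefer bootstrap-t.

The tuning ratio r(f) = QERB/N_SFOAE is the quotient of the two trends
on the delay trend's grid (the Q trend is interpolated linearly in
(log₂ f, value); alignment is otherwise arbitrary and this choice is
stable under grid refinement). Prediction multiplies a delay trend by r;
on a single species this closes identically (Q = N·(Q/N)), which is
asserted to 1e−9. Where a reference sample lacks high-CF fibers, Q10 is
extended by OLS of Q10 on log₂ CF restricted to CF > 1.7 kHz, evaluated
with ±1 SE of the mean prediction on the extension grid (3.35→4.6 kHz);
log₂ CF is the regressor because every other frequency axis in the
chain is logarithmic. The extended portion of r carries the band
multiplicatively. The QERB/Q10 scale factor defaults to 1.76 (a
representative avian median) but is taken from the measured per-fiber
median whenever a metrics sample is available.

`db_per_octave` is the OLS slope of 10·log₁₀(value) on log₂(f) —
3.01 dB/octave means doubling per octave. LOESS (tricube weights over
the span fraction of nearest points, local first-degree fit on the
log₂-frequency axis, span 0.65) is provided for summarizing scattered
behavioral points; it is exact for data linear in log₂ f.

## Banded mixed-effects analysis

Band centers are geometric from 1 to 5 kHz ({1000, 1495, 2236, 3344,
5000} Hz); edges are geometric midpoints, mirrored at the outside. Per
ear and band, a first-degree polynomial in log₂ f is fit by bisquare
IRLS (tuning constant 4.685, MAD scale, ≤50 iterations; reduces to OLS
on clean data, and a gross outlier among ten points moves the estimate
<1%) and evaluated at the center; bands with fewer than two points are
missing for that ear.

The frequency effect is tested in the model value ~ band (categorical)
+ (1 | ear), REML, α = 0.01. For a complete balanced ear×band table the
band F test has the exact classical form F = MS_band/MS_resid with
(b−1), (a−1)(b−1) degrees of freedom — identical to the
REML-Wald/Satterthwaite result whenever the REML solution is interior,
and an exact test under normality (its empirical type-I error at
α = 0.01 is 0.010 over 20,000 null simulations) — so it is used
directly, with method-of-moments variance components. Unbalanced tables
use a REML Wald F with denominator df N − ears − bands + 1, flagged
`df_fallback`; REML non-convergence falls back to a fixed-ear two-way
ANOVA, flagged. For the balanced 22-ear × 5-band layout the fallback df
equals the classical 84.

## What the synthetic verification shows — and does not

The generator gives every stage a recoverable target: stimulus terms
cancel to machine precision; a constant-latency emission at 20 dB
per-repetition SNR is recovered with N_SFOAE within 5% of f·τ across
1–5 kHz; Q metrics match dense-grid brute force within 1%; prediction
closes identically on one species and within a few percent across two
synthetic species sharing r. What it does not emulate: middle-ear and
probe-system transfer functions (assumed compensated upstream),
two-source emission mixing and its fine structure, efferent or
level-dependent effects, non-white physiological noise, and real tuning
curves' irregular sampling and tip asymmetries. Passing tests therefore
establish correctness of the computations under the stated measurement
model, not the biological accuracy of any particular recording.

## Problem sizes

Unit tests run on shortened sweeps (0.3–1 s, reduced spans) where only
estimator behavior is at stake; the end-to-end properties use the full
2.05-s, 50-kHz, 40-repetition sessions. The acceptance script runs 22
synthetic ears (plus a 10-ear reference species), 127 + 289 fibers, 500
bootstrap-coverage populations, and 2000 null simulations — sizes chosen
to match the study design while keeping a desk run around a minute.
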