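# cochleartune

Otoacoustic estimation of cochlear frequency tuning, built as a tested,
fully synthetic-verifiable pipeline for auditory physiologists.

## The problem

The sharpness of cochlear frequency tuning is fundamental to hearing, but
measuring it directly requires invasive auditory-nerve recordings.
Stimulus-frequency otoacoustic emissions (SFOAEs) — faint sounds the
healthy cochlea emits at the stimulus frequency — offer a non-invasive
alternative: filter theory links longer emission delays to sharper tuning.
This package implements the complete computational chain needed to test
that link in a small bird:

1. **Emission isolation** (suppressor paradigm). A 40-dB-SPL probe tone is
   swept 0.5→8 kHz over 2.05 s; a 55-dB-SPL suppressor is swept 0.54→8.04
   kHz. From the ear-canal pressure recorded for probe, suppressor, and
   both together, the emission is the vector residual

   P_SFOAE = P_probe + P_suppressor − P_probe+suppressor,

   since everything that combines linearly cancels and the suppressor
   removes the emission from the combined condition. Transient artifacts
   are excised (20 ms around every threshold crossing) before averaging.
2. **Swept-tone spectral analysis.** A Hann-weighted least-squares fit of a
   quadrature pair locked to the probe's instantaneous phase (20-ms
   window, 5-ms hop) yields emission magnitude and phase along the sweep.
   The noise floor is the same analysis applied to half the difference of
   odd- and even-trial residuals. Points within 10 dB of the median noise
   floor, or at the base of magnitude notches, are excluded.
3. **Delay in stimulus cycles.** N_SFOAE(f) = −f·dφ/df with phase φ in
   cycles — the dimensionless phase-gradient delay that tracks tuning
   quality.
4. **Auditory-nerve tuning metrics.** Frequency-threshold tuning curves are
   smoothed with a five-point triangular window; CF is the frequency of
   lowest threshold, Q10 = CF / (bandwidth 10 dB above threshold minimum),
   and QERB = CF / ERB with the ERB computed from the area under the
   inverted tuning curve on a linear power scale.
5. **Tuning ratio and prediction.** Gaussian-weighted trends (σ = 0.25
   octaves for delays, fit in the group-delay domain; σ = 0.5 octaves for
   Q metrics) with 1000-rep bootstrap CIs over ears/fibers give the tuning
   ratio r(f) = QERB/N_SFOAE. Multiplying another species' N_SFOAE trend by
   r predicts its cochlear tuning; Q10 can be extrapolated (OLS on log2 CF
   above 1.7 kHz) where a reference sample lacks high-CF fibers.
6. **Banded statistics.** Per-ear values are condensed into five log-spaced
   bands (1–5 kHz, robust per-band line evaluated at the center) and the
   frequency effect is tested with a linear mixed model (band fixed, ear
   random intercept, REML, α = 0.01).

Because real recordings are large and instrument-specific, the package
includes a first-class synthetic ear (`cochleartune.synthetic_ear`): swept
sessions with an embedded emission of known level, notch structure, and
frequency-dependent group delay (so the extracted N_SFOAE has a closed-form
ground truth), plus V-shaped tuning-curve populations whose Q10 follows a
known power law in CF. Every stage is verified against these ground truths
and independent brute-force oracles.

## Worked example

The numbered drivers under `analysis/` run a desk-scale study (6 synthetic
ears × 40 repetitions, 127 fibers) end to end:

```bash
python analysis/01_simulate.py          # WAV sessions + tuning curves
python analysis/02_extract_sfoae.py     # emission spectra and delay curves
python analysis/03_nerve_metrics.py     # CF, Q10, QERB per fiber
python analysis/04_trends_prediction.py # trends, tuning ratio, prediction
python analysis/05_band_statistics.py   # banded mixed-effects tests
```

Output from a run of steps 03–05 (tables land in `results/`):

```
127 fibers; Q10 defined for 125
QERB/Q10 median 1.868 (IQR 1.844-1.887, n=125)
Q10 recovery vs ground truth: median |error| 4.2% (median bias -4.2%, ...)
N_SFOAE trend slope: 1.58 dB/octave (generator truth 1.65)
Q10 trend slope (measured fibers): 0.81 dB/octave (generator law 0.87)
tuning ratio r at 700 Hz: 3.41
tuning ratio r at 5500 Hz: 2.02
QERB predicted from emission delays x reference r: median deviation from
the measured QERB trend 4.4% over 130 grid points (22 from extrapolated Q10)
nsfoae : F(4,20) = 51.99, p = 2.74e-10 (significant at alpha=0.01; balanced_exact)
level  : F(4,20) = 3.41, p = 0.028 (ns at alpha=0.01; balanced_exact)
```

Reading this: the per-fiber equivalent-rectangular-bandwidth sharpness
exceeds the 10-dB sharpness by a median factor of 1.87 (the analytic value
for rounded-exponential filters is 1.944; the 4% shortfall is the bias of
the mandated five-point smoothing at 28 points/octave). Emission delay in
cycles grows at ~1.6 dB/octave, about twice the Q10 growth rate, and the
tuning ratio r falls from ~3.4 at 700 Hz to ~2 at 5.5 kHz. Multiplying the
delay trend by a reference species' r recovers the measured QERB trend to
within a few percent, and the banded mixed model confirms a highly
significant frequency effect on delay.

A `cochleartune` CLI wraps the same stages (`simulate`, `extract`, `tc`,
`trend`, `ratio`, `predict`, `stats`); `cochleartune --help` lists options.

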