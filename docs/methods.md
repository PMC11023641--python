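# Methods

This note documents the models, algorithms, defaults and limits of the
`cardiovagal` pipeline in the order data flows through it.

## Synthetic trial generator

The generator has two tiers sharing one root seed (all randomness flows
through `numpy.random.SeedSequence` spawns keyed by subject/day/session, so
a fixed seed yields a bit-identical trial).

**Metric tier.** 24 subjects (11 taVNS, 13 Sham by default), each with a
number of recording days drawn from N(11.1, 6.8²) rounded and clipped to
[2, 13].  Every subject has a per-metric baseline drawn from
population-plausible ICU distributions (e.g. HR 76 ± 8 bpm, RMSSD 28 ± 8 ms,
QTc 430 ± 20 ms, ICP 12 ± 3 mmHg).  For each day after Day 1 the
*change-from-Day-1* of metric *m* is drawn as N(μ_arm, σ_m) with
μ_taVNS − μ_Sham = d_m·σ_m, so the requested `arm_effects` (in Cohen's d
units) are realized in expectation over subject-days.  Default effects
mirror a taVNS-like pattern: RMSSD +0.42, SDNN +0.10, QTc −0.57, HR −0.01,
PPI −0.49, respiration +0.37.  The seven HRV variables share a latent
two-factor structure (an overall-variability factor and a parasympathetic
factor with loadings ≥ 0.75 on disjoint variable sets, plus a shared RMSSD
loading), so they are genuinely correlated — without this the factor
analysis stage would have nothing to find.  Per-session acute heart-rate
deltas follow a linear model with intercept 0.73, arm shift −0.29, mRS-change
slope 1.47, arm × mRS interaction −1.85, a subject random intercept (SD 1)
and residual SD 2; these defaults give the mixed-model stage a non-trivial
signal with a known answer.

**Signal tier.** Raw signals are rendered lazily per treatment session: a
block spanning pre/during/post (20 minutes each) plus 2-minute margins.
The RR tachogram is a stationary Gaussian process built from two narrowband
components (Gaussian spectral bumps at 0.10 Hz and 0.25 Hz, i.e. the LF and
HF bands), sampled by inverse FFT with uniform random phases.  The two
amplitudes are solved numerically (deterministic function evaluations, no
randomness inside the solver) so the realized SDNN and RMSSD of the clean
series equal the targets; when a requested pair sits beyond the stationary
ceiling implied by the band geometry, the solver falls back to the closest
achievable pair and logs the miss.  Ectopic beats (premature by 30–50% of
the preceding interval) and outliers (> 2.1 s or < 280 ms) are injected
after the clean series is built, with ground-truth labels returned.

The ECG renders each beat as a sum of raised-cosine (Hann) bumps
(P, Q, R, S, T).  Compact support makes every onset/offset an exact sample
index; exact ground truth was deliberately preferred over morphological
realism because the signal's purpose is to score the delineator.  The
default QT rule is QT = QTc·√RR, which makes every beat's true Bazett QTc a
known constant.  Rendering full 24-hour, multi-day 500 Hz records for a
whole trial would be enormous and add nothing to the analysis, so raw ECG
exists only around sessions; daily group-level analyses run on the metric
tier.  Vitals are AR(1) processes (φ = 0.98) around the arm-specific daily
means — only their daily means and SDs enter the analysis.  The
treatment-event trace is a unit rectangular pulse train over sessions with
additive uniform noise bounded below half-maximum.

**What the generator does not emulate.** Real SAH recordings contain
non-stationary autonomic swings, medication effects, arrhythmias, electrode
artifacts and T-wave morphology changes.  Passing tests therefore show that
the pipeline is *correct* (it recovers what is truly in the signal), not
that its accuracy numbers transfer to bedside recordings.

## ECG processing

* Filtering: 0.5 Hz fifth-order Butterworth high-pass plus a 60 Hz notch
  (second-order IIR, Q = 30), both applied forward-backward.  Zero-phase
  application preserves fiducial timing; gaps are propagated, never
  interpolated.
* R detection: the signal is band-limited to 5–22 Hz, the squared gradient
  averaged over 100 ms, and the envelope thresholded at 0.4 of its own 95th
  percentile of candidate peak heights — adaptive and amplitude-scale
  invariant.  A 200 ms refractory period (physiological upper rate bound)
  prunes double detections; beats within 300 ms of a gap are dropped.
* Delineation: quadratic-spline dyadic wavelet transform (à-trous scheme,
  smoothing filter [1,3,3,1]/8, derivative filter [2,−2]), with each band
  re-aligned by its accumulated group delay.  QRS boundaries are read at
  scale 2⁴ (at 500 Hz): the modulus-maxima pair around R is located, and
  the first/last modulus maximum before/after the pair (the Q and S waves,
  threshold 6% of the pair amplitude) marks onset/offset.  The T wave is
  the dominant *adjacent* opposite-signed modulus-maxima pair at scale 2⁵
  in a window from 60 ms after the QRS offset to 150 ms before the next
  beat; its peak is the zero crossing between the pair and its offset the
  crossing of 30% of the trailing maximum.  Beats with no supra-threshold
  T pair carry absent T fields; beats with out-of-order fiducials are
  dropped and counted.  The threshold fractions were fixed against the
  generator's exact fiducials; on clean signals the mean QT error is ~2 ms.
* Event binarization: rectify, threshold at half the trace maximum, keep
  contiguous supra-threshold runs of at least 60 s.

## RR cleaning and metrics

Outliers (RR > 2000 ms or < 300 ms) are flagged first; each remaining
interval is then compared with the previous *retained* interval and flagged
ectopic above a 20% relative difference — comparing against the retained
chain prevents one outlier from poisoning its successor.  Flags annotate,
never mutate.

* SDNN uses the n−1 sample SD (clinical HRV convention).
* RMSSD and pNNI_50 use successive differences between *adjacent valid*
  intervals only; pairs spanning a flagged beat are excluded.  pNNI_50
  counts differences strictly greater than 50 ms.
* Spectral powers: valid intervals are resampled at 4 Hz with cubic
  interpolation, Welch PSD (120 s segments, 50% overlap, constant detrend);
  total power integrates 0–0.4 Hz excluding DC; normalized HF power is the
  0.15–0.4 Hz share of that total.  Lomb-Scargle was considered and
  rejected: at the pipeline's window lengths the resampled-Welch route is
  the dominant convention and materially simpler.
* CVI/CSI follow the Toichi Lorenz-plot convention: SD1² = var(ΔRR)/2,
  SD2² = 2·SDNN² − SD1², L = 4·SD2, T = 4·SD1, CSI = L/T,
  CVI = log₁₀(L·T).  These indices are named but not defined in most
  clinical reports; the Toichi definition is the original one.
* QTc = QT/√RR (Bazett), RR in seconds, per beat with the interval ending
  at that beat; prolonged-QTc uses an inclusive 500 ms threshold.

## Aggregation

A "day" is a consecutive 24 h block from each subject's recording start.
Daily summaries require ≥ 4 h of valid ECG coverage (configurable); days
failing coverage are absent with a logged reason.  Change-from-Day-1 is
zero on Day 1 by construction.  Three-day bins are {2–4, 5–7, 8–10, 11–13};
Day 1 is the baseline and never binned, and each subject-day is one
observation.  Event-locked analysis uses 6-minute windows stepped 3 minutes
bi-directionally from session onset; windows are z-scored against the daily
mean/SD obtained with the same sliding-window procedure over the whole day
(a zero daily SD makes that metric absent), and pre/during/post period
means use only fully contained windows.  Windows touching a beat gap longer
than 3 s are dropped.

## Factor analysis

The seven variables (RMSSD, SDNN, pNNI_50, total power, normalized HF
power, CVI, CSI) are z-scored within subject (or subject-day for
window-level tables) and decomposed into two factors.  Extraction is
minimum-residual: uniquenesses are optimized by L-BFGS-B (bounds
[0.005, 1], SMC start values) with the rank-2 eigen-approximation inside
the objective; varimax (Kaiser, SVD iteration) rotates for
interpretability; scores use the regression (Thurstone) estimator
F = Z R⁻¹ Λ.  Because factor order and sign out of the optimizer are
arbitrary, labels are assigned by loading pattern: the factor loading
most heavily on {RMSSD, SDNN, pNNI_50, total power} is *Overall HRV*; a
factor loading positively on RMSSD and HF power and negatively on CSI is
*Parasympathetic Activity*.  Rows with any missing variable are dropped
listwise.  Bartlett's sphericity test gates the fit with a warning (not a
hard stop) when correlations are absent.

## Statistics

* Group comparisons: Shapiro-Wilk on each group at α = 0.05; Student's t
  iff both pass, else two-sided tie-corrected Mann-Whitney U.  Cohen's d
  with the pooled sample SD is reported regardless of the test chosen,
  signed taVNS − Sham.  Bonferroni ×6 for the cardiac family (HR, QTc,
  RMSSD, SDNN, two factors), ×4 for the vitals family.
* TOST equivalence: two one-sided pooled-SD t-tests against ±margin
  (5 bpm HR, 50 ms QT, 2 mmHg BP); equivalent iff both one-sided p < α.
* Power: noncentral t with df = n₁+n₂−2 and ncp = d·√(n₁n₂/(n₁+n₂));
  required n is the smallest equal-arm size reaching the target.
* Mixed model: response ~ treatment + mRS change + interaction with a
  per-subject random intercept, REML, Wald CIs; a singular fit falls back
  to OLS with a warning (the fixed effects remain consistent).
* Interaction regression, ANCOVA (age as decade midpoint) and Pearson
  correlation are ordinary least-squares / moment estimators via
  statsmodels and scipy.

## Numerical and scale choices

Monte-Carlo calibration checks use fixed seeds and principled tolerances:
rates estimated from finite replicates are compared with a one-sided
binomial test against the nominal level rather than a hard equality, so
the checks fail only on genuine miscalibration, not sampling noise.  The
pipeline's full-trial demonstrations run the metric tier at the study's
actual size (24 subjects, ~11 days) and push a configurable number of
session blocks (default 2) through the raw-signal path; this keeps a full
run around seconds while every signal-path property is still exercised
end-to-end on 600-second records in the test suite.

## Known limitations

* The delineator's thresholds are tuned to the template morphology class
  (upright R, upright T); inverted or biphasic T waves are out of scope.
* Bazett's correction over- and under-corrects at extreme heart rates;
  it is used because it is the correction the safety question is posed in.
* The synthetic acute response enters the session tables directly rather
  than being expressed in the rendered ECG beyond a uniform post-onset HR
  shift; event-locked signal analyses therefore validate mechanics, not
  acute-effect sizes.
* Mann-Whitney p-values use the large-sample approximation for n > 20.
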