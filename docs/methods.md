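# Methods

## Signal model and preprocessing

The raw observation is an ordered series of RR intervals (ms).  Cumulative
beat time is derived as t[k] = Σ_{i≤k} RR_i / 1000; a beat belongs to an
analysis window when its *end* time falls in the half-open interval
[start, end).  The default window, 360–480 s, keeps minute 7 through
minute 8 of a 10-minute warm-up, late enough that the on-transient of the
bout has settled and long enough (≈240–300 beats at 120–150 bpm) for a
stable short-term DFA slope.

**Artifact correction.** Beat-detection artifacts (ectopic beats, missed
beats, spuriously split beats) corrupt α1 badly because they inject
large-amplitude, high-frequency structure exactly at the box sizes DFA
measures.  Commercial HRV software uses proprietary "automatic" filters; we
implement a documented equivalent: a beat is flagged when its deviation
from the local 11-beat median exceeds c times the rolling quartile
deviation of the successive RR differences (c = 5.2, window 91 beats,
floored at 20 ms so metronomic stretches are not flagged wholesale), or
falls outside the 200–3000 ms plausibility window.  Flagged beats are
replaced by a cubic spline over the surrounding normal beats.  The detector
is validated statistically — recall ≥ 0.8 on seeded synthetic injections,
zero false corrections on clean fractal series — not against any particular
vendor's output, and downstream cohort statistics use measured α1 values as
data, so they do not depend on the detector's fine behavior.  Recordings
with more than 5% corrected beats are excluded; this threshold is a
subject-screening rule, surfaced in the CLI as its own exit code.

**Detrending.** Slow non-stationarities (drift in exercise intensity,
thermoregulation) are removed with a smoothness-priors smoother: the trend
is (I + λ²D₂ᵀD₂)⁻¹z with D₂ the second-difference operator and λ = 500
(dimensionless; larger λ pushes the smoother's cutoff toward lower
frequencies).  The solve uses a sparse Cholesky-style factorization; a
dense solve is the test oracle.  The operator removes the mean along with
the trend, so the pre-detrend mean is re-added: DFA is mean-invariant
either way, but mean heart rate (60000 / mean RR) must come from
physiological intervals.  Order of operations is fixed and documented:
correct → extract segment → detrend → DFA; detrending is applied to the
extracted segment, mirroring per-window preprocessing in HRV software.
Whether any given vendor applies the same order internally is not claimed.

## DFA α1

The mean-subtracted intervals are integrated to a profile, the profile is
divided into ⌊N/n⌋ non-overlapping boxes of n beats from the start
(remainder discarded — the original convention; no backward second pass), a
least-squares line is removed per box, and F(n) is the RMS residual pooled
over covered points.  α1 is the unweighted least-squares slope of log₁₀F
against log₁₀n over all 13 integer box sizes n = 4…16.  The log base is
irrelevant to the slope.  A series needs at least `min_beats` (default 100,
> 2·16 by construction) and strictly positive F(n) everywhere; a constant
series raises a degenerate-signal error rather than returning a slope.

Expected behavior on canonical signals: α1 ≈ 0.5 for white noise, ≈1.0 for
1/f noise, ≈1.5 for Brownian motion.  At these box sizes the estimator has
a known small upward bias at the uncorrelated end (white-noise estimates
average ≈0.58 at N = 1000); tests and the acceptance script therefore check
recovery within stochastic bands (±0.1 around the mean over seeds, ±0.15
per class) rather than point equality.

`rolling_alpha1` re-evaluates α1 over a trailing window (default 120 s)
every 5–30 s; windows with too few beats yield NaN markers instead of
raising, so a live monitoring loop survives dropouts.

## Reliability and inference statistics

All SDs are sample SDs (n − 1).  For each monitoring variable:

* **CV** = 100·SD/mean over the whole group's PRE values of the light
  session (the designated baseline);
* **SWC** = f·(CV/100)·mean_baseline, algebraically f·SD_baseline, with
  f = 0.3 for performance measures (jump height/force, foot-tapping) and
  f = 0.5 for physiological and psychometric measures (α1, HR,
  recovery/stress scores);
* **TE** = SD(PRE_light − PRE_heavy per-participant differences)/√2 — the
  two PREs act as a test-retest pair on days when the true score should not
  have changed, and a difference of two equally noisy measurements has
  variance 2·TE².

**Paired comparisons.** Differences are always POST − PRE (heavy − light
for the once-per-session RPE contrast).  A Shapiro–Wilk test on the
difference scores at α = 0.05 selects a paired t-test (normal) or a
Wilcoxon signed-rank test; the registry can force the choice per variable —
RPE, an ordinal category-ratio scale, is forced to Wilcoxon.  The 90% CI of
the mean difference is t-based (df = n − 1) regardless of the test chosen.
Effect sizes: Cohen's dz = mean(diff)/SD(diff) for t-tested variables
(verified to reproduce the cohort's printed large effects, which a
pooled-SD d does not); r = |z|/√n for Wilcoxon, with z the plain normal
approximation of W+ without tie or continuity correction.  The Wilcoxon p
is exact for n ≤ 25 with no zero differences, computed by a
generating-function convolution over doubled midranks (valid under ties);
otherwise the normal approximation is used.  Pairwise deletion handles
missing cells (one athlete lacks heavy-session jump/tap values); n is
reported per comparison.

**Group MBI.** With SE = SD(diff)/√n and T ~ Student-t(df = n − 1):
chance_positive = P(T > (SWC − mean_diff)/SE), chance_negative =
P(T < (−SWC − mean_diff)/SE), trivial the remainder; the unrounded triplet
sums to 100 exactly.  **Individual MBI** uses the normal distribution with
SD √2·TE around the observed change, with a 50% CI of
delta ± 0.6745·√2·TE.  Both distribution choices were reverse-engineered
from the published chance triplets (t for groups, normal for individuals)
and are validated against them in the acceptance tests.  Qualitative
descriptors map the dominant chance onto the standard probability scale
(<0.5% most unlikely … >99.5% most likely): the dominant substantial
direction labels the result when its chance is ≥ 25%, otherwise the trivial
chance does; a result is "unclear" when both substantial directions exceed
5%.  The published labels for two jump-height rows do not follow any single
simple rule we could identify, so labels are informative output while the
numeric chances are the tested contract.  Display rounding is to integer
percentages ("99/01/00"); all internal values are unrounded, so a displayed
triplet may sum to 99–101.

## Synthetic data

`generate_fractal_rr` synthesizes series by shaping a Gaussian spectrum to
power ∝ f^(−β) with β = 2·α1_target − 1 and random phases, then rescaling
to a target mean/SD (defaults 450 ± 25 ms, the cohort's warm-up intensity)
and clipping to 200–3000 ms.  The β↔α1 mapping is asymptotic, hence the
stochastic tolerances above; clipping slightly biases extreme-SD
specifications.  Spectral synthesis was chosen over a Davies–Harte
fractional-Gaussian-noise construction for simplicity and speed; it covers
the α1 range 0.5–1.5 the monitoring problem occupies, with a warning
outside it.

`inject_artifacts` places non-overlapping events (ectopic: −40% on one
beat, +40% on the next; missed: two beats merged; extra: one beat split),
conserving total recording time exactly and returning ground-truth indices.

`generate_cohort` draws value = μ + b_i + δ_session·[POST] + ε with
b_i ~ N(0, between-subject SD) and ε ~ N(0, noise SD); the noise SD *is*
the typical error by construction, which is what makes TE-estimator
recovery a meaningful test.  Defaults mirror the study conditions for α1:
11 athletes, between-subject SD 0.24, noise SD 0.18, true change 0 (light)
and −0.28 (heavy).

What the synthetic generators do **not** emulate: respiratory sinus
arrhythmia and other physiological oscillations, intensity-dependent drift
of α1 within a bout, non-Gaussian measurement error, or correlated noise
across variables.  Passing tests therefore demonstrate the estimators'
correctness under the stated statistical model, not robustness to every
feature of field recordings.

## Numerical choices and degenerate inputs

* Sparse solve for the smoothness prior; dense-solve agreement to <1e-6 ms.
* Per-box fits use closed-form simple regression on the index 0…n−1.
* Zero-variance difference scores yield a flagged degenerate comparison
  (p undefined) rather than an exception; an all-equal baseline yields
  CV = 0.
* Exclusion is strict: excluded ⇔ percent corrected > threshold, at exactly
  the configured threshold.
* Exact-Wilcoxon two-sided p is 2·min(CDF, SF) capped at 1.
* All generators are deterministic per seed within one platform/NumPy
  version; cross-implementation bit equality is not claimed.

## Problem sizes

Test and acceptance runs use 1000-beat series (10–50 seeds per condition),
600-beat artifact fixtures, 200-participant synthetic cohorts (50 seeds)
for TE recovery and 200 seeds for CI-coverage checks.  These sizes give
Monte-Carlo error comfortably inside the asserted bands while keeping the
whole suite to a few seconds.

## Known limitations

* The artifact detector is a documented surrogate for proprietary filters;
  its percent-corrected values will differ from vendor software on real
  data even when both make the same exclusion decision.
* TE/CV/SWC from n = 11 and a single repeated baseline are themselves noisy
  (the cohort's own limitation); the package reports them as computed and
  leaves shrinkage or pooling to the user.
* MBI is reported in its historical form (chance triplets against ±SWC);
  it is not a Bayesian posterior with informative priors, and no
  multiple-testing correction is applied across variables.
* Group means of the recovery/stress composites reproduce the published
  summary rows, but the published change-score CIs for those two variables
  are narrower than the printed individual data imply; the package computes
  from the individual data.
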