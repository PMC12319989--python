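# Methods

This note documents the models behind `tdcsdose`, the defaults that matter,
what the synthetic-data generator does and does not emulate, and the design
choices made where the procedure left room.

## Study design being modeled

Three parallel arms receive 0, 4, or 6 mA of HD-tDCS over right M1 (four
electrode pairs at 0.25 / 1.0 / 1.5 mA each) while performing a 36-trial,
10-s-per-trial sequence-learning task with the left hand. Outcomes per
subject: mean NCS (correct 5-press sequences per trial, averaged over all
36 trials), the post/pre ratio of median MEP amplitudes from 60 single-pulse
TMS trials per timepoint, and windowed TEP amplitudes at five canonical
post-pulse latencies. Baseline typing speed (WPM) is both the allocation
covariate and the ANCOVA covariate.

## Group assignment (minimization)

After the first three subjects seed the arms sequentially, each newcomer is
placed in the arm minimizing the *variance across group-mean WPMs* over the
three candidate placements. We note explicitly that the superficially
similar objective "total within-group variance" must not be used: placing
each subject to minimize within-group spread clusters similar speeds into
the same arm (it is a 1-D k-means step) and therefore maximizes
between-group differences; simulation shows a ~3–4× larger group-mean gap
than pure randomization. The module keeps that quantity available as a
diagnostic (`summed_variance`) with a warning in its docstring, while
`allocation_imbalance` (variance of group means) is the allocation
objective. Ties break to the smallest group, then the lowest group index;
a seeded random tie-break is available behind a flag. Sample variance uses
ddof = 1, and empty/singleton groups contribute 0.

WPM is word-count based (63 words / elapsed minutes). A chars/5 convention
is available via `per_chars` but is not the default, since the task's word
count is exact.

## Behavioral scoring

Presses partition into fixed consecutive 5-press blocks — the task display
advances on every press regardless of correctness — so NCS counts complete
blocks matching the target and an incomplete trailing block never counts.
An alternative "restart block on error" reading is deliberately not
implemented. Accuracy is pooled over all 36 trials (correct presses / total
presses). Exclusions: pooled accuracy < 0.5; pauses > 3 s in ≥ 3 distinct
trials (the threshold count quantifies "consistent" pauses and is
configurable); any trial with zero presses. The leading wait from trial
start to the first press counts as a gap.

## MEP detection and summaries

A valid MEP is a positive peak in 20–50 ms post-trigger satisfying a
minimum prominence and maximum width, followed by a negative valley with
minimum prominence and minimum width; amplitude is peak minus valley
(peak-to-peak, the standard MEP convention). The exact numeric criteria
used in the original recordings were never published, so all thresholds are
configuration with these defaults: prominence = max(3 × robust noise SD of
the ≥ 60 ms tail, 0.05 mV); peak width ≤ 15 ms; valley width ≥ 1 ms. The
0–80 ms segment is upsampled to 10 kHz by cubic spline before peak picking
so that 500 Hz and 2 kHz recordings (both occurred in practice) give
consistent amplitudes; on noiseless synthetic epochs the recovered
amplitude is within 1% at 500 Hz and within 0.01% at 2 kHz.

Across-trial outlier rejection: with L = log(amplitude²), keep trials with
|L − median(L)| ≤ 3·IQR(L). "Three quartiles away from the median" is
ambiguous; we read it as 3 interquartile ranges on log power (squared
amplitude), with the multiplier configurable. A degenerate IQR of 0 keeps
all trials. The post/pre ratio of medians is defined only when ≥ 30 MEPs
survive at both timepoints and the pre median is nonzero; otherwise it is
flagged undefined rather than propagated as NaN.

## TEP pipeline

Epochs span −500..+500 ms at 5 kHz. Samples in −3..10 ms are replaced by a
least-squares cubic fitted to 4 ms of flanking samples on each side; a
spline through individual noisy edge samples oscillates across the 13-ms
gap, while the least-squares fit is stable and — because supporting samples
are never modified — idempotent. Interpolation (not sample deletion) keeps
a uniform time base. Per-trial, per-channel baselines (−500..−400 ms mean)
are then subtracted. Median TEPs across trials feed 10-ms windows centred
exactly on 33/45/55/100/175 ms; ROI amplitudes average C2/C4 (right M1) or
C1/C3 (left). LMFP is defined as the RMS across ROI channels of the median
TEP (the across-channel-SD and mean-absolute alternatives were considered;
RMS is the common field-power convention), GMFP the same over all channels.
Group statistics are always nonparametric — Wilcoxon signed-rank within
subjects, Kruskal–Wallis across arms, Bonferroni N = 5 over windows for the
ROI dose test; a Lilliefors-type normality pre-check is provided as advice
but never gates the test choice.

ICA-based artifact component removal is out of scope: the synthetic data
carry no blink/muscle components, and the deterministic artifact-window
interpolation covers the pulse artifact the generator does plant.

## Inference

Dose is coded ordinally (0/1/2) in "graded" models. Note that rank coding
and mA coding (0/4/6) are *not* affinely related, so they give slightly
different F statistics; the package uses ranks throughout (the coding is a
parameter), and p-values are invariant under any affine — indeed any
order-preserving relabeling of the three arms maps to the same ranks.

Staged H1 tree: stage 1 tests the graded term of
`mean_ncs ~ graded + wpm` at α = .05 → *monotonic* if significant.
Otherwise stage 2 tests the 2-df categorical dose factor (with covariate)
at α/2 → *no effect* if null. Otherwise stage 3 runs Tukey HSD between the
4 and 6 mA arms at α/2 → *reversing* if significant, else *saturating*.
The Bonferroni factor for the follow-up stages was never printed; 2 is the
default and it is configurable. Under a null cohort the tree returns
*no effect* in ≈ 0.95 × 0.975 ≈ 93% of replicates.

H2: OLS of the MEP ratio on graded dose; the slope F-test is the dose
test, and the intercept is separately t-tested against 1 on the ratio
scale (ratio 1 = no overall excitability change). H3: mixed model of
performance on MEP ratio with subject random intercept; with one
observation per subject the random-intercept variance is unidentified, so
the fit reduces to OLS and says so in its notes (the same inferential
target). The sensation model takes sensation and current as continuous
fixed effects with interaction; in the end-to-end pipeline the
subject-mean rating is modeled, because mean NCS has no within-subject
variation and a random intercept would absorb all between-subject signal.

BF01 uses the Zellner–Siow mixture-of-g prior: the added regressor is
residualized on the nuisance design, and
BF10 = ∫ (1+g)^{(n−2)/2} (1+(1−r²)g)^{−(n−1)/2} π(g) dg with
g ~ InvGamma(1/2, n·s²/2), evaluated by adaptive quadrature after
peak-shifting the log-integrand for stability. The default Cauchy scale is
s = √2/2; at s = 1 the quadrature reproduces the classic JZS correlation
Bayes factor to four significant figures (verified against an independent
implementation in the tests).

## Power analyses

* **H1 simulation.** Per replicate, (NCS, WPM) are bivariate standard
  normal with correlation 0.62; the scenario's group means in SD units are
  added to NCS; the fitted model tests the dose term at α = .05 — by
  default the 1-df graded term, not the omnibus F (the covariate would
  trivially inflate omnibus power); a categorical 2-df mode is a flag.
  Scenario means: linear (0, 0.56, 0.92), saturating (0, 0.56, 0.56),
  reversing (0, 0.56, 0), null. The reversing scenario has essentially no
  power under the graded term (~5%, it is a null for a linear trend) but
  high power under the categorical mode — the two modes bracket the
  ambiguity in how such scenario simulations can be run, and both are
  provided rather than resolved.
* **H2 analytic.** f² = η²/(1−η²), λ = f²·N, power = P(F′(1, N−2; λ) >
  F₀.₉₅(1, N−2)); at η² = 0.12, N = 120 this gives 0.98 ≥ 0.95, and the
  closed form matches a direct simulation within Monte-Carlo error.
* **H3 simulation.** Substrate s = a·dose + subject offset (the
  per-subject random offset acts on the substrate, upstream of both
  outcomes — the only placement consistent with both the closed-form
  correlation r = b²·var(s)/(b²·var(s)+1) and power = α at b = 0);
  MEP = b·s + ε₁, performance = b·s + ε₂ with unit-SD noise. b is
  calibrated by bisection on the monotone closed form to hit a target
  sample correlation, the realized mean sample r is recorded, and the
  simulated power agrees with the Fisher-z approximation
  Φ(atanh(r)·√(n−3) − z₀.₉₇₅) within Monte-Carlo error (≈ 0.90 at
  r = 0.29, N = 120).

Replicate seeds derive from the top-level seed via numpy seed sequences
(`[seed, replicate]`), making runs reproducible and parallel-safe;
sample-size sweeps derive one seed per grid point. Degenerate designs
(n = 1 per group exhausts the residual df) are flagged, not computed.

## Synthetic-data generator

What it emulates, with defaults chosen once as field-plausible conventions:

* Typing ~ N(33.5, 12²) WPM, floored at 5; latent skill correlated at 0.62.
* Learning curve: rate_t = plateau·(1 − e^{−t/τ}) + baseline sequences per
  trial with τ = 5 trials (the empirical curve saturates within ~10
  trials), plateau 4.0 ± 1.0 between subjects, baseline 1.0, per-press
  error probability 0.03, gamma inter-press intervals (CV 0.25). Absolute
  NCS levels were never published, so plateau defaults are conventions,
  not calibrations; dose effects are therefore specified in SD units.
* MEPs: biphasic difference-of-Gaussians (lobes +1.0/−0.8 scaled, σ = 2 ms,
  7 ms apart, latency 24 ms), lognormal across trials (σ = 0.5; motivated
  by the empirical non-normality of MEP amplitudes), band-limited Gaussian
  noise; pre medians lognormal across subjects around 1 mV; post/pre drift
  1.19 with lognormal subject scatter (σ = 0.15).
* TEPs: Gaussian peaks at 33/45/55/100/175 ms with alternating-sign
  amplitudes scaled by a crude motor-strip topography; a high-amplitude
  damped artifact hard-masked to −3..10 ms; per-trial baseline offsets and
  white noise. An optional dose-proportional negative shift at 45 ms
  provides a known TEP dose response.
* Sensation: ordered-logistic ratings (0–10) rising with current and
  fading across begin/mid/after; belief-of-stimulation probability rising
  with current.

Trial-sampling noise attenuates cohort-level standardized effects by a few
percent relative to the planted Cohen's d (the planted shift acts on the
plateau, while the outcome SD also contains trial noise); recovery tests
therefore compare scored effects both against the cohort's own ground
truth (tight) and against the planted parameters (within Monte-Carlo
error). What the generator does **not** emulate: blink/cardiac/muscle ICA
components, electrode impedance drift, neuronavigation variability, scalp
current flow, or task disengagement beyond the modeled error rate — so
green tests certify the pipeline's arithmetic and statistical behavior on
well-formed inputs, not robustness to every pathology of real recordings.

## Problem sizes

The shipped analysis runs use 3 × 20 subjects with 8-trial, 17-channel EEG;
power simulations use 1,000 replicates (300 for sample-size sweeps);
statistical-recovery tests use up to 3 × 150 subjects. These sizes give
Monte-Carlo standard errors of ~1–3 percentage points on the reported
rates while keeping a full run interactive.

## Known limitations

* The exact peak-detection thresholds, the stage-2/3 Bonferroni factors,
  and the study's LMFP definition are unpublished; all are configurable
  with documented defaults, and results can shift under other choices.
* The mixed models degenerate to OLS at one observation per subject; with
  genuinely repeated outcomes the `statsmodels` REML path is used instead.
* The Lilliefors pre-check reports a raw Kolmogorov–Smirnov p-value
  against the fitted normal (conservative); it is advisory only.
* The generator's absolute NCS and TEP scales are conventions; only
  relative/standardized quantities should be compared against real data.
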