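# tdcsdose

Analysis pipeline for a three-arm dose–response study of high-definition
transcranial direct current stimulation (HD-tDCS, 0 / 4 / 6 mA) over right
M1 during motor sequence learning. The package implements the study's
computational core end to end — covariate-adaptive group assignment,
behavioral and evoked-potential scoring, the preregistered staged inference
procedure, and the three preregistered power analyses — and ships a
synthetic-data generator with known ground truth so every stage is testable
without any recorded data.

It is written for researchers planning or re-analyzing non-invasive brain
stimulation experiments who want the preregistered procedures as tested,
reusable code rather than a one-off script.

## What it computes

**Allocation.** Baseline typing speed (WPM = 63 words / elapsed minutes)
feeds a minimization allocator: the first three subjects seed the three
arms, and each later subject is placed in the arm that minimizes the
variance across group-mean WPMs (deterministic tie-breaks).

**Behavior.** Performance is NCS — the number of correct sequences per
10-s trial, a correct sequence being 5 consecutive keypresses matching the
target with no errors — averaged over all 36 trials, with preregistered
attentiveness exclusions (pooled accuracy < 50%, consistent > 3 s pauses,
any empty trial).

**MEP.** Motor-evoked potentials are detected per EMG epoch as a positive
peak in the 20–50 ms post-TMS window (prominence/width criteria) followed by
a negative valley; amplitude is peak-to-peak. Trials more than three IQRs
from the median in log power are excluded; the change score is the
post/pre-tDCS ratio of median amplitudes, defined only with ≥ 30 MEPs at
both timepoints.

**TEP.** TMS-evoked EEG potentials: the −3..10 ms pulse artifact is
replaced by cubic interpolation between the window edges, the −500..−400 ms
baseline is subtracted, median TEPs are taken across trials, and amplitudes
are averaged over 10-ms windows at 33/45/55/100/175 ms in ROI channels
(C2/C4 over right M1). Comparisons are nonparametric (Wilcoxon signed-rank
pre/post; Kruskal–Wallis across arms; Bonferroni N = 5 over windows).

**Inference.** H1 follows a staged decision tree: ANCOVA of mean NCS on
graded dose (ordinal 0/1/2) with typing covariate → if null, categorical
dose at a Bonferroni-corrected level → if significant, Tukey HSD between
4 and 6 mA; the outcome is labeled *monotonic*, *reversing*, *saturating*,
or *no effect*. H2 regresses the MEP ratio on graded dose and tests the
intercept against 1. H3 is a mixed model of performance on MEP ratio with
subject random intercept (degenerating, with a flag, to OLS at one
observation per subject). Null results are quantified by
Jeffreys–Zellner–Siow Bayes factors (BF01) computed by quadrature.

**Power.** (1) H1 scenario simulation: (NCS, WPM) drawn bivariate-normal
with r = 0.62, group shifts in Cohen's-d units — linear (0, 0.56, 0.92),
saturating (0, 0.56, 0.56), reversing (0, 0.56, 0), null. (2) H2 analytic
noncentral-F power: f² = η²/(1−η²), λ = f²·N. (3) H3 common-cause
simulation: a latent substrate s = a·dose + subject offset drives both
outcomes with equal slopes b plus unit noise, giving outcome correlation
r = b²·var(s)/(b²·var(s)+1); b is calibrated by bisection to a target r and
the result cross-checked against the Fisher-z closed form.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (3 × 20 subjects, seed 2026; bulky epoch files go to `scratch/`,
tables to `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_score_behavior.py
python analysis/03_score_mep.py
python analysis/04_score_tep.py
python analysis/05_primary_inference.py
python analysis/06_power_analyses.py
python analysis/07_dosimetry.py
```

Selected output (no behavioral dose effect is planted in this cohort; a
negative 45-ms TEP dose response and a post/pre MEP drift of 1.19 are):

```
corr(typing speed, mean NCS) = 0.648 (generator: 0.62)
median post/pre ratio = 1.192 (generator drift: 1.19)
significant windows: [45.0] (generator plants a negative dose response at 45 ms)
H1 (behavior) staged outcome: NO_EFFECT
  stage 1 graded ANCOVA: F(1, 57) = 2.025, p = 0.1601
H2 (MEP ratio ~ dose): F(1, 58) = 0.011, p = 0.9176; intercept = 1.207 (t vs 1: 4.40, p = 0.0000)
H1 scenario simulation (3 x 40, r = 0.62 covariate, 1000 reps):
  linear     with covariate: 0.998   without: 0.980
H3 simulated power at r = 0.29 (N = 120): 0.902 (Fisher-z closed form: 0.898)
```

Reading this: the scored cohort reproduces the planted typing–performance
correlation and MEP drift; the TEP dose map flags exactly the planted
window; the staged H1 tree correctly stops at *no effect*; and the power
machinery reproduces the planning values (> 90% for the linear scenario
with covariate, ~90% at r = 0.29 for the association test).

A single command runs the same pipeline end to end from a TOML config:

```bash
tdcsdose run --seed 7 --out scratch/run7
```

## Layout

- `src/tdcsdose/` — the library: `synth`, `assignment`, `behavior`, `mep`,
  `tep`, `inference`, `power`, `dosimetry`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers (see worked example)
- `tests/` — pytest suite incl. brute-force oracles and the acceptance checks
- `docs/methods.md` — modeling assumptions, parameter defaults, limitations
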