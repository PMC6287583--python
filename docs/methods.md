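# Methods

`saccd` implements an analysis pipeline for the double-step saccade
paradigm with an explicit corollary-discharge (CD) gain, together with
the surrounding machinery a study of oculomotor monitoring needs:
synthetic cohorts with clinical covariates, trial screening, trial-level
compensation statistics, adaptive contrast thresholds, DAT-SPECT binding
ratios, and mixed-effects inference. This note records the model, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Task geometry

The first target T1 appears 16° from central fixation in one of the four
screen quadrants; the second target T2 is flashed on the horizontal
meridian on the same side, at one of four candidate positions spaced
2.4° apart and centred under T1. Coordinates are pixels (origin at
screen centre, +x right, +y up) converted with a flat 22 px/°
constant. That constant is treated as authoritative even though it is
not exactly derivable from the nominal 19″/70 cm viewing geometry; a
tangent-screen model would change positions by less than typical
endpoint scatter at these eccentricities. T1's polar angle within its
quadrant defaults to 45° (configurable); the candidate T2 grid is this
package's concrete choice — only the minimum spacing is a task
constraint.

All analysis happens in a canonical frame obtained by reflecting each
trial so T1 lies in the upper-right quadrant. The reflection is a pair
of sign flips: an involution that preserves distances and unsigned angle
differences.

## Generative model of a trial

With T1, T2 the target positions, per-subject CD gain λ and motor gains
g₁, g₂:

1. first-saccade endpoint E₁ = g₁·T1 + ε₁,
2. perceived displacement D̂ = λ·E₁,
3. second-saccade goal G = T2* − D̂ (retinocentric), where T2* adds
   Gaussian memory noise to the stored target in the Memory condition,
4. second endpoint E₂ = E₁ + g₂·G + ε₂.

Motor noise is isotropic Gaussian with SD proportional to intended
amplitude (signal-dependent noise; default CV 0.05). The CD gain
multiplies the *executed* first-saccade vector: this is the minimal form
in which an overestimated first saccade (λ > 1, "amplified CD") pulls
the second saccade inward, toward the initial fixation point, and λ < 1
("diminished CD") pushes it outward. With zero noise the horizontal T2
error is (1 − λ)·g₂-weighted and therefore strictly decreasing in λ,
and λ = 1 compensates exactly even when g₁ < 1 — the sign law the test
suite checks trial by trial.

Each trial emits four fixations (centre, E₁, E₂, return to centre).
With probability `invalid_rate` (default 0.06) the first saccade is
misdirected into a random other quadrant, giving the screening rule a
known population of trials to catch; at this rate the excluded fraction
matches the ballpark reported for real cohorts in this paradigm (~6%).

### Subjects and couplings

A cohort holds `n_pd` patients and `n_control` controls (defaults 14 +
14), each completing 30 Baseline and 30 Memory trials, condition order
counterbalanced across subjects. Patients' symptom laterality follows
an 8:4:2 left/right/symmetric mix scaled to the group size. Mean
striatal DAT binding (specific binding ratio, SBR) is drawn per
hemisphere: ≈2.0 ± 0.15 for controls, ≈1.1 ± 0.25 in the more affected
hemisphere of patients (contralateral to the symptomatic body side)
with the other hemisphere ≈0.35 higher.

Two couplings tie behaviour to the covariates, both linear in the
depletion (dat_reference − low-hemisphere SBR, reference 2.0):

- `dat_coupling_cd` (default 0.20 per SBR unit) raises λ — patients
  average λ ≈ 1.18, the amplified-CD regime;
- `dat_coupling_gain` (default 0.08) lowers both motor gains —
  hypometria that deepens with dopaminergic loss.

Trials toward the symptomatic side additionally shift λ by
`laterality_delta_cd` (+0.08) and g₁ by `laterality_delta_gain`
(−0.03). Motor gains are (Baseline, Memory) pairs — (0.94, 0.90) for
the first saccade, (1.00, 0.97) for the second — so memory-guided
movements are mildly more hypometric. Between-subject scatter of λ and
the gains is `subject_sd` (0.05). These magnitudes were chosen once as
realistic for an early-stage patient cohort; with them the fitted
ideal-angle × DAT interaction lands near 0.17 degrees of saccade angle
per degree of ideal angle per SBR unit, the size of effect reported for
this paradigm.

### What the generator does not emulate

No raw gaze samples, velocity profiles, corrective multi-step saccades,
blinks, drift, anticipatory errors, or learning across trials; fixation
timing is schematic. Passing tests therefore demonstrate that the
*estimators* are calibrated for data of this structure, not that real
eye-tracking data meet the model's assumptions.

## Preprocessing

A trial is kept iff the first saccade (first inter-fixation movement ≥
2°) deviates from the direction to T1 by at most 45°, and some later
movement is directed toward T2 under the same tolerance; exclusion
reasons are recorded. The tolerance and amplitude floor are this
package's operationalisation — the screening rule is usually stated
qualitatively — and both are configurable. The fixations closest to T1
and (after it) to T2 are matched to the targets; errors are
fixation − target in the canonical frame, making T1 undershoot negative
and T2 undershoot (stopping above the meridian) positive in the
vertical component. On labelled synthetic cohorts the rule recovers
≥ 95% of generator-flagged invalid trials and loses nothing from
noiseless data.

## Compensation statistics

Given the realised first endpoint f₁, the ideal second saccade is
T2 − f₁ and the actual one f₂ − f₁, each summarised as amplitude and
absolute direction (atan2, degrees CCW from +x). The angle reference
for the ideal/actual comparison is not fixed by convention in this
paradigm; absolute direction in the canonical frame is used here, under
which angle error (actual − ideal) is negative exactly when the saccade
is rotated toward the initial fixation point ("inward"). Predictors are
mean-centred before modelling — grand-mean by default, per-subject
optionally (the two differ whenever subjects sample different layouts).

Laterality coding: relative to the symptomatic body side, targets on the
same screen side are *ipsi*; relative to the lower-binding hemisphere,
targets in the hemifield that hemisphere processes (the opposite one —
the crossed retinotopic mapping, applied exactly once) are *contra*.
Symmetric subjects code as *none* and drop out of laterality models.

A per-subject CD-gain estimator is included for recovery tests: since
f₂ − f₁ = g₂·T2 − g₂λ·f₁ + noise, stacking both components of all trials
and solving the two-regressor least-squares problem gives λ̂ = −b₂/b₁.

## QUEST thresholds

The staircase holds a discretised posterior over the log₁₀ Michelson
contrast threshold of a Weibull psychometric function (slope 3.5, guess
0.5, lapse 0.01 — standard 2AFC settings; the grid spans the Gaussian
prior's mean ± 4 SD at grain 0.01). Each trial is placed at the
posterior mean and the final estimate is the posterior mean (the "mean"
QUEST variant); sessions default to 64 trials. The likelihood is
anchored so P(correct) = 0.81 exactly at threshold. Probing a matched
observer at the returned estimate yields ≈ 81% correct — the package's
self-contained fidelity check (`scripts/acceptance.py`).

Threshold sessions for fixation / during-saccade / after-saccade blocks
are compared with a mixed model (per-subject intercepts); the simulation
defaults elevate thresholds by 1.96 and 0.78 log units in the saccade
and after-saccade conditions, the magnitude of saccadic suppression this
paradigm reports, identically for both groups.

## Imaging

SBR = (ROI − OCC)/OCC per region (caudate, anterior and posterior
putamen) against the occipital reference; hemisphere summaries are
arithmetic means of the three regional SBRs, the lower one defines the
more affected hemisphere (ties broken to left, with a warning), and the
covariate entering the models is cohort-centred. A scan-to-test delay
column can be carried as an optional covariate; off by default.

## Inference

All models are linear mixed models fitted by REML on single-trial data:
error models use random intercepts plus random Baseline/Memory *and*
T1/T2 slopes per subject; compensation and threshold models use random
intercepts. The target slope is a deliberate enrichment over the
leaner intercept+condition structure this paradigm's analyses usually
report: when the CD gain and motor gains vary across subjects, each
subject carries their own T1-vs-T2 error contrast, and omitting the
target slope treats that contrast as independent noise — on simulated
null cohorts it inflates the false-positive rate of the group main
effect to ~15% and of the group × target interaction to ~57%, versus
~5–9% with the slope included. Users who want the leaner structure for
comparability can pass ``re_formula="~is_memory"``.
Wald t statistics and normal-approximation 95% CIs are reported; no
p-values, and a term is called significant iff its CI excludes zero.
Pruning removes, one refit at a time, the removable term (one not
contained in any retained interaction) with the smallest |t| < 2, and
records the full trace; the one-at-a-time order is this package's
resolution of the usual one-line description of the rule. Singular or
non-converged fits are flagged in the result metadata, never silently
simplified. Group-mean error bars use the percentile cluster bootstrap
(subjects resampled, 1,000 draws). Questionnaire items (0–3 ordinal)
are compared with a two-sided Mann–Whitney test using the tie-corrected
normal approximation, computed in-package so that fully tied items
degenerate cleanly to Z = 0, p = 1.

Calibration, measured by the acceptance suite at cohort scale (28
subjects × 60 trials, 100 replicates): pooled 95% CI coverage of
injected fixed effects falls in the 90–98% band; on null cohorts each
group term is flagged in ≲10% of runs; and the injected DAT→λ coupling
is recovered with the correct sign in ≥95% of cohorts and with mean
magnitude within 2 SEM of its asymptotic value (computed by pooled OLS
on six independent cohorts, since the coupling acts on λ and its induced
regression coefficient has no closed form).

## Pipeline

`run_pipeline` chains simulate → preprocess → compensate → imaging →
analyze → psychophys → report from a schema-validated YAML config
(unknown keys rejected), writes every table as CSV plus model JSON, a
Markdown report in the Estimate / 95% CI / t-value layout, and a SHA-256
manifest; identical config and seed give bit-identical artifacts. The
global seed is expanded into independent per-stage streams so toggling
one stage leaves the others' randomness untouched. Named fixture
bundles (`veridical`, `amplified_cd`, `diminished_cd`, `null_cohort`,
≤200 trials each) embody the regimes the tests rely on.

## Problem sizes and numerical choices

Default simulations run at study scale (28 subjects, 60 trials each);
calibration checks use 100 replicate cohorts, a size chosen to keep
binomial noise on coverage/sign rates near ±2–4 points. Geometry is
exact to float precision (oracle tolerance 1e-9 relative); angle
differences are wrapped to (−180°, 180°]; degenerate zero-length
saccade vectors are flagged rather than given an angle; mixed-model
optimisation uses statsmodels' default optimizer sequence, which
converged on all model families where a single fixed choice did not.

## Known limitations

The CD gain is applied to the executed (not planned) first saccade —
the two are indistinguishable in endpoint data unless noise sources are
separated experimentally. Wald CIs slightly undercover with 28
clusters (the measured ~92–95% pooled coverage reflects this). The
generator's couplings are linear and its covariate distributions
stylised; they define recoverable ground truth, not population
epidemiology. The laterality and DAT analyses of real datasets would
additionally need medication state and disease-duration covariates that
the generator does not model.
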