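# saccd

Analysis pipeline for the **double-step saccade task** with an explicit
corollary-discharge (CD) gain, aimed at oculomotor and movement-disorders
researchers who want to model internal monitoring of eye movements — e.g.
in Parkinson's disease cohorts — and to validate their statistics on
synthetic data with known ground truth.

In the double-step task two targets are flashed in sequence; because the
first saccade displaces the eye, the second saccade is only accurate if
the brain accounts for the movement it just made. `saccd` models that
accounting with a single gain λ on the executed first saccade:

```
E1 = g1·T1 + ε1                  first-saccade endpoint
D̂  = λ·E1                        displacement signalled by the CD
E2 = E1 + g2·(T2* − D̂) + ε2      second-saccade endpoint
```

λ = 1 is veridical; λ > 1 (*amplified* CD — the brain believes it moved
farther than it did) biases the second saccade **inward**, toward the
initial fixation; λ < 1 (*diminished* CD) biases it outward. The
package provides:

- `saccd.cohort` — generative model of two-saccade trials plus subject
  covariates (group, symptom laterality, motor MDS-UPDRS, per-hemisphere
  striatal DAT binding) with configurable couplings to λ and the motor
  gains, and a simulated Weibull 2AFC observer;
- `saccd.geometry` — screen/task geometry and the canonical upper-right
  transposition;
- `saccd.preprocess` — trial screening ("first saccade directed toward
  the first target…"), closest-fixation matching, signed errors;
- `saccd.compensation` — ideal vs. actual second-saccade angle and
  amplitude, centred predictors, ipsi/contra laterality coding, and a
  per-subject λ estimator;
- `saccd.psychophysics` — QUEST adaptive staircase for the 81% contrast
  threshold and the saccadic-suppression mixed model;
- `saccd.imaging` — DAT-SPECT specific binding ratios
  SBR = (ROI − OCC)/OCC and hemisphere summaries;
- `saccd.inference` — trial-level mixed models (REML), |t| < 2 pruning
  with marginality, cluster-bootstrap CIs, Mann–Whitney questionnaire
  tests;
- `saccd.pipeline` / the `saccd` CLI — config-driven, seeded, end-to-end
  runs with a SHA-256 manifest and a Markdown model report.

## Worked example

```python
import numpy as np
from saccd.cohort import GenParams, simulate_cohort
from saccd.preprocess import preprocess_table
from saccd.compensation import add_compensation, center_predictors
from saccd.inference import fit_mixed

fix, subjects, truth = simulate_cohort(GenParams(seed=1))   # 14 PD + 14 controls
obs = preprocess_table(fix)
print(f"kept {obs.valid.mean():.1%} of {len(obs)} trials")

rec = center_predictors(add_compensation(obs))
rec = rec.merge(subjects[["subject_id", "dat_left", "dat_right"]], on="subject_id")
low = rec[["dat_left", "dat_right"]].min(axis=1)
rec["dat_c"] = low - low.mean()
res = fit_mixed(rec, "actual_angle",
                ["ideal_angle_c", "dat_c", "ideal_angle_c:dat_c"], re_formula="1")
print(res.terms.round(3)[["estimate", "ci_low", "ci_high", "tvalue"]])
```

prints

```
kept 94.0% of 1680 trials
                     estimate  ci_low  ci_high   tvalue
Intercept             -88.531 -89.221  -87.842 -251.655
ideal_angle_c           0.916   0.901    0.931  118.290
dat_c                  12.431  10.817   14.044   15.095
ideal_angle_c:dat_c     0.168   0.132    0.204    9.133
```

Read: ~6% of trials fail the direction screen (the generator misdirects
6% on purpose). The mean second-saccade direction is −88.5° (straight
down to the meridian target in the canonical frame). The slope of the
actual on the ideal second-saccade angle is 0.92 — saccades compensate
most, not all, of the first saccade's endpoint variability — and the
positive `ideal_angle_c:dat_c` interaction (+0.17 per SBR unit, t ≈ 9)
says compensation degrades as striatal DAT binding falls, exactly the
coupling the generator injected (λ rises as binding drops).

A full run — trial tables, compensation records, DAT summaries, model
JSON and a Markdown report — is one command:

```bash
saccd run --seed 1 --outdir out/
```

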