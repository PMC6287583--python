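"""Generative model of double-saccade behaviour under a corollary-discharge
(CD) gain hypothesis, plus subject-level covariates.

Each trial unfolds in four steps:

1. first-saccade endpoint  ``E1 = g1 * T1 + noise``,
2. perceived displacement  ``Dhat = lambda * E1``  (the CD carries a scaled
   copy of the executed movement; ``lambda = 1`` is veridical, ``> 1``
   amplified, ``< 1`` diminished),
3. second-saccade motor goal ``G = T2* - Dhat`` in eye-displacement terms,
   where ``T2*`` is the stored second-target position (memory noise is
   added in the Memory condition),
4. second endpoint ``E2 = E1 + g2 * G + noise``.

Motor noise is isotropic Gaussian with standard deviation proportional to
the intended movement amplitude (signal-dependent noise).  An amplified
CD (``lambda > 1``) therefore biases the second saccade inward, toward
the initial fixation point, and a diminished CD biases it outward —
exactly the two signatures the double-step task discriminates.

Subjects carry clinical covariates (group, symptom laterality, motor
MDS-UPDRS, per-hemisphere mean striatal DAT binding).  The CD gain and
motor gains can be coupled to the lower-hemisphere DAT binding and to the
side of the screen relative to the symptomatic body side, so that cohort
level analyses have a known ground truth to recover.

The module also provides the simulated 2AFC observer used to exercise the
QUEST staircase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    QUADRANTS,
    ScreenConfig,
    TrialLayout,
    deg_to_px,
    make_layout,
)
from .psychophysics import weibull_p_correct

__all__ = [
    "GenParams",
    "simulate_trial",
    "simulate_cohort",
    "simulate_observer",
    "roi_uptake_table",
    "FIXATION_COLUMNS",
]

#: Column order of the fixation-level trial table written to CSV.
FIXATION_COLUMNS = [
    "subject_id",
    "trial_id",
    "condition",
    "quadrant",
    "t2_index",
    "fix_index",
    "x",
    "y",
    "onset_ms",
    "offset_ms",
]

CONDITIONS = ("Baseline", "Memory")

#: Striatal regions averaged into the per-hemisphere DAT summary.
STRIATAL_REGIONS = ("caudate", "anterior_putamen", "posterior_putamen")


@dataclass(frozen=True)
class GenParams:
    """Population-level parameters of the generative model.

    Gains are (Baseline, Memory) pairs: memory-guided saccades are
    slightly more hypometric than visually-guided ones.  ``dat_coupling_*``
    are slopes per unit of mean striatal specific binding ratio (SBR)
    *below* ``dat_reference``: subjects with lower binding get a larger CD
    gain (amplified CD) and a smaller motor gain (hypometria).
    ``laterality_delta_*`` shift the effective parameters on trials whose
    targets appear on the same screen side as the predominant motor
    symptoms (asymmetric patients only).
    """

    cd_gain: float = 1.0
    motor_gain_1: tuple[float, float] = (0.94, 0.90)
    motor_gain_2: tuple[float, float] = (1.00, 0.97)
    motor_noise_cv: float = 0.05
    memory_noise_deg: float = 1.0
    invalid_rate: float = 0.06
    subject_sd: float = 0.05
    dat_coupling_cd: float = 0.20
    dat_coupling_gain: float = 0.08
    dat_reference: float = 2.0
    laterality_delta_cd: float = 0.08
    laterality_delta_gain: float = -0.03
    t1_polar_angle_deg: float = 45.0
    trials_per_condition: int = 30
    seed: int = 12345

    def __post_init__(self) -> None:
        for name in ("motor_gain_1", "motor_gain_2"):
            pair = getattr(self, name)
            if len(pair) != 2 or any(g <= 0 for g in pair):
                raise ValueError(f"{name} must be a positive (Baseline, Memory) pair")
        if self.cd_gain <= 0:
            raise ValueError("cd_gain must be > 0")
        for name in ("motor_noise_cv", "memory_noise_deg", "subject_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.invalid_rate < 1.0:
            raise ValueError("invalid_rate must be in [0, 1)")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")


def simulate_observer(
    true_log_threshold: float,
    slope: float = 3.5,
    guess: float = 0.5,
    lapse: float = 0.01,
    target_p: float = 0.81,
):
    """Stochastic 2AFC observer with a Weibull psychometric function.

    Returns ``observer(intensity, rng) -> bool`` whose probability of a
    correct response equals ``target_p`` exactly at the true threshold,
    tends to ``guess`` far below it and to ``1 - lapse`` far above it.
    """
    if not 0.0 <= lapse < 0.1:
        raise ValueError("lapse must be in [0, 0.1)")

    def observer(intensity: float, rng: np.random.Generator) -> bool:
        p = weibull_p_correct(intensity, true_log_threshold, slope, guess, lapse, target_p)
        return bool(rng.random() < float(p))

    observer.true_log_threshold = true_log_threshold
    observer.p_correct = lambda intensity: weibull_p_correct(
        intensity, true_log_threshold, slope, guess, lapse, target_p
    )
    return observer


def _symptom_sides(n_pd: int) -> list[str]:
    """Symptom-laterality mix: predominantly left, some right, few symmetric.

    Proportions follow the 8:4:2 left/right/symmetric split of the
    cohort this task family describes, rounded to the requested size.
    """
    n_left = int(round(n_pd * 8 / 14))
    n_right = int(round(n_pd * 4 / 14))
    n_left = min(n_left, n_pd)
    n_right = min(n_right, n_pd - n_left)
    sides = ["left"] * n_left + ["right"] * n_right
    sides += ["symmetric"] * (n_pd - len(sides))
    return sides


def _draw_subjects(
    gen: GenParams, n_pd: int, n_control: int, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    sides = _symptom_sides(n_pd)
    for group, n in (("control", n_control), ("PD", n_pd)):
        for i in range(n):
            sid = f"{'pd' if group == 'PD' else 'ctl'}{i + 1:02d}"
            if group == "control":
                symptom_side = "none"
                dat_left = max(0.2, rng.normal(2.0, 0.15))
                dat_right = max(0.2, rng.normal(2.0, 0.15))
                updrs = float(np.clip(rng.normal(2.0, 2.0), 0.0, 10.0))
            else:
                symptom_side = sides[i]
                updrs = float(np.clip(rng.normal(37.0, 20.0), 11.0, 95.0))
                if symptom_side == "symmetric":
                    m = max(0.3, rng.normal(1.2, 0.25))
                    d = rng.normal(0.0, 0.05)
                    dat_left, dat_right = max(0.2, m - d / 2), max(0.2, m + d / 2)
                else:
                    low = max(0.3, rng.normal(1.1, 0.25))
                    high = low + abs(rng.normal(0.35, 0.10))
                    # dominant symptoms are contralateral to the depleted hemisphere
                    if symptom_side == "left":
                        dat_right, dat_left = low, high
                    else:
                        dat_left, dat_right = low, high
            dat_low = min(dat_left, dat_right)
            depletion = gen.dat_reference - dat_low
            lam = gen.cd_gain + gen.dat_coupling_cd * depletion + rng.normal(0, gen.subject_sd)
            g1_off = -gen.dat_coupling_gain * depletion + rng.normal(0, gen.subject_sd)
            g2_off = -gen.dat_coupling_gain * depletion + rng.normal(0, gen.subject_sd)
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "symptom_side": symptom_side,
                    "motor_updrs": updrs,
                    "dat_left": float(dat_left),
                    "dat_right": float(dat_right),
                    "cd_gain": float(max(0.05, lam)),
                    "motor_gain_1_baseline": float(max(0.1, gen.motor_gain_1[0] + g1_off)),
                    "motor_gain_1_memory": float(max(0.1, gen.motor_gain_1[1] + g1_off)),
                    "motor_gain_2_baseline": float(max(0.1, gen.motor_gain_2[0] + g2_off)),
                    "motor_gain_2_memory": float(max(0.1, gen.motor_gain_2[1] + g2_off)),
                }
            )
    return pd.DataFrame(rows)


def _noisy(vec: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Add isotropic Gaussian noise with SD = cv * |vec| to a movement vector."""
    if cv == 0:
        return vec
    sd = cv * float(np.hypot(*vec))
    return vec + rng.normal(0.0, sd, size=2)


def simulate_trial(
    subject: pd.Series,
    gen: GenParams,
    layout: TrialLayout,
    condition: str,
    rng: np.random.Generator,
    screen: ScreenConfig,
    trial_id: int = 1,
) -> tuple[list[dict], dict]:
    """Simulate one trial; returns (fixation rows, ground-truth record).

    Fixations are emitted at the central start point, the first-saccade
    endpoint, the second-saccade endpoint, and a return-to-centre
    fixation.  With probability ``invalid_rate`` the first saccade is
    misdirected into a random other quadrant (the behaviour the
    preprocessing exclusion rule must catch); the truth record labels it.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    mem = condition == "Memory"
    cond_key = "memory" if mem else "baseline"
    lam = float(subject["cd_gain"])
    g1 = float(subject[f"motor_gain_1_{cond_key}"])
    g2 = float(subject[f"motor_gain_2_{cond_key}"])
    toward_symptoms = (
        subject["group"] == "PD"
        and subject["symptom_side"] in ("left", "right")
        and layout.side == subject["symptom_side"]
    )
    if toward_symptoms:
        lam += gen.laterality_delta_cd
        g1 += gen.laterality_delta_gain

    t1 = np.asarray(layout.t1_pos, dtype=float)
    t2 = np.asarray(layout.t2_pos, dtype=float)
    invalid = bool(rng.random() < gen.invalid_rate)
    if invalid:
        wrong = rng.choice([q for q in QUADRANTS if q != layout.quadrant])
        aim1 = np.abs(t1) * np.array(
            [math.copysign(1.0, v) for v in _quadrant_unit(wrong)]
        )
    else:
        aim1 = t1.copy()
    mem_sd = deg_to_px(gen.memory_noise_deg, screen) if mem else 0.0
    if mem_sd > 0:
        aim1 = aim1 + rng.normal(0.0, mem_sd, size=2)
        t2_star = t2 + rng.normal(0.0, mem_sd, size=2)
    else:
        t2_star = t2.copy()

    e1 = _noisy(g1 * aim1, gen.motor_noise_cv, rng)
    d_hat = lam * e1
    goal = t2_star - d_hat
    e2 = e1 + _noisy(g2 * goal, gen.motor_noise_cv, rng)

    fix_dur = layout.fixation_duration_ms
    latency = 200.0
    dwell = 300.0
    points = [np.zeros(2), e1, e2, np.zeros(2)]
    onsets = [0.0, fix_dur + latency, fix_dur + latency + dwell + 50.0,
              fix_dur + latency + 2 * (dwell + 50.0)]
    rows = []
    for k, (pt, onset) in enumerate(zip(points, onsets)):
        rows.append(
            {
                "subject_id": subject["subject_id"],
                "trial_id": trial_id,
                "condition": condition,
                "quadrant": layout.quadrant,
                "t2_index": layout.t2_index,
                "fix_index": k,
                "x": float(pt[0]),
                "y": float(pt[1]),
                "onset_ms": onset,
                "offset_ms": onset + (fix_dur if k == 0 else dwell),
            }
        )
    truth = {
        "subject_id": subject["subject_id"],
        "trial_id": trial_id,
        "condition": condition,
        "quadrant": layout.quadrant,
        "t2_index": layout.t2_index,
        "side": layout.side,
        "invalid": invalid,
        "cd_gain_eff": lam,
        "motor_gain_1_eff": g1,
        "motor_gain_2_eff": g2,
        "e1x": float(e1[0]),
        "e1y": float(e1[1]),
        "e2x": float(e2[0]),
        "e2y": float(e2[1]),
    }
    return rows, truth


def _quadrant_unit(quadrant: str) -> tuple[float, float]:
    from .geometry import quadrant_signs

    return quadrant_signs(quadrant)


def simulate_cohort(
    gen: GenParams | None = None,
    n_pd: int = 14,
    n_control: int = 14,
    trials_per_condition: int | None = None,
    screen: ScreenConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (fixations, subjects, trial truth).

    Every subject completes ``trials_per_condition`` trials (default 30)
    in each of the Baseline and Memory conditions, condition order
    counterbalanced across subjects.  Reproducible given ``gen.seed`` (or
    an explicit ``rng``).
    """
    gen = GenParams() if gen is None else gen
    screen = ScreenConfig() if screen is None else screen
    if n_pd < 0 or n_control < 0 or n_pd + n_control < 1:
        raise ValueError("cohort must contain at least one subject")
    tpc = gen.trials_per_condition if trials_per_condition is None else trials_per_condition
    rng = np.random.default_rng(gen.seed) if rng is None else rng
    subjects = _draw_subjects(gen, n_pd, n_control, rng)
    fix_rows: list[dict] = []
    truth_rows: list[dict] = []
    for si, (_, subj) in enumerate(subjects.iterrows()):
        order = CONDITIONS if si % 2 == 0 else CONDITIONS[::-1]
        trial_id = 0
        for condition in order:
            for _ in range(tpc):
                trial_id += 1
                quadrant = str(rng.choice(QUADRANTS))
                t2_index = int(rng.integers(1, 5))
                layout = make_layout(
                    screen, quadrant, t2_index, polar_angle=gen.t1_polar_angle_deg
                )
                rows, truth = simulate_trial(
                    subj, gen, layout, condition, rng, screen, trial_id
                )
                fix_rows.extend(rows)
                truth_rows.append(truth)
    fixations = pd.DataFrame(fix_rows, columns=FIXATION_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return fixations, subjects, truth


def roi_uptake_table(
    subjects: pd.DataFrame,
    rng: np.random.Generator | None = None,
    region_sd: float = 0.08,
) -> pd.DataFrame:
    """Region-level SPECT uptakes consistent with the subjects' DAT summaries.

    Emits raw uptakes (occipital reference plus six striatal regions)
    whose specific binding ratios average back to the per-hemisphere mean
    striatal values stored in *subjects*; used to exercise the imaging
    module end-to-end.  Regional scatter around the hemisphere mean is
    re-centred so the mean is matched exactly.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    rows = []
    for _, subj in subjects.iterrows():
        occ = max(0.5, rng.normal(1.0, 0.05))
        row = {"subject_id": subj["subject_id"], "occipital": float(occ)}
        for hemi in ("left", "right"):
            mean_sbr = float(subj[f"dat_{hemi}"])
            dev = rng.normal(0.0, region_sd, size=len(STRIATAL_REGIONS))
            dev -= dev.mean()
            for region, d in zip(STRIATAL_REGIONS, dev):
                sbr_region = max(0.01, mean_sbr + d)
                row[f"{hemi}_{region}"] = float(occ * (1.0 + sbr_region))
        rows.append(row)
    return pd.DataFrame(rows)
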