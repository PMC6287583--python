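"""QUEST adaptive staircase and saccadic-suppression threshold analysis.

The detection task is a 2AFC localisation of a briefly flashed Gabor; the
staircase adaptively varies the stimulus intensity (log10 Michelson
contrast) to find the 81% correct threshold.  The staircase keeps a
discretised Bayesian posterior over the log-contrast threshold of a
Weibull psychometric function, places each trial at the posterior mean,
and reports the posterior mean as the final estimate (the "mean" QUEST
variant).

The Weibull likelihood is anchored so that the probability of a correct
response equals ``target_p`` exactly when the intensity equals the
threshold parameter, whatever the guess and lapse rates.

Thresholds measured under fixation, during saccades, and right after
saccades are compared with a linear mixed model (per-subject intercepts),
with non-contributing terms pruned at |t| < 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference

__all__ = [
    "CONDITIONS",
    "weibull_p_correct",
    "QuestState",
    "ThresholdResult",
    "quest_init",
    "quest_update",
    "quest_next",
    "quest_estimate",
    "run_threshold_session",
    "simulate_suppression_study",
    "suppression_model",
]

#: Threshold-measurement conditions, in block order.
CONDITIONS = ("fixation", "saccade", "after_saccade")


def weibull_p_correct(
    intensity,
    threshold,
    slope: float = 3.5,
    guess: float = 0.5,
    lapse: float = 0.01,
    target_p: float = 0.81,
):
    """Probability of a correct response under a Weibull psychometric function.

    ``P(correct | x) = guess + (1 - guess - lapse) * (1 - exp(-10**(slope*(x - threshold + eps))))``

    with ``eps`` chosen so that ``P(correct | threshold) == target_p``.
    ``intensity`` and ``threshold`` are log10 contrast and broadcast
    against each other.
    """
    if not guess <= target_p <= 1.0 - lapse:
        raise ValueError("target_p must lie between the guess floor and the lapse ceiling")
    span = 1.0 - guess - lapse
    frac = (target_p - guess) / span
    eps = np.log10(-np.log1p(-frac)) / slope
    x = np.asarray(intensity, dtype=float)
    u = 10.0 ** (slope * (x - np.asarray(threshold, dtype=float) + eps))
    return guess + span * (-np.expm1(-u))


@dataclass
class QuestState:
    """Discretised posterior over the log10-contrast threshold."""

    grid: np.ndarray
    posterior: np.ndarray
    slope: float = 3.5
    guess: float = 0.5
    lapse: float = 0.01
    target_p: float = 0.81
    history: list = field(default_factory=list)


@dataclass(frozen=True)
class ThresholdResult:
    """Per-condition threshold estimate for one subject."""

    condition: str
    log10_threshold: float
    n_trials: int
    subject_id: str = ""


def quest_init(
    prior_mean: float,
    prior_sd: float,
    slope: float = 3.5,
    guess: float = 0.5,
    lapse: float = 0.01,
    target_p: float = 0.81,
    grain: float = 0.01,
    span_sd: float = 4.0,
) -> QuestState:
    """Gaussian prior over the threshold on a grid of ``prior_mean +/- span_sd*prior_sd``."""
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    if grain <= 0 or grain >= 2 * span_sd * prior_sd:
        raise ValueError("degenerate posterior grid")
    n = int(round(2 * span_sd * prior_sd / grain)) + 1
    grid = prior_mean + (np.arange(n) - (n - 1) / 2.0) * grain
    post = np.exp(-0.5 * ((grid - prior_mean) / prior_sd) ** 2)
    post /= post.sum()
    return QuestState(
        grid=grid, posterior=post, slope=slope, guess=guess, lapse=lapse, target_p=target_p
    )


def quest_update(state: QuestState, intensity: float, response: bool) -> QuestState:
    """Bayes-update the posterior with one (intensity, response) observation."""
    if not np.isfinite(intensity):
        raise ValueError("intensity must be finite")
    p = weibull_p_correct(
        intensity, state.grid, state.slope, state.guess, state.lapse, state.target_p
    )
    like = p if response else 1.0 - p
    post = state.posterior * like
    total = post.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError("posterior mass vanished during update")
    state.posterior = post / total
    state.history.append((float(intensity), bool(response)))
    return state


def quest_next(state: QuestState) -> float:
    """Intensity for the next trial: the current posterior mean."""
    return float(np.dot(state.grid, state.posterior))


def quest_estimate(state: QuestState) -> float:
    """Final threshold estimate: the posterior mean."""
    return quest_next(state)


def run_threshold_session(
    condition: str,
    observer,
    n_trials: int = 64,
    rng: np.random.Generator | None = None,
    prior_mean: float = -1.0,
    prior_sd: float = 0.5,
    subject_id: str = "",
    **quest_kwargs,
) -> ThresholdResult:
    """Run a full staircase against *observer* and return the estimate.

    ``observer(intensity, rng) -> bool`` supplies the per-trial response;
    :func:`saccd.cohort.simulate_observer` builds a Weibull observer with
    this signature.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng() if rng is None else rng
    state = quest_init(prior_mean, prior_sd, **quest_kwargs)
    for _ in range(n_trials):
        x = quest_next(state)
        quest_update(state, x, observer(x, rng))
    return ThresholdResult(
        condition=condition,
        log10_threshold=quest_estimate(state),
        n_trials=n_trials,
        subject_id=subject_id,
    )


def simulate_suppression_study(
    n_pd: int = 14,
    n_control: int = 14,
    fixation_mean: float = -2.2,
    subject_sd: float = 0.2,
    saccade_elevation: float = 1.96,
    after_elevation: float = 0.78,
    pd_delta: tuple[float, float, float] = (0.0, 0.0, 0.0),
    n_trials: int = 64,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the three-condition threshold study through the staircase.

    Each subject has a latent fixation threshold (log10 contrast) with
    between-subject scatter; the saccade and after-saccade conditions
    elevate it by the configured amounts (defaults match the magnitude of
    saccadic suppression this task family reports: about two log units
    during the saccade, under one right after).  ``pd_delta`` adds a
    per-condition offset for the patient group (zero by default: patients
    and controls show equivalent suppression).
    """
    from .cohort import simulate_observer  # local import to avoid a cycle

    rng = np.random.default_rng() if rng is None else rng
    elevations = dict(
        zip(CONDITIONS, (0.0, saccade_elevation, after_elevation), strict=True)
    )
    deltas = dict(zip(CONDITIONS, pd_delta, strict=True))
    rows = []
    for group, n in (("control", n_control), ("PD", n_pd)):
        for i in range(n):
            sid = f"{'pd' if group == 'PD' else 'ctl'}{i + 1:02d}"
            base = rng.normal(fixation_mean, subject_sd)
            for cond in CONDITIONS:
                true_thr = base + elevations[cond] + (deltas[cond] if group == "PD" else 0.0)
                obs = simulate_observer(true_thr)
                res = run_threshold_session(
                    cond,
                    obs,
                    n_trials=n_trials,
                    rng=rng,
                    prior_mean=fixation_mean + 1.0,
                    prior_sd=1.0,
                    subject_id=sid,
                )
                rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "condition": cond,
                        "log10_threshold": res.log10_threshold,
                        "n_trials": n_trials,
                    }
                )
    return pd.DataFrame(rows)


def suppression_model(results: pd.DataFrame, prune: bool = True) -> inference.ModelResult:
    """Mixed model of log-threshold on condition (and group, pruned if inert).

    Fits ``log10_threshold ~ saccade + after + group + group:condition``
    with a per-subject random intercept, then drops terms with |t| < 2
    (highest-order, least-contributing first).  With healthy suppression
    the condition effects survive pruning and the group terms do not.
    """
    data = results.copy()
    data["is_saccade"] = (data["condition"] == "saccade").astype(float)
    data["is_after"] = (data["condition"] == "after_saccade").astype(float)
    data["is_pd"] = (data["group"] == "PD").astype(float)
    terms = ["is_saccade", "is_after", "is_pd", "is_pd:is_saccade", "is_pd:is_after"]
    if prune:
        return inference.prune(data, "log10_threshold", terms, re_formula="1")
    return inference.fit_mixed(data, "log10_threshold", terms, re_formula="1")
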