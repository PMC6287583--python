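"""Trial-by-trial compensation statistics for the second saccade.

Given the realised endpoint of the first saccade, the *ideal* second
saccade is the vector from that endpoint to the second target; the
*actual* second saccade is the vector to the matched second fixation.
Both are summarised as amplitude (px) and absolute direction (degrees,
counterclockwise from +x, ``atan2`` convention) in the canonical
upper-right frame.  In that frame the second target lies below the first
saccade's endpoint and the initial fixation point is down-and-left of
it, so a *negative* angle error (actual minus ideal) means the saccade
was rotated toward the initial fixation point - an "inward" error, the
signature of an amplified corollary discharge - while a positive error
is outward (diminished CD).

Predictors are mean-centred (grand mean by default, per-subject
optionally) before entering the mixed models, and each trial is coded
ipsi/contralateral either to the symptomatic body side or to the
cerebral hemisphere with lower DAT binding (visual hemifields project to
the contralateral hemisphere, so that mapping is crossed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "polar",
    "ideal_second_saccade",
    "actual_second_saccade",
    "add_compensation",
    "center_predictors",
    "laterality_code",
    "add_laterality",
    "estimate_cd_gain",
]


def polar(vec) -> tuple[float, float]:
    """(amplitude, angle) of a 2-vector; angle in degrees in (-180, 180]."""
    v = np.asarray(vec, dtype=float)
    amp = float(np.hypot(v[0], v[1]))
    angle = float(np.degrees(np.arctan2(v[1], v[0])))
    return amp, angle


def ideal_second_saccade(f1, t2) -> tuple[float, float]:
    """Amplitude and angle of the saccade that would land exactly on T2.

    ``f1`` is the canonical first-saccade endpoint, ``t2`` the canonical
    second-target position.  A zero-length ideal vector (``f1 == t2``)
    returns amplitude 0 with NaN angle; downstream code must treat such
    records as degenerate.
    """
    v = np.asarray(t2, dtype=float) - np.asarray(f1, dtype=float)
    if np.allclose(v, 0.0):
        return 0.0, float("nan")
    return polar(v)


def actual_second_saccade(f1, f2) -> tuple[float, float]:
    """Amplitude and angle of the executed second saccade (f2 - f1)."""
    v = np.asarray(f2, dtype=float) - np.asarray(f1, dtype=float)
    if np.allclose(v, 0.0):
        return 0.0, float("nan")
    return polar(v)


def _wrap_angle(a):
    """Wrap angle differences into (-180, 180]."""
    return -(np.mod(-np.asarray(a) + 180.0, 360.0) - 180.0)


def add_compensation(observations: pd.DataFrame) -> pd.DataFrame:
    """Compute compensation records for every valid trial observation.

    Expects the canonical-frame columns produced by
    :func:`saccd.preprocess.preprocess_table` and returns one record per
    valid trial with ideal/actual amplitude and angle, the signed angle
    error (negative = inward) and amplitude error.  Degenerate trials
    (first fixation already on the second target) are flagged and carry
    NaN angles.
    """
    obs = observations.loc[observations["valid"]].copy()
    vx = obs["t2x"] - obs["f1x"]
    vy = obs["t2y"] - obs["f1y"]
    ax = obs["f2x"] - obs["f1x"]
    ay = obs["f2y"] - obs["f1y"]
    obs["ideal_amp"] = np.hypot(vx, vy)
    obs["actual_amp"] = np.hypot(ax, ay)
    with np.errstate(invalid="ignore"):
        obs["ideal_angle"] = np.degrees(np.arctan2(vy, vx))
        obs["actual_angle"] = np.degrees(np.arctan2(ay, ax))
    degenerate = (obs["ideal_amp"] == 0) | (obs["actual_amp"] == 0)
    obs.loc[degenerate, ["ideal_angle", "actual_angle"]] = np.nan
    obs["degenerate"] = degenerate
    obs["angle_error"] = _wrap_angle(obs["actual_angle"] - obs["ideal_angle"])
    obs["amp_error"] = obs["actual_amp"] - obs["ideal_amp"]
    return obs


def center_predictors(
    records: pd.DataFrame,
    grouping: str = "grand",
    columns: tuple[str, ...] = ("ideal_angle", "ideal_amp"),
) -> pd.DataFrame:
    """Store mean-centred copies of the ideal-saccade predictors.

    ``grouping="grand"`` subtracts the mean over the whole analysis set
    (the default, matching a single centred predictor per model);
    ``grouping="subject"`` centres within subject.  Centred columns get
    a ``_c`` suffix; raw values are kept.
    """
    if len(records) == 0:
        raise ValueError("cannot centre an empty record set")
    out = records.copy()
    for col in columns:
        if grouping == "grand":
            out[f"{col}_c"] = out[col] - out[col].mean()
        elif grouping == "subject":
            out[f"{col}_c"] = out[col] - out.groupby("subject_id")[col].transform("mean")
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
    return out


def laterality_code(
    side: str,
    symptom_side: str = "none",
    dat_left: float | None = None,
    dat_right: float | None = None,
    reference: str = "symptom_side",
) -> str:
    """Code a trial's target side as 'ipsi', 'contra' or 'none'.

    ``reference="symptom_side"``: targets on the same screen side as the
    predominant motor symptoms are *ipsi*; symmetric (or healthy)
    subjects give 'none'.

    ``reference="low_dat_hemisphere"``: each visual hemifield projects to
    the contralateral hemisphere, so targets in the hemifield *opposite*
    the lower-binding hemisphere are the ones that hemisphere processes -
    they are coded *contra* (the crossed mapping, applied exactly once
    here).  Targets on the same side as the lower-binding hemisphere are
    'ipsi'.  Equal binding gives 'none'.
    """
    if side not in ("left", "right"):
        raise ValueError(f"trial side must be 'left' or 'right', got {side!r}")
    if reference == "symptom_side":
        if symptom_side not in ("left", "right"):
            return "none"
        return "ipsi" if side == symptom_side else "contra"
    if reference == "low_dat_hemisphere":
        if dat_left is None or dat_right is None or dat_left == dat_right:
            return "none"
        low = "left" if dat_left < dat_right else "right"
        return "contra" if side != low else "ipsi"
    raise ValueError(f"unknown laterality reference {reference!r}")


def add_laterality(
    records: pd.DataFrame,
    subjects: pd.DataFrame,
    reference: str = "symptom_side",
) -> pd.DataFrame:
    """Merge subject covariates and attach the per-trial laterality code."""
    merged = records.merge(
        subjects, on="subject_id", how="left", validate="many_to_one"
    )
    merged["laterality"] = [
        laterality_code(
            row["side"],
            row.get("symptom_side", "none"),
            row.get("dat_left"),
            row.get("dat_right"),
            reference,
        )
        for _, row in merged.iterrows()
    ]
    return merged


def estimate_cd_gain(observations: pd.DataFrame) -> pd.DataFrame:
    """Least-squares CD-gain estimate per subject from valid trials.

    Under the generative model the executed second-saccade vector is
    ``f2 - f1 = g2*T2 - g2*lambda*f1`` (plus noise), so regressing the
    executed vector's components on the target and first-endpoint
    components (both x and y equations stacked, no intercept) gives
    coefficients ``b1 = g2`` and ``b2 = -g2*lambda``, hence
    ``lambda = -b2/b1``.  Memory-condition trials carry extra target
    noise; the estimator is unbiased for both conditions but tighter on
    Baseline data.
    """
    rows = []
    for sid, sub in observations.loc[observations["valid"]].groupby("subject_id"):
        a = np.concatenate(
            [(sub["f2x"] - sub["f1x"]).to_numpy(), (sub["f2y"] - sub["f1y"]).to_numpy()]
        )
        t2 = np.concatenate([sub["t2x"].to_numpy(), sub["t2y"].to_numpy()])
        f1 = np.concatenate([sub["f1x"].to_numpy(), sub["f1y"].to_numpy()])
        design = np.column_stack([t2, f1])
        coef, *_ = np.linalg.lstsq(design, a, rcond=None)
        b1, b2 = coef
        rows.append(
            {
                "subject_id": sid,
                "gain2_hat": float(b1),
                "cd_gain_hat": float(-b2 / b1) if b1 != 0 else np.nan,
                "n_trials": len(sub),
            }
        )
    return pd.DataFrame(rows)
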