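"""Trial screening, fixation-to-target matching and signed errors.

A trial is kept only if (a) the first saccade was directed toward the
first target and (b) a later saccade was directed toward the second
target; everything else is excluded with a recorded reason.  "Directed
toward" is operationalised as a movement of at least ``min_amplitude_deg``
whose direction deviates from the line of sight to the target by at most
``direction_tol_deg`` (both configurable; the defaults are a 45-degree
half-angle and a 2-degree amplitude floor).

For valid trials the fixations closest to the first and second target
are selected (the second among fixations occurring after the first), the
coordinates are reflected into the canonical upper-right arrangement,
and signed component errors ``fixation - target`` are computed.  Under
this convention undershoot of the eccentric first target gives negative
errors, while stopping short of the second target - which lies below the
first on the horizontal meridian - gives a positive vertical error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ScreenConfig, TrialLayout, deg_to_px, make_layout, to_canonical

__all__ = [
    "PreprocessConfig",
    "screen_trial",
    "match_fixations",
    "compute_errors",
    "preprocess_table",
    "OBSERVATION_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Column order of the trial-observation table written to CSV.
OBSERVATION_COLUMNS = [
    "subject_id",
    "trial_id",
    "condition",
    "quadrant",
    "t2_index",
    "side",
    "valid",
    "reason",
    "f1x",
    "f1y",
    "f2x",
    "f2y",
    "t1x",
    "t1y",
    "t2x",
    "t2y",
    "t1_dx",
    "t1_dy",
    "t2_dx",
    "t2_dy",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tolerances of the "directed toward the target" screening rule."""

    direction_tol_deg: float = 45.0
    min_amplitude_deg: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.direction_tol_deg <= 90:
            raise ValueError("direction_tol_deg must be in (0, 90]")
        if self.min_amplitude_deg < 0:
            raise ValueError("min_amplitude_deg must be >= 0")


def _angle_between(v: np.ndarray, w: np.ndarray) -> float:
    """Unsigned angle between two vectors, degrees."""
    nv, nw = np.hypot(*v), np.hypot(*w)
    if nv == 0 or nw == 0:
        return 0.0
    c = float(np.dot(v, w) / (nv * nw))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def screen_trial(
    points: np.ndarray,
    layout: TrialLayout,
    screen: ScreenConfig | None = None,
    config: PreprocessConfig | None = None,
) -> tuple[bool, str]:
    """Validity screen for one trial's ordered fixation positions.

    *points* is the (n, 2) array of fixation positions in presentation
    order (screen coordinates, not canonical).  Returns ``(valid,
    reason)`` with reason ``"ok"`` for kept trials.
    """
    screen = ScreenConfig() if screen is None else screen
    config = PreprocessConfig() if config is None else config
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < 2:
        return False, "no_saccade"
    min_amp = deg_to_px(config.min_amplitude_deg, screen)
    steps = np.diff(points, axis=0)
    amps = np.hypot(steps[:, 0], steps[:, 1])
    saccadic = np.flatnonzero(amps >= min_amp)
    if saccadic.size == 0:
        return False, "no_saccade"
    k = int(saccadic[0])
    origin = points[k]
    if _angle_between(steps[k], np.asarray(layout.t1_pos) - origin) > config.direction_tol_deg:
        return False, "t1_misdirected"
    t2 = np.asarray(layout.t2_pos)
    for j in saccadic[saccadic > k]:
        if _angle_between(steps[j], t2 - points[j]) <= config.direction_tol_deg:
            return True, "ok"
    return False, "no_second_saccade"


def match_fixations(
    points: np.ndarray, layout: TrialLayout
) -> tuple[int, int | None]:
    """Indices of the fixations closest to T1 and, after it, to T2.

    ``i1`` minimises the Euclidean distance to the first target over all
    fixations; ``i2`` minimises the distance to the second target over
    the fixations strictly after ``i1``, so a return-to-centre fixation
    is only ever selected when nothing closer to T2 follows the first
    matched fixation.  ``i2`` is ``None`` when no fixation follows
    ``i1`` (degenerate trial).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        raise ValueError("trial has no fixations")
    t1 = np.asarray(layout.t1_pos)
    t2 = np.asarray(layout.t2_pos)
    d1 = np.hypot(*(points - t1).T)
    i1 = int(np.argmin(d1))
    if i1 + 1 >= len(points):
        return i1, None
    d2 = np.hypot(*(points[i1 + 1 :] - t2).T)
    i2 = i1 + 1 + int(np.argmin(d2))
    return i1, i2


def compute_errors(
    f1: np.ndarray, f2: np.ndarray, layout: TrialLayout
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Canonicalise matched fixations and compute signed errors.

    Returns ``(f1c, f2c, t1c, t2c, err1, err2)`` where errors are
    ``fixation - target`` componentwise in the canonical (upper-right)
    frame.
    """
    q = layout.quadrant
    f1c = to_canonical(f1, q)
    f2c = to_canonical(f2, q)
    t1c = to_canonical(layout.t1_pos, q)
    t2c = to_canonical(layout.t2_pos, q)
    return f1c, f2c, t1c, t2c, f1c - t1c, f2c - t2c


def preprocess_table(
    fixations: pd.DataFrame,
    screen: ScreenConfig | None = None,
    config: PreprocessConfig | None = None,
    polar_angle: float = 45.0,
) -> pd.DataFrame:
    """Screen, match and canonicalise every trial of a fixation table.

    *fixations* follows the generator's fixation-table schema (one row
    per fixation, ordered by ``fix_index`` within a trial).  Returns one
    row per trial; error columns are NaN for excluded trials.  The
    function is deterministic and side-effect free, so re-running it on
    the same input reproduces its output exactly.
    """
    screen = ScreenConfig() if screen is None else screen
    config = PreprocessConfig() if config is None else config
    out: list[dict] = []
    for (sid, tid), trial in fixations.groupby(["subject_id", "trial_id"], sort=True):
        trial = trial.sort_values("fix_index")
        first = trial.iloc[0]
        layout = make_layout(
            screen, str(first["quadrant"]), int(first["t2_index"]), polar_angle
        )
        points = trial[["x", "y"]].to_numpy(dtype=float)
        row = {
            "subject_id": sid,
            "trial_id": tid,
            "condition": first["condition"],
            "quadrant": layout.quadrant,
            "t2_index": layout.t2_index,
            "side": layout.side,
            "valid": False,
            "reason": "",
            "f1x": np.nan, "f1y": np.nan, "f2x": np.nan, "f2y": np.nan,
            "t1x": np.nan, "t1y": np.nan, "t2x": np.nan, "t2y": np.nan,
            "t1_dx": np.nan, "t1_dy": np.nan, "t2_dx": np.nan, "t2_dy": np.nan,
        }
        valid, reason = screen_trial(points, layout, screen, config)
        if valid:
            i1, i2 = match_fixations(points, layout)
            if i2 is None:
                valid, reason = False, "no_fixation_after_t1"
            else:
                f1c, f2c, t1c, t2c, err1, err2 = compute_errors(
                    points[i1], points[i2], layout
                )
                row.update(
                    f1x=f1c[0], f1y=f1c[1], f2x=f2c[0], f2y=f2c[1],
                    t1x=t1c[0], t1y=t1c[1], t2x=t2c[0], t2y=t2c[1],
                    t1_dx=err1[0], t1_dy=err1[1], t2_dx=err2[0], t2_dy=err2[1],
                )
        row["valid"] = valid
        row["reason"] = reason
        if not valid:
            logger.info("excluded trial %s/%s: %s", sid, tid, reason)
        out.append(row)
    return pd.DataFrame(out, columns=OBSERVATION_COLUMNS)
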