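"""Screen and task geometry for the double-step saccade task.

The task presents a first target (T1) about 16 degrees from central
fixation in one of the four screen quadrants, followed by a second target
(T2) flashed on the horizontal meridian on the same side of the screen.
Analyses are carried out in a canonical frame in which T1 lies in the
upper-right quadrant; trials from other quadrants are reflected into it
by sign flips (``to_canonical``), which preserve distances and unsigned
angle differences.

Coordinates are pixels, origin at the screen centre, +x rightward,
+y upward.  Degrees are converted with a flat pixels-per-degree constant
(default 22 px/deg for the 1024x768 CRT geometry this task was designed
around) rather than a full tangent-screen model; at 16 deg eccentricity
the flat approximation is well within the endpoint scatter of real
saccades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "QUADRANTS",
    "ScreenConfig",
    "TrialLayout",
    "deg_to_px",
    "px_to_deg",
    "quadrant_signs",
    "t2_candidates",
    "make_layout",
    "to_canonical",
]

QUADRANTS = ("UR", "UL", "LR", "LL")

_SIGNS = {
    "UR": (1.0, 1.0),
    "UL": (-1.0, 1.0),
    "LR": (1.0, -1.0),
    "LL": (-1.0, -1.0),
}

#: Eccentricity of the first target from central fixation, degrees.
T1_ECCENTRICITY_DEG = 16.0
#: Minimum separation of the candidate second-target positions, degrees.
T2_SPACING_DEG = 2.4
#: Number of equally likely second-target positions.
N_T2_POSITIONS = 4


@dataclass(frozen=True)
class ScreenConfig:
    """Display geometry and timing of the experimental monitor."""

    width_px: int = 1024
    height_px: int = 768
    px_per_deg: float = 22.0
    refresh_hz: float = 85.0
    viewing_distance_cm: float = 70.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "px_per_deg", "refresh_hz",
                     "viewing_distance_cm"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"ScreenConfig.{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class TrialLayout:
    """Target placement and stimulus timing for one double-saccade trial.

    ``t1_pos``/``t2_pos`` are screen points in pixels (centre origin).
    ``t2_index`` selects one of the four candidate T2 x-positions
    (1-based, ordered from the innermost candidate outward).
    """

    quadrant: str
    t1_pos: tuple[float, float]
    t2_pos: tuple[float, float]
    t2_index: int
    t1_duration_ms: float = 500.0
    t2_duration_ms: float = 130.0
    fixation_duration_ms: float = 1350.0

    def __post_init__(self) -> None:
        if self.quadrant not in QUADRANTS:
            raise ValueError(f"unknown quadrant {self.quadrant!r}")
        if not 1 <= self.t2_index <= N_T2_POSITIONS:
            raise ValueError(f"t2_index must be in 1..{N_T2_POSITIONS}")
        if self.t2_pos[1] != 0.0:
            raise ValueError("second target must lie on the horizontal meridian")

    @property
    def side(self) -> str:
        """Screen side ('left'/'right') on which the targets appeared."""
        return "left" if self.t1_pos[0] < 0 else "right"


def deg_to_px(value: float, config: ScreenConfig) -> float:
    """Convert visual degrees to pixels with the configured flat scale."""
    return value * config.px_per_deg


def px_to_deg(value: float, config: ScreenConfig) -> float:
    """Inverse of :func:`deg_to_px`."""
    return value / config.px_per_deg


def quadrant_signs(quadrant: str) -> tuple[float, float]:
    """(sx, sy) sign pair mapping canonical (UR) coordinates into *quadrant*."""
    try:
        return _SIGNS[quadrant]
    except KeyError:
        raise ValueError(f"unknown quadrant {quadrant!r}") from None


def t2_candidates(
    config: ScreenConfig,
    quadrant: str,
    polar_angle: float = 45.0,
    spacing_deg: float = T2_SPACING_DEG,
) -> np.ndarray:
    """The four candidate T2 x-positions (px) for a given T1 placement.

    Candidates are evenly spaced at ``spacing_deg`` steps, centred on the
    horizontal position of T1 so that the flashed second target sits
    "under" the first in the canonical arrangement.  Only the minimum
    spacing is a task constraint; the even centred grid is this package's
    concrete choice.
    """
    t1x = _t1_position(config, quadrant, polar_angle)[0]
    step = deg_to_px(spacing_deg, config)
    offsets = (np.arange(N_T2_POSITIONS) - (N_T2_POSITIONS - 1) / 2.0) * step
    xs = t1x + offsets
    # order by eccentricity so index 1 is always the innermost candidate
    return xs[np.argsort(np.abs(xs))]


def _t1_position(config: ScreenConfig, quadrant: str, polar_angle: float) -> tuple[float, float]:
    if not 0.0 < polar_angle < 90.0:
        raise ValueError("polar_angle must lie strictly inside (0, 90) degrees")
    ecc_px = deg_to_px(T1_ECCENTRICITY_DEG, config)
    sx, sy = quadrant_signs(quadrant)
    x = sx * ecc_px * math.cos(math.radians(polar_angle))
    y = sy * ecc_px * math.sin(math.radians(polar_angle))
    return (x, y)


def make_layout(
    config: ScreenConfig,
    quadrant: str,
    t2_index: int,
    polar_angle: float = 45.0,
    spacing_deg: float = T2_SPACING_DEG,
    fixation_duration_ms: float = 1350.0,
) -> TrialLayout:
    """Place T1 at 16 deg eccentricity in *quadrant* and pick a T2 candidate.

    Raises ``ValueError`` if the requested placement falls off the screen
    or a candidate T2 would cross the vertical meridian (the task keeps
    both targets on the same side of the screen).
    """
    t1 = _t1_position(config, quadrant, polar_angle)
    half_w, half_h = config.width_px / 2.0, config.height_px / 2.0
    if abs(t1[0]) > half_w or abs(t1[1]) > half_h:
        raise ValueError(
            f"T1 at {t1} px falls off the {config.width_px}x{config.height_px} screen"
        )
    xs = t2_candidates(config, quadrant, polar_angle, spacing_deg)
    if np.any(np.sign(xs) != np.sign(t1[0])) or np.any(np.abs(xs) > half_w):
        raise ValueError("candidate T2 positions leave the target half-screen")
    t2 = (float(xs[t2_index - 1]), 0.0)
    return TrialLayout(
        quadrant=quadrant,
        t1_pos=t1,
        t2_pos=t2,
        t2_index=t2_index,
        fixation_duration_ms=fixation_duration_ms,
    )


def to_canonical(point, quadrant: str) -> np.ndarray:
    """Reflect *point* so the trial matches the upper-right arrangement.

    The map multiplies x by -1 for left-side quadrants (UL, LL) and y by
    -1 for lower quadrants (LR, LL); applying it twice is the identity.
    Works on a single (x, y) pair or an (n, 2) array.
    """
    sx, sy = quadrant_signs(quadrant)
    pt = np.asarray(point, dtype=float)
    return pt * np.array([sx, sy])
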