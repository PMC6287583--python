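"""DAT-SPECT specific binding ratios and hemisphere summaries.

The specific binding ratio of a region of interest is its uptake
relative to an occipital reference region::

    SBR = (ROI - OCC) / OCC

Mean striatal binding per hemisphere is the arithmetic mean of the
caudate, anterior putamen and posterior putamen SBRs.  The hemisphere
with the lower mean is the "more affected" one; its (cohort-centred)
binding enters the behavioural models as a covariate, and each trial is
coded relative to it (see :mod:`saccd.compensation`).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["STRIATAL_REGIONS", "sbr", "summarize_dat"]

STRIATAL_REGIONS = ("caudate", "anterior_putamen", "posterior_putamen")
HEMISPHERES = ("left", "right")


def sbr(roi_uptake, occ_uptake):
    """Specific binding ratio ``(ROI - OCC) / OCC``; scale invariant."""
    roi = np.asarray(roi_uptake, dtype=float)
    occ = np.asarray(occ_uptake, dtype=float)
    if np.any(occ <= 0):
        raise ValueError("occipital reference uptake must be > 0")
    out = (roi - occ) / occ
    return float(out) if out.ndim == 0 else out


def summarize_dat(uptakes: pd.DataFrame) -> pd.DataFrame:
    """Per-subject DAT summary from region-level uptakes.

    *uptakes* has one row per subject with columns ``occipital`` and
    ``<hemisphere>_<region>`` for both hemispheres and the three striatal
    regions.  Returns regional SBRs, per-hemisphere mean striatal values,
    the lower-binding hemisphere (ties broken to 'left' with a warning),
    the mean striatal binding of that hemisphere, and its cohort-centred
    copy (``*_c``; zero cohort mean by construction).
    """
    required = ["occipital"] + [
        f"{h}_{r}" for h in HEMISPHERES for r in STRIATAL_REGIONS
    ]
    missing = [c for c in required if c not in uptakes.columns]
    if missing:
        raise ValueError(f"uptake table missing columns: {missing}")
    out = uptakes[["subject_id"]].copy() if "subject_id" in uptakes.columns else pd.DataFrame(index=uptakes.index)
    occ = uptakes["occipital"]
    for hemi in HEMISPHERES:
        cols = []
        for region in STRIATAL_REGIONS:
            col = f"sbr_{hemi}_{region}"
            out[col] = sbr(uptakes[f"{hemi}_{region}"], occ)
            cols.append(col)
        out[f"mean_striatal_{hemi}"] = out[cols].mean(axis=1)
    ties = out["mean_striatal_left"] == out["mean_striatal_right"]
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} subject(s) with identical hemisphere means; "
            "low-binding hemisphere set to 'left'",
            stacklevel=2,
        )
    out["low_binding_hemisphere"] = np.where(
        out["mean_striatal_left"] <= out["mean_striatal_right"], "left", "right"
    )
    out["mean_striatal_low"] = out[["mean_striatal_left", "mean_striatal_right"]].min(axis=1)
    out["mean_striatal_low_c"] = out["mean_striatal_low"] - out["mean_striatal_low"].mean()
    return out
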