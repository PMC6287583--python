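"""Shared fixtures: screen geometry, canned generator regimes, cohorts."""

import numpy as np
import pandas as pd
import pytest

from saccd.cohort import GenParams, simulate_cohort
from saccd.geometry import ScreenConfig, TrialLayout
from saccd.preprocess import preprocess_table


def noiseless_params(cd_gain=1.0, g1=1.0, g2=1.0, seed=0, **overrides) -> GenParams:
    """Generator parameters with every stochastic ingredient switched off."""
    base = dict(
        cd_gain=cd_gain,
        motor_gain_1=(g1, g1),
        motor_gain_2=(g2, g2),
        motor_noise_cv=0.0,
        memory_noise_deg=0.0,
        invalid_rate=0.0,
        subject_sd=0.0,
        dat_coupling_cd=0.0,
        dat_coupling_gain=0.0,
        laterality_delta_cd=0.0,
        laterality_delta_gain=0.0,
        seed=seed,
    )
    base.update(overrides)
    return GenParams(**base)


def subject_row(cd_gain=1.0, g1=1.0, g2=1.0, group="control", symptom_side="none"):
    """Minimal subject record for direct simulate_trial calls."""
    return pd.Series(
        dict(
            subject_id="s1",
            group=group,
            symptom_side=symptom_side,
            cd_gain=cd_gain,
            motor_gain_1_baseline=g1,
            motor_gain_1_memory=g1,
            motor_gain_2_baseline=g2,
            motor_gain_2_memory=g2,
        )
    )


def example_layout(t2x=248.9015869776647):
    """Canonical upper-right layout with T2 directly below T1."""
    return TrialLayout(
        quadrant="UR",
        t1_pos=(248.9015869776647, 248.9015869776647),
        t2_pos=(t2x, 0.0),
        t2_index=2,
    )


@pytest.fixture(scope="session")
def screen() -> ScreenConfig:
    return ScreenConfig()


@pytest.fixture(scope="session")
def default_cohort():
    """One stochastic paper-scale cohort (14 PD + 14 controls, 30+30 trials)."""
    return simulate_cohort(GenParams(seed=20260923))


@pytest.fixture(scope="session")
def default_observations(default_cohort, screen):
    fixations, _, _ = default_cohort
    return preprocess_table(fixations, screen)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
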