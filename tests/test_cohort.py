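"""Generative model: closed-loop geometry, CD sign behaviour, cohort contracts."""

import numpy as np
import pandas as pd
import pytest

from conftest import example_layout, noiseless_params, subject_row
from saccd.cohort import (
    GenParams,
    _symptom_sides,
    roi_uptake_table,
    simulate_cohort,
    simulate_observer,
    simulate_trial,
)
from saccd.geometry import ScreenConfig


def _one_trial(cd_gain, g1, g2, condition="Baseline", layout=None, screen=None, seed=0):
    screen = screen or ScreenConfig()
    layout = layout or example_layout()
    gen = noiseless_params(cd_gain=cd_gain, g1=g1, g2=g2)
    subj = subject_row(cd_gain=cd_gain, g1=g1, g2=g2)
    rng = np.random.default_rng(seed)
    return simulate_trial(subj, gen, layout, condition, rng, screen)


@pytest.mark.parametrize("condition", ["Baseline", "Memory"])
def test_veridical_closed_loop_lands_on_t2(condition):
    _, truth = _one_trial(1.0, 1.0, 1.0, condition)
    layout = example_layout()
    assert truth["e2x"] == pytest.approx(layout.t2_pos[0], abs=1e-9)
    assert truth["e2y"] == pytest.approx(layout.t2_pos[1], abs=1e-9)


def test_amplified_cd_worked_example():
    # lambda=1.2, g1=0.85: E1 = 0.85*T1, E2 = E1 + (T2 - 1.2*E1)
    _, truth = _one_trial(1.2, 0.85, 1.0)
    assert truth["e1x"] == pytest.approx(211.6, abs=0.1)
    assert truth["e1y"] == pytest.approx(211.6, abs=0.1)
    assert truth["e2x"] == pytest.approx(206.6, abs=0.1)
    assert truth["e2y"] == pytest.approx(-42.3, abs=0.1)
    # horizontal error at T2 is inward (negative, toward screen centre)
    assert truth["e2x"] - example_layout().t2_pos[0] == pytest.approx(-42.3, abs=0.1)


def test_diminished_cd_biases_outward():
    _, truth = _one_trial(0.8, 0.85, 1.0)
    assert truth["e2x"] - example_layout().t2_pos[0] > 0


def test_t2_horizontal_error_decreases_in_cd_gain():
    errors = []
    for lam in (0.8, 0.9, 1.0, 1.1, 1.2):
        _, truth = _one_trial(lam, 0.9, 1.0)
        errors.append(truth["e2x"] - example_layout().t2_pos[0])
    assert all(a > b for a, b in zip(errors, errors[1:]))
    # lambda = 1 compensates exactly despite the hypometric first saccade
    assert errors[2] == pytest.approx(0.0, abs=1e-9)


def test_hypometric_first_saccade_fully_compensated_at_unit_gain():
    _, truth = _one_trial(1.0, 0.85, 1.0)
    layout = example_layout()
    assert truth["e1x"] - layout.t1_pos[0] < 0
    assert truth["e1y"] - layout.t1_pos[1] < 0
    assert truth["e2x"] == pytest.approx(layout.t2_pos[0], abs=1e-9)
    assert truth["e2y"] == pytest.approx(layout.t2_pos[1], abs=1e-9)


def test_trial_emits_start_endpoints_and_return_fixations():
    rows, truth = _one_trial(1.0, 1.0, 1.0)
    assert [r["fix_index"] for r in rows] == [0, 1, 2, 3]
    assert (rows[0]["x"], rows[0]["y"]) == (0.0, 0.0)
    assert (rows[3]["x"], rows[3]["y"]) == (0.0, 0.0)
    assert rows[1]["x"] == pytest.approx(truth["e1x"])
    assert rows[2]["y"] == pytest.approx(truth["e2y"])


def test_cohort_counts_and_counterbalancing():
    fix, subjects, truth = simulate_cohort(GenParams(seed=3), n_pd=14, n_control=14)
    assert len(subjects) == 28
    per = truth.groupby(["subject_id", "condition"]).size()
    assert (per == 30).all()
    # condition order alternates across subjects
    first_conditions = truth.groupby("subject_id", sort=False)["condition"].first()
    assert set(first_conditions) == {"Baseline", "Memory"}
    s0, s1 = subjects["subject_id"].iloc[:2]
    assert first_conditions[s0] != first_conditions[s1]


def test_cohort_is_deterministic_given_seed():
    a = simulate_cohort(GenParams(seed=11), n_pd=2, n_control=2)
    b = simulate_cohort(GenParams(seed=11), n_pd=2, n_control=2)
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x, y)


def test_symptom_side_mix_matches_cohort_profile():
    sides = _symptom_sides(14)
    assert sides.count("left") == 8
    assert sides.count("right") == 4
    assert sides.count("symmetric") == 2


def test_subject_covariates_have_expected_structure(default_cohort):
    _, subjects, _ = default_cohort
    controls = subjects[subjects["group"] == "control"]
    patients = subjects[subjects["group"] == "PD"]
    assert (controls["symptom_side"] == "none").all()
    assert (subjects[["dat_left", "dat_right"]] > 0).all().all()
    # patients carry a striatal deficit relative to controls
    assert patients[["dat_left", "dat_right"]].mean(axis=1).mean() < \
        controls[["dat_left", "dat_right"]].mean(axis=1).mean()
    # depleted striatum couples into an amplified CD gain
    assert patients["cd_gain"].mean() > controls["cd_gain"].mean()


def test_dat_coupling_drives_lambda_not_group_label():
    gen = GenParams(seed=5, dat_coupling_cd=0.0, dat_coupling_gain=0.0,
                    laterality_delta_cd=0.0, laterality_delta_gain=0.0)
    _, subjects, _ = simulate_cohort(gen, n_pd=40, n_control=40)
    pd_gain = subjects.loc[subjects.group == "PD", "cd_gain"]
    ctl_gain = subjects.loc[subjects.group == "control", "cd_gain"]
    assert abs(pd_gain.mean() - ctl_gain.mean()) < 0.05


def test_invalid_trials_labelled_at_configured_rate():
    gen = noiseless_params(invalid_rate=0.2, seed=21)
    _, _, truth = simulate_cohort(gen, n_pd=5, n_control=5, trials_per_condition=30)
    rate = truth["invalid"].mean()
    assert rate == pytest.approx(0.2, abs=0.04)


def test_roi_uptakes_recover_subject_dat_means(default_cohort):
    _, subjects, _ = default_cohort
    uptakes = roi_uptake_table(subjects, rng=np.random.default_rng(1))
    occ = uptakes["occipital"]
    for hemi in ("left", "right"):
        cols = [f"{hemi}_caudate", f"{hemi}_anterior_putamen", f"{hemi}_posterior_putamen"]
        sbr_mean = (uptakes[cols].sub(occ, axis=0).div(occ, axis=0)).mean(axis=1)
        assert np.allclose(sbr_mean, subjects[f"dat_{hemi}"], atol=1e-6)


class TestObserver:
    def test_floor_and_ceiling(self):
        obs = simulate_observer(-1.5)
        assert obs.p_correct(-10.0) == pytest.approx(0.5, abs=1e-6)
        assert obs.p_correct(10.0) == pytest.approx(0.99, abs=1e-6)

    def test_target_probability_at_threshold(self):
        obs = simulate_observer(-1.5)
        assert obs.p_correct(-1.5) == pytest.approx(0.81, abs=1e-9)

    def test_lapse_validation(self):
        with pytest.raises(ValueError):
            simulate_observer(-1.5, lapse=0.5)
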