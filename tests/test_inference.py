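"""Mixed-model fitting, pruning, bootstrap CIs, Mann-Whitney oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saccd.inference import (
    _mann_whitney,
    bootstrap_ci,
    fit_mixed,
    prune,
    questionnaire_test,
    simulate_mixed_responses,
)


def _toy_design(n_subjects=12, n_trials=40, rng=None):
    rng = np.random.default_rng(0) if rng is None else rng
    rows = []
    for s in range(n_subjects):
        for t in range(n_trials):
            rows.append(
                {
                    "subject_id": f"s{s:02d}",
                    "is_pd": float(s >= n_subjects // 2),
                    "is_memory": float(t % 2),
                    "noise_pred": rng.normal(),
                }
            )
    return pd.DataFrame(rows)


def test_recovers_known_coefficients_within_wald_cis():
    rng = np.random.default_rng(42)
    design = _toy_design(16, 60, rng)
    beta = {"Intercept": -20.0, "is_pd": -8.0, "is_memory": 12.0, "is_pd:is_memory": -15.0}
    design["y"] = simulate_mixed_responses(
        design, beta, re_sd=10.0, slope_sd=5.0, resid_sd=20.0, rng=rng
    )
    res = fit_mixed(design, "y", ["is_pd", "is_memory", "is_pd:is_memory"],
                    re_formula="~is_memory")
    assert res.converged
    for term, true_val in beta.items():
        row = res.terms.loc[term]
        se = (row["ci_high"] - row["ci_low"]) / (2 * 1.959963984540054)
        assert abs(row["estimate"] - true_val) < 3 * se


def test_prune_keeps_strong_model_untouched():
    rng = np.random.default_rng(1)
    design = _toy_design(16, 60, rng)
    beta = {"Intercept": -20.0, "is_pd": -15.0, "is_memory": 18.0, "is_pd:is_memory": -20.0}
    design["y"] = simulate_mixed_responses(design, beta, re_sd=5.0, resid_sd=15.0, rng=rng)
    res = prune(design, "y", ["is_pd", "is_memory", "is_pd:is_memory"])
    assert res.pruning_trace == []
    assert set(res.terms.index) == {"Intercept", "is_pd", "is_memory", "is_pd:is_memory"}


def test_prune_removes_pure_noise_predictor():
    rng = np.random.default_rng(2)
    design = _toy_design(16, 60, rng)
    beta = {"Intercept": -20.0, "is_pd": -15.0, "is_memory": 18.0}
    design["y"] = simulate_mixed_responses(design, beta, re_sd=5.0, resid_sd=15.0, rng=rng)
    res = prune(design, "y", ["is_pd", "is_memory", "noise_pred"])
    assert "noise_pred" not in res.terms.index
    assert [step["removed"] for step in res.pruning_trace] == ["noise_pred"]
    assert abs(res.pruning_trace[0]["tvalue"]) < 2


def test_prune_respects_marginality():
    # main effects stay while their interaction is retained, even at |t| < 2
    rng = np.random.default_rng(3)
    design = _toy_design(20, 80, rng)
    beta = {"Intercept": 0.0, "is_pd": 0.0, "is_memory": 0.0, "is_pd:is_memory": 25.0}
    design["y"] = simulate_mixed_responses(design, beta, re_sd=5.0, resid_sd=15.0, rng=rng)
    res = prune(design, "y", ["is_pd", "is_memory", "is_pd:is_memory"])
    assert "is_pd:is_memory" in res.terms.index
    assert {"is_pd", "is_memory"} <= set(res.terms.index)


def test_prune_is_deterministic():
    rng = np.random.default_rng(4)
    design = _toy_design(12, 40, rng)
    design["y"] = simulate_mixed_responses(
        design, {"Intercept": 1.0, "is_memory": 5.0}, re_sd=3.0, resid_sd=10.0, rng=rng
    )
    r1 = prune(design, "y", ["is_pd", "is_memory", "noise_pred"])
    r2 = prune(design, "y", ["is_pd", "is_memory", "noise_pred"])
    assert r1.pruning_trace == r2.pruning_trace
    pd.testing.assert_frame_equal(r1.terms, r2.terms)


class TestBootstrap:
    def test_constant_data_gives_zero_width(self):
        low, high = bootstrap_ci(np.full(14, 3.25), rng=np.random.default_rng(0))
        assert low == high == pytest.approx(3.25)

    def test_matches_normal_theory_oracle(self):
        rng = np.random.default_rng(5)
        sample = rng.normal(0.0, 1.0, size=14)
        low, high = bootstrap_ci(sample, n_boot=20000, rng=rng)
        se = sample.std(ddof=0) / np.sqrt(14)
        assert low == pytest.approx(sample.mean() - 1.96 * se, abs=0.15)
        assert high == pytest.approx(sample.mean() + 1.96 * se, abs=0.15)

    def test_deterministic_given_seed(self):
        sample = np.arange(10.0)
        a = bootstrap_ci(sample, rng=np.random.default_rng(7))
        b = bootstrap_ci(sample, rng=np.random.default_rng(7))
        assert a == b

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0])


def _enumeration_oracle(x, y):
    """Exact U distribution by enumerating all group assignments of the pooled data."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    observed_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
    return observed_u, np.asarray(us)


class TestQuestionnaire:
    def test_identical_groups_give_zero_z(self):
        u, z, p = _mann_whitney([1, 2, 3], [1, 2, 3])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_zero_item_degenerates_to_z0_p1(self):
        # an item nobody endorses in either group
        u, z, p = _mann_whitney([0, 0, 0, 0], [0, 0, 0])
        assert z == 0.0 and p == 1.0
        assert u == pytest.approx(4 * 3 / 2)

    def test_small_fixture_matches_enumeration_oracle(self):
        x, y = [0, 1, 3], [2, 2, 3]
        u, z, p = _mann_whitney(x, y)
        observed_u, all_us = _enumeration_oracle(x, y)
        assert u == pytest.approx(observed_u)
        # Z from the tie-corrected normal approximation, computed independently
        mu = np.mean(all_us)
        sd = np.std(all_us)  # exact permutation SD equals the tie-corrected formula
        assert z == pytest.approx((observed_u - mu) / sd, abs=1e-12)

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(25):
            x = rng.integers(0, 4, size=rng.integers(3, 15))
            y = rng.integers(0, 4, size=rng.integers(3, 15))
            if np.unique(np.concatenate([x, y])).size < 2:
                continue  # scipy's asymptotic p is NaN in the fully tied case
            u, z, p = _mann_whitney(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                     use_continuity=False)
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_long_format_table_per_item(self):
        scores = pd.DataFrame(
            {
                "subject_id": ["c1", "c2", "p1", "p2"] * 2,
                "group": ["control", "control", "PD", "PD"] * 2,
                "item": ["nausea"] * 4 + ["hallucinations"] * 4,
                "score": [0, 1, 1, 2, 0, 0, 0, 0],
            }
        )
        table = questionnaire_test(scores)
        assert list(table.index) == ["nausea", "hallucinations", "Total"]
        assert table.loc["hallucinations", "Z"] == 0.0
        assert table.loc["hallucinations", "p"] == 1.0
        assert table.loc["nausea", "Z"] < 0  # controls scored lower

    def test_requires_two_groups(self):
        bad = pd.DataFrame({"group": ["PD"], "item": ["a"], "score": [1]})
        with pytest.raises(ValueError):
            questionnaire_test(bad)
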