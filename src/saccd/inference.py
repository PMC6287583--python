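"""Mixed-effects inference with |t|-based pruning, cluster bootstrap CIs,
and the questionnaire group comparison.

All saccade-error and compensation analyses are fitted at the single-trial
level with linear mixed models (REML, via statsmodels' ``MixedLM``):
participants contribute random intercepts and, where stated, random
condition slopes.  Following the reporting convention of this analysis
family, no p-values are attached to the mixed models; a fixed effect is
called significant iff its Wald 95% confidence interval excludes zero,
and model pruning removes fixed-effect terms with |t| < 2, smallest
first, never removing a term that still participates in a retained
higher-order interaction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelResult",
    "fit_mixed",
    "prune",
    "fit_error_model",
    "fit_compensation_model",
    "bootstrap_ci",
    "questionnaire_test",
    "simulate_mixed_responses",
]

#: z quantile used for Wald 95% confidence intervals.
_Z95 = stats.norm.ppf(0.975)


@dataclass
class ModelResult:
    """Fitted fixed effects in the Estimate / 95% CI / t-value layout."""

    terms: pd.DataFrame  # index: term; columns: estimate, ci_low, ci_high, tvalue, significant
    formula: str
    converged: bool
    n_obs: int
    n_groups: int
    singular: bool = False
    pruning_trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "converged": self.converged,
            "singular": self.singular,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "pruning_trace": self.pruning_trace,
            "terms": {
                term: {
                    "estimate": float(row["estimate"]),
                    "ci_low": float(row["ci_low"]),
                    "ci_high": float(row["ci_high"]),
                    "tvalue": float(row["tvalue"]),
                    "significant": bool(row["significant"]),
                }
                for term, row in self.terms.iterrows()
            },
        }

    def to_markdown(self, title: str = "") -> str:
        lines = []
        if title:
            lines.append(f"### {title}")
            lines.append("")
        lines.append("| Predictor | Estimate | 95% CI | t value |")
        lines.append("|---|---|---|---|")
        for term, row in self.terms.iterrows():
            lines.append(
                f"| {term} | {row['estimate']:.2f} "
                f"| [{row['ci_low']:.2f}, {row['ci_high']:.2f}] | {row['tvalue']:.2f} |"
            )
        if self.pruning_trace:
            removed = ", ".join(step["removed"] for step in self.pruning_trace)
            lines.append("")
            lines.append(f"Pruned (|t| < 2): {removed}")
        if not self.converged:
            lines.append("")
            lines.append("WARNING: fit did not converge; estimates are provisional.")
        return "\n".join(lines)


def _term_factors(term: str) -> frozenset:
    return frozenset(term.split(":"))


def fit_mixed(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    groups: str = "subject_id",
    re_formula: str = "1",
    reml: bool = True,
) -> ModelResult:
    """Fit ``response ~ 1 + terms`` with the given random structure.

    ``terms`` are patsy-style fixed-effect terms over *numeric* columns
    (e.g. ``"is_pd"``, ``"is_pd:is_memory"``); an intercept is always
    included.  Singular or non-converged fits are reported in the result
    metadata, never silently simplified.
    """
    rhs = " + ".join(terms) if terms else "1"
    formula = f"{response} ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = MixedLM.from_formula(
            formula, data=data, groups=data[groups], re_formula=re_formula
        )
        fitted = model.fit(reml=reml)
    fe = fitted.fe_params
    se = fitted.bse_fe
    tvals = fe / se
    table = pd.DataFrame(
        {
            "estimate": fe,
            "ci_low": fe - _Z95 * se,
            "ci_high": fe + _Z95 * se,
            "tvalue": tvals,
        }
    )
    table["significant"] = (table["ci_low"] > 0) | (table["ci_high"] < 0)
    return ModelResult(
        terms=table,
        formula=formula,
        converged=bool(fitted.converged),
        singular=bool(se.isna().any() or (se <= 0).any()),
        n_obs=int(model.nobs),
        n_groups=int(model.n_groups),
    )


def prune(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    groups: str = "subject_id",
    re_formula: str = "1",
    threshold: float = 2.0,
    reml: bool = True,
) -> ModelResult:
    """Backward-prune fixed effects with |t| below *threshold*.

    One term is removed per refit: among terms not contained in any
    retained higher-order interaction, the one with the smallest |t| is
    dropped if that |t| < threshold.  The intercept is never pruned.  The
    full trace of removals (term and its |t| at removal) is recorded.
    """
    current = list(terms)
    trace: list[dict] = []
    while True:
        result = fit_mixed(data, response, current, groups, re_formula, reml)
        tvals = result.terms["tvalue"]
        removable = [
            t
            for t in current
            if not any(
                _term_factors(t) < _term_factors(other) for other in current if other != t
            )
        ]
        candidates = [t for t in removable if abs(tvals.get(t, np.inf)) < threshold]
        if not candidates:
            result.pruning_trace = trace
            return result
        worst = min(candidates, key=lambda t: abs(tvals[t]))
        trace.append({"removed": worst, "tvalue": float(tvals[worst])})
        current.remove(worst)


def fit_error_model(
    data: pd.DataFrame,
    response: str,
    do_prune: bool = False,
    re_formula: str = "~is_memory + is_t2",
) -> ModelResult:
    """Trial-level model of fixation error on group, target and condition.

    Expects one row per (trial, target) with numeric indicator columns
    ``is_pd`` (patient), ``is_t2`` (second target) and ``is_memory``
    (memory-guided condition), and fits all main effects plus every
    interaction with per-subject random effects.  This is the model
    family behind the horizontal- and vertical-error tables.

    The default random structure carries intercept, condition *and*
    target slopes per subject.  When corollary-discharge and motor gains
    vary across subjects, each subject has their own T1-vs-T2 error
    contrast; omitting the target slope treats that contrast as
    independent noise and inflates the false-positive rate of the
    between-group terms severalfold (measured on null cohorts).  Pass
    ``re_formula="~is_memory"`` for the leaner intercept+condition
    structure used in earlier analyses of this paradigm.
    """
    terms = [
        "is_pd",
        "is_t2",
        "is_memory",
        "is_pd:is_t2",
        "is_pd:is_memory",
        "is_t2:is_memory",
        "is_pd:is_t2:is_memory",
    ]
    if do_prune:
        return prune(data, response, terms, re_formula=re_formula)
    return fit_mixed(data, response, terms, re_formula=re_formula)


def fit_compensation_model(
    records: pd.DataFrame,
    response: str = "actual_angle",
    predictor: str = "ideal_angle_c",
    moderators: list[str] | None = None,
    do_prune: bool = False,
    re_formula: str = "1",
) -> ModelResult:
    """Trial-level model of the executed second saccade on its ideal value.

    The core predictor is the centred ideal angle (or amplitude) required
    to land exactly on the second target given the realised first-saccade
    endpoint; ``moderators`` (e.g. ``["is_pd", "is_memory"]`` or a centred
    DAT-binding column) enter with all interactions up to the full order.
    Rows flagged degenerate (undefined angle) must be removed upstream.
    """
    moderators = list(moderators or [])
    base = [predictor] + moderators
    terms = []
    for r in range(1, len(base) + 1):
        for combo in itertools.combinations(base, r):
            terms.append(":".join(combo))
    if do_prune:
        return prune(records, response, terms, re_formula=re_formula)
    return fit_mixed(records, response, terms, re_formula=re_formula)


def bootstrap_ci(
    values,
    n_boot: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of per-subject values.

    Resamples subjects (not trials) with replacement — the cluster
    bootstrap behind the figure error bars.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least two subjects to bootstrap")
    rng = np.random.default_rng() if rng is None else rng
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(means, [alpha, 1.0 - alpha])
    return float(low), float(high)


def _mann_whitney(x, y) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U with normal approximation and tie correction.

    Returns (U, Z, p) where U counts pairs won by the first sample and Z
    is signed so that smaller first-sample scores give negative Z.  When
    every observation is identical the statistic degenerates to
    (U = n1*n2/2, Z = 0, p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return mu, 0.0, 1.0
    z = (u1 - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(u1), float(z), float(min(p, 1.0))


def questionnaire_test(scores: pd.DataFrame, group_col: str = "group",
                       item_col: str = "item", score_col: str = "score",
                       reference_group: str = "control") -> pd.DataFrame:
    """Per-item Mann-Whitney comparison of ordinal questionnaire scores.

    *scores* is long-format with one row per (subject, item).  Returns a
    table with U, Z and two-sided p per item plus a ``Total`` row on the
    per-subject mean score.  Z is signed with the reference group first,
    so a reference group scoring lower gives negative Z.
    """
    groups = scores[group_col].unique()
    if len(groups) != 2:
        raise ValueError("questionnaire_test expects exactly two groups")
    other = next(g for g in groups if g != reference_group)
    rows = []
    for item, sub in scores.groupby(item_col, sort=False):
        x = sub.loc[sub[group_col] == reference_group, score_col]
        y = sub.loc[sub[group_col] == other, score_col]
        u, z, p = _mann_whitney(x, y)
        rows.append({"item": item, "U": u, "Z": z, "p": p})
    if "subject_id" in scores.columns:
        totals = scores.groupby(["subject_id", group_col], sort=False)[score_col].mean()
        totals = totals.reset_index()
        x = totals.loc[totals[group_col] == reference_group, score_col]
        y = totals.loc[totals[group_col] == other, score_col]
        u, z, p = _mann_whitney(x, y)
        rows.append({"item": "Total", "U": u, "Z": z, "p": p})
    return pd.DataFrame(rows).set_index("item")


def simulate_mixed_responses(
    design: pd.DataFrame,
    beta: dict[str, float],
    re_sd: float,
    slope_sd: float = 0.0,
    resid_sd: float = 1.0,
    slope_col: str = "is_memory",
    groups: str = "subject_id",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw responses from a known linear mixed model over *design*.

    ``beta`` maps term names (``"Intercept"``, ``"is_pd"``,
    ``"is_pd:is_t2"`` ...) to true coefficients; products are taken over
    the named numeric columns.  Subjects get Gaussian random intercepts
    (``re_sd``) and, if ``slope_sd > 0``, random slopes on ``slope_col``.
    This is the calibration oracle used to check estimator coverage.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = len(design)
    y = np.zeros(n)
    for term, b in beta.items():
        if term == "Intercept":
            y += b
        else:
            x = np.ones(n)
            for factor in term.split(":"):
                x = x * design[factor].to_numpy(dtype=float)
            y += b * x
    subjects = design[groups].to_numpy()
    uniq = pd.unique(subjects)
    b0 = dict(zip(uniq, rng.normal(0.0, re_sd, size=len(uniq))))
    y += np.array([b0[s] for s in subjects])
    if slope_sd > 0:
        b1 = dict(zip(uniq, rng.normal(0.0, slope_sd, size=len(uniq))))
        y += np.array([b1[s] for s in subjects]) * design[slope_col].to_numpy(dtype=float)
    y += rng.normal(0.0, resid_sd, size=n)
    return y
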