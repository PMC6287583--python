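"""Config-driven end-to-end runs and deterministic test fixtures.

A run executes simulate -> preprocess -> compensate -> imaging ->
analyze -> psychophys -> report, writing every stage's tables to the
output directory together with a SHA-256 manifest; identical config and
seed reproduce identical files.  Stages can be toggled off, in which
case downstream stages consume the previously written CSVs.

The single global seed is expanded into independent per-stage streams
(``numpy`` seed sequences), so disabling one stage does not perturb the
randomness of the others.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compensation, imaging, inference, preprocess, psychophysics
from .cohort import GenParams, roi_uptake_table, simulate_cohort
from .geometry import ScreenConfig

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "make_fixtures", "STAGES"]

STAGES = ("simulate", "preprocess", "compensate", "imaging", "analyze", "psychophys", "report")

DEFAULT_CONFIG: dict = {
    "seed": 12345,
    "screen": {
        "width_px": 1024,
        "height_px": 768,
        "px_per_deg": 22.0,
        "refresh_hz": 85.0,
        "viewing_distance_cm": 70.0,
    },
    "task": {
        "t1_polar_angle_deg": 45.0,
        "trials_per_condition": 30,
    },
    "cohort": {
        "n_pd": 14,
        "n_control": 14,
    },
    "generator": {
        "cd_gain": 1.0,
        "motor_gain_1": [0.94, 0.90],
        "motor_gain_2": [1.00, 0.97],
        "motor_noise_cv": 0.05,
        "memory_noise_deg": 1.0,
        "invalid_rate": 0.06,
        "subject_sd": 0.05,
        "dat_coupling_cd": 0.20,
        "dat_coupling_gain": 0.08,
        "dat_reference": 2.0,
        "laterality_delta_cd": 0.08,
        "laterality_delta_gain": -0.03,
    },
    "preprocess": {
        "direction_tol_deg": 45.0,
        "min_amplitude_deg": 2.0,
    },
    "psychophysics": {
        "n_trials": 64,
        "fixation_mean": -2.2,
        "subject_sd": 0.2,
        "saccade_elevation": 1.96,
        "after_elevation": 0.78,
    },
    "inference": {
        "centering": "grand",
        "prune": True,
    },
}


def _merge_validate(defaults: dict, override: dict, path: str = "") -> dict:
    out = {}
    for key, value in defaults.items():
        if key in override and isinstance(value, dict):
            if not isinstance(override[key], dict):
                raise ValueError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge_validate(value, override[key], path + key + ".")
        elif key in override:
            out[key] = override[key]
        else:
            out[key] = value
    unknown = set(override) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(path + k for k in unknown)}")
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load and schema-validate a YAML run config; unknown keys are rejected."""
    cfg = {}
    if path is not None:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    cfg = _merge_validate(DEFAULT_CONFIG, cfg)
    if overrides:
        cfg = _merge_validate(cfg, overrides)
    return cfg


def _gen_params(config: dict, seed: int) -> GenParams:
    g = dict(config["generator"])
    g["motor_gain_1"] = tuple(g["motor_gain_1"])
    g["motor_gain_2"] = tuple(g["motor_gain_2"])
    return GenParams(
        **g,
        t1_polar_angle_deg=config["task"]["t1_polar_angle_deg"],
        trials_per_condition=config["task"]["trials_per_condition"],
        seed=seed,
    )


def _write(df: pd.DataFrame, outdir: Path, name: str, manifest: dict) -> Path:
    path = outdir / name
    df.to_csv(path, index=False)
    manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return path


def _error_long_table(obs: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """One row per (valid trial, target) with indicator-coded predictors."""
    valid = obs.loc[obs["valid"]].merge(
        subjects[["subject_id", "group"]], on="subject_id"
    )
    frames = []
    for target, dx, dy in (("T1", "t1_dx", "t1_dy"), ("T2", "t2_dx", "t2_dy")):
        part = valid[["subject_id", "trial_id", "condition", "group"]].copy()
        part["target"] = target
        part["herror"] = valid[dx].to_numpy()
        part["verror"] = valid[dy].to_numpy()
        frames.append(part)
    long = pd.concat(frames, ignore_index=True)
    long["is_pd"] = (long["group"] == "PD").astype(float)
    long["is_t2"] = (long["target"] == "T2").astype(float)
    long["is_memory"] = (long["condition"] == "Memory").astype(float)
    return long


def run_pipeline(
    config: dict | None = None,
    seed: int | None = None,
    outdir: str | Path = "saccd_run",
    stages: tuple[str, ...] | list[str] | None = None,
) -> dict:
    """Run the configured stages, writing artifacts and a manifest.

    Returns a dict with the output paths, the manifest, and the fitted
    model results.  Stages not listed in *stages* are skipped and their
    outputs are read back from *outdir*.
    """
    config = DEFAULT_CONFIG if config is None else _merge_validate(DEFAULT_CONFIG, config)
    seed = config["seed"] if seed is None else int(seed)
    stages = STAGES if stages is None else tuple(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {}
    results: dict = {"outdir": str(outdir), "manifest": manifest, "models": {}}
    screen = ScreenConfig(**config["screen"])
    # independent per-stage random streams from the one global seed
    seeds = np.random.SeedSequence(seed).spawn(len(STAGES))
    stage_rng = {name: np.random.default_rng(s) for name, s in zip(STAGES, seeds)}

    cache: dict = {}

    def _read(name: str) -> pd.DataFrame:
        """Fetch a stage input, reading a previous run's CSV when the
        producing stage is disabled in this run."""
        if name not in cache:
            path = outdir / name
            if not path.exists():
                raise FileNotFoundError(
                    f"stage input {name} missing from {outdir}; "
                    "run its producing stage first"
                )
            cache[name] = pd.read_csv(path)
        return cache[name]

    if "simulate" in stages:
        gen = _gen_params(config, seed)
        fixations, subjects, truth = simulate_cohort(
            gen,
            n_pd=config["cohort"]["n_pd"],
            n_control=config["cohort"]["n_control"],
            screen=screen,
            rng=stage_rng["simulate"],
        )
        uptakes = roi_uptake_table(subjects, rng=stage_rng["simulate"])
        cache["fixations.csv"] = fixations
        cache["subjects.csv"] = subjects
        _write(fixations, outdir, "fixations.csv", manifest)
        _write(subjects, outdir, "subjects.csv", manifest)
        _write(truth, outdir, "trial_truth.csv", manifest)
        _write(uptakes, outdir, "roi_uptake.csv", manifest)

    if "preprocess" in stages:
        ppcfg = preprocess.PreprocessConfig(**config["preprocess"])
        observations = preprocess.preprocess_table(
            _read("fixations.csv"), screen, ppcfg,
            polar_angle=config["task"]["t1_polar_angle_deg"],
        )
        cache["observations.csv"] = observations
        _write(observations, outdir, "observations.csv", manifest)

    if "compensate" in stages:
        records = compensation.add_compensation(_read("observations.csv"))
        records = records.loc[~records["degenerate"]]
        records = compensation.center_predictors(
            records, grouping=config["inference"]["centering"]
        )
        cache["compensation.csv"] = records
        _write(records, outdir, "compensation.csv", manifest)

    if "imaging" in stages:
        dat = imaging.summarize_dat(_read("roi_uptake.csv"))
        cache["dat_summary.csv"] = dat
        _write(dat, outdir, "dat_summary.csv", manifest)

    if "analyze" in stages:
        observations = _read("observations.csv")
        subjects = _read("subjects.csv")
        long = _error_long_table(observations, subjects)
        models = {}
        for resp, label in (("herror", "horizontal_errors"), ("verror", "vertical_errors")):
            models[label] = inference.fit_error_model(long, resp)
        rec = _read("compensation.csv").merge(
            subjects[["subject_id", "group"]], on="subject_id"
        )
        rec["is_pd"] = (rec["group"] == "PD").astype(float)
        rec["is_memory"] = (rec["condition"] == "Memory").astype(float)
        do_prune = bool(config["inference"]["prune"])
        models["compensation_angle"] = inference.fit_compensation_model(
            rec, "actual_angle", "ideal_angle_c", ["is_pd", "is_memory"], do_prune=do_prune
        )
        models["compensation_amplitude"] = inference.fit_compensation_model(
            rec, "actual_amp", "ideal_amp_c", ["is_pd", "is_memory"], do_prune=do_prune
        )
        results["models"].update(models)
        payload = {k: m.to_dict() for k, m in models.items()}
        (outdir / "models.json").write_text(json.dumps(payload, indent=2))
        manifest["models.json"] = hashlib.sha256(
            (outdir / "models.json").read_bytes()
        ).hexdigest()

    if "psychophys" in stages:
        psy = config["psychophysics"]
        thresholds = psychophysics.simulate_suppression_study(
            n_pd=config["cohort"]["n_pd"],
            n_control=config["cohort"]["n_control"],
            fixation_mean=psy["fixation_mean"],
            subject_sd=psy["subject_sd"],
            saccade_elevation=psy["saccade_elevation"],
            after_elevation=psy["after_elevation"],
            n_trials=psy["n_trials"],
            rng=stage_rng["psychophys"],
        )
        _write(thresholds, outdir, "thresholds.csv", manifest)
        supp = psychophysics.suppression_model(thresholds)
        results["models"]["suppression"] = supp
        (outdir / "suppression.json").write_text(json.dumps(supp.to_dict(), indent=2))
        manifest["suppression.json"] = hashlib.sha256(
            (outdir / "suppression.json").read_bytes()
        ).hexdigest()

    if "report" in stages:
        lines = ["# Double-saccade analysis report", ""]
        lines.append(f"Seed: {seed}; subjects: {len(subjects)}; "
                     f"valid trials: {int(observations['valid'].sum())}"
                     f"/{len(observations)}")
        lines.append("")
        for label, model in results["models"].items():
            lines.append(model.to_markdown(title=label.replace("_", " ")))
            lines.append("")
        (outdir / "report.md").write_text("\n".join(lines))
        manifest["report.md"] = hashlib.sha256((outdir / "report.md").read_bytes()).hexdigest()

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


def make_fixtures(kind: str, seed: int = 0) -> dict[str, pd.DataFrame]:
    """Small deterministic cohorts embodying named generator regimes.

    ``veridical``  - unit CD gain and motor gains, zero noise: every
                     saccade lands exactly on its target.
    ``amplified_cd``  - CD gain 1.2, hypometric first saccades, zero
                     noise: second saccades biased inward.
    ``diminished_cd`` - CD gain 0.8: second saccades biased outward.
    ``null_cohort``   - stochastic defaults with every group coupling
                     switched off: PD and control distributions
                     identical.

    Bundles are kept at or under 200 trials (4 subjects x 25 trials x 2
    conditions).
    """
    zero_noise = dict(
        motor_noise_cv=0.0,
        memory_noise_deg=0.0,
        invalid_rate=0.0,
        subject_sd=0.0,
        dat_coupling_cd=0.0,
        dat_coupling_gain=0.0,
        laterality_delta_cd=0.0,
        laterality_delta_gain=0.0,
    )
    regimes = {
        "veridical": GenParams(
            cd_gain=1.0, motor_gain_1=(1.0, 1.0), motor_gain_2=(1.0, 1.0),
            seed=seed, trials_per_condition=25, **zero_noise,
        ),
        "amplified_cd": GenParams(
            cd_gain=1.2, motor_gain_1=(0.85, 0.85), motor_gain_2=(1.0, 1.0),
            seed=seed, trials_per_condition=25, **zero_noise,
        ),
        "diminished_cd": GenParams(
            cd_gain=0.8, motor_gain_1=(0.85, 0.85), motor_gain_2=(1.0, 1.0),
            seed=seed, trials_per_condition=25, **zero_noise,
        ),
        "null_cohort": GenParams(
            seed=seed, trials_per_condition=25,
            dat_coupling_cd=0.0, dat_coupling_gain=0.0,
            laterality_delta_cd=0.0, laterality_delta_gain=0.0,
        ),
    }
    if kind not in regimes:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(regimes)}")
    fixations, subjects, truth = simulate_cohort(regimes[kind], n_pd=2, n_control=2)
    return {"fixations": fixations, "subjects": subjects, "trial_truth": truth}
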