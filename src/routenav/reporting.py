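"""Pipeline orchestration and summary reporting.

Runs the full analysis end-to-end — scenario generation, synthetic trial
generation, preprocessing, comparison metrics, model fitting, and parameter
summaries (including the Box-Cox transform of the right-skewed repulsion
parameter epsilon) — writing tidy CSV/JSON outputs plus a manifest that makes
every number traceable to the configuration and master seed. Inferential
statistics (mixed models, ANOVA) are deliberately exported, not computed: the
emitted tables carry the player x route-type factor structure external tools
need.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy import stats

from . import metrics as _metrics
from .dpmp import DPMPParams, Outcome
from .fitting import DEFAULT_BOUNDS, fit_trajectory
from .preprocess import bin_by_y, filter_trials
from .scenario import (
    PAPER_STARTS,
    PAPER_TARGETS,
    enumerate_scenarios,
    read_scenarios,
    write_scenarios,
)
from .synthetic import (
    default_profiles,
    generate_dataset,
    navigable_obstacle_configs,
    trials_to_dataframe,
)

__all__ = ["RunConfig", "boxcox_transform", "summarize_params", "run_pipeline"]

log = logging.getLogger("routenav")


class PreprocessConfig(BaseModel):
    max_duration: float = 20.0  # s, trial discard rule
    length_factor: float = 1.2  # x scenario mean path length
    bin_width: float = 0.2  # m
    y_min: float = -16.0
    y_max: float = 16.0


class KinematicsConfig(BaseModel):
    forward_speed: float = 10.0  # m/s
    max_turn_rate: float = 25.0  # deg/s
    turn_accel: float = 62.5  # deg/s^2
    frame_rate: float = 50.0  # Hz
    decision_interval: int = 5


class FittingConfig(BaseModel):
    bounds: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    maxiter: int = 60
    popsize: int = 12
    tol: float = 0.01
    n_fit_trials_per_group: int = 2  # trials fitted per population


class RunConfig(BaseModel):
    """Everything a pipeline run depends on, in one validated object."""

    output_dir: str = "run"
    scenario_dir: str | None = None  # read scenarios instead of generating
    seed: int = 0
    n_configs: int = 3
    n_obstacles: int = 9
    min_clearance: float = 2.0
    n_agents_per_profile: int = 10
    reps: int = 6
    route_threshold: float = 0.10  # preferred-route share
    ci_level: float = 95.0
    constants: dict[str, float] = Field(
        default_factory=lambda: {
            k: getattr(DPMPParams(), k) for k in ("c1", "c2", "c3", "c4")
        }
    )
    kinematics: KinematicsConfig = Field(default_factory=KinematicsConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    fitting: FittingConfig = Field(default_factory=FittingConfig)

    @field_validator("n_configs", "n_agents_per_profile", "reps")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("must be >= 1")
        return v

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())


def boxcox_transform(values: np.ndarray, lmbda: float | None = None):
    """Box-Cox power transform of strictly positive values.

    With ``lmbda=None`` the maximum-likelihood lambda is estimated; the
    transform is ``(x**lmbda - 1)/lmbda`` (``log x`` at lambda 0). Returns
    ``(transformed, lmbda)``.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if lmbda is None:
        transformed, lam = stats.boxcox(values)
        return transformed, float(lam)
    return stats.boxcox(values, lmbda=lmbda), float(lmbda)


def summarize_params(
    table: pd.DataFrame,
    group_cols: list[str] | None = None,
    param_cols: tuple[str, ...] = ("beta", "gamma", "epsilon"),
) -> pd.DataFrame:
    """Descriptive statistics of parameter values per group.

    For each group: mean, SD, min, max, skewness, and excess kurtosis of
    each parameter and of Box-Cox-transformed epsilon (one lambda estimated
    over the full table). Empty groups are flagged with ``n = 0`` rows.
    """
    if table.empty:
        raise ValueError("empty parameter table")
    group_cols = group_cols or [
        c for c in ("group", "profile", "route_type") if c in table.columns
    ]
    work = table.copy()
    lam = None
    eps = work["epsilon"] if "epsilon" in work.columns else None
    if eps is not None and (eps > 0).all() and eps.nunique() > 1:
        transformed, lam = boxcox_transform(eps.to_numpy())
        work["epsilon_boxcox"] = transformed
    cols = [c for c in (*param_cols, "epsilon_boxcox") if c in work.columns]
    rows = []
    grouped = work.groupby(group_cols) if group_cols else [((), work)]
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        for col in cols:
            v = sub[col].dropna().to_numpy()
            rows.append(
                {
                    **dict(zip(group_cols, key)),
                    "parameter": col,
                    "n": len(v),
                    "mean": float(np.mean(v)) if len(v) else np.nan,
                    "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                    "min": float(np.min(v)) if len(v) else np.nan,
                    "max": float(np.max(v)) if len(v) else np.nan,
                    "skew": float(stats.skew(v)) if len(v) > 2 else np.nan,
                    "kurtosis": float(stats.kurtosis(v)) if len(v) > 3 else np.nan,
                    "boxcox_lambda": lam if col == "epsilon_boxcox" else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest.

    Stages: scenario generation (or loading) -> synthetic trial generation ->
    preprocessing (discard filters + binning) -> comparison metrics
    (within/between distances, CI containment, preferred routes) -> model
    fitting on a configurable subset -> parameter summary. All outputs are
    CSV/JSON under ``config.output_dir``; the returned manifest records
    seeds, stage counts, and output hashes.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": config.model_dump(),
                      "stages": {}}

    # --- scenarios --------------------------------------------------------
    if config.scenario_dir is not None:
        scenarios = read_scenarios(config.scenario_dir)
    else:
        rng = np.random.default_rng(config.seed)
        configs = navigable_obstacle_configs(
            config.n_configs,
            n_obstacles=config.n_obstacles,
            min_clearance=config.min_clearance,
            seed=rng,
        )
        scenarios = enumerate_scenarios(configs, PAPER_STARTS, PAPER_TARGETS)
    write_scenarios(scenarios, out / "scenarios")
    log.info("stage scenarios: %d scenarios", len(scenarios))
    manifest["stages"]["scenarios"] = {"n_scenarios": len(scenarios)}

    # --- synthetic data ---------------------------------------------------
    profiles = list(default_profiles())
    trials = generate_dataset(
        profiles=profiles,
        n_agents_per_profile=config.n_agents_per_profile,
        scenarios=scenarios,
        reps=config.reps,
        seed=config.seed,
    )
    trial_df = trials_to_dataframe(trials)
    trial_df.to_csv(out / "trials.csv", index=False)
    n_excluded = int(trial_df["excluded"].sum())
    log.info("stage gen-data: %d trials (%d excluded)", len(trials), n_excluded)
    manifest["stages"]["gen_data"] = {
        "n_trials": len(trials),
        "n_excluded": n_excluded,
    }

    # --- preprocess -------------------------------------------------------
    pp = config.preprocess
    kept_trials, n_disc = [], {"length": 0, "duration": 0}
    by_scenario: dict[str, list] = {}
    for t in trials:
        if t.excluded or t.outcome != Outcome.REACHED_TARGET:
            continue
        by_scenario.setdefault(t.scenario_id, []).append(t)
    scen_by_id = {s.config_id: s for s in scenarios}
    binned_trials = []
    for sid, ts in by_scenario.items():
        kept, discarded = filter_trials(
            [t.trajectory for t in ts],
            max_duration=pp.max_duration,
            length_factor=pp.length_factor,
        )
        for _, reason in discarded:
            n_disc[reason] += 1
        kept_set = {id(k) for k in kept}
        for t in ts:
            if id(t.trajectory) not in kept_set:
                continue
            b = bin_by_y(
                t.trajectory,
                y_min=pp.y_min,
                y_max=pp.y_max,
                bin_width=pp.bin_width,
                source_id=f"{t.agent_id}_{sid}_r{t.rep}",
            )
            binned_trials.append(
                _metrics.BinnedTrial(
                    binned=b,
                    agent_id=t.agent_id,
                    group=t.profile_label,
                    scenario_id=sid,
                    route_type=scen_by_id[sid].route_type,
                )
            )
            kept_trials.append(t)
    wide = pd.DataFrame(
        {bt.binned.source_id: bt.binned.x_values for bt in binned_trials},
        index=binned_trials[0].binned.y_grid if binned_trials else None,
    )
    wide.to_csv(out / "binned.csv", index_label="y_center")
    log.info(
        "stage preprocess: kept %d, discarded %s", len(binned_trials), n_disc
    )
    manifest["stages"]["preprocess"] = {
        "n_kept": len(binned_trials),
        "n_discarded_per_rule": n_disc,
    }

    # --- metrics ----------------------------------------------------------
    records, aggregates = _metrics.aggregate_distances(binned_trials)
    records.to_csv(out / "distance_records.csv", index=False)
    aggregates.to_csv(out / "distance_aggregates.csv", index=False)
    containment_rows, route_rows = [], []
    groups = sorted({bt.group for bt in binned_trials})
    for sid in sorted(by_scenario):
        sub = [bt for bt in binned_trials if bt.scenario_id == sid]
        if len(groups) == 2:
            ref_group, band_group = groups[0], groups[1]
            band_members = [bt.binned for bt in sub if bt.group == band_group]
            ref_members = [bt.binned for bt in sub if bt.group == ref_group]
            if len(band_members) >= 2 and ref_members:
                band = _metrics.ci_band(band_members, level=config.ci_level)
                ref_mean = _metrics.group_mean(ref_members)
                containment_rows.append(
                    {
                        "scenario_id": sid,
                        "reference_group": ref_group,
                        "band_group": band_group,
                        "containment": _metrics.ci_containment(ref_mean, band),
                    }
                )
        for group in groups:
            sigs = []
            for t in kept_trials:
                if t.scenario_id != sid or t.profile_label != group:
                    continue
                try:
                    sigs.append(
                        _metrics.route_signature(t.trajectory, scen_by_id[sid])
                    )
                except ValueError:
                    continue
            if sigs:
                for sig_key, share in _metrics.preferred_routes(
                    sigs, threshold=config.route_threshold
                ):
                    route_rows.append(
                        {
                            "scenario_id": sid,
                            "group": group,
                            "signature": "|".join(sig_key),
                            "share": share,
                        }
                    )
    pd.DataFrame(containment_rows).to_csv(out / "ci_containment.csv", index=False)
    pd.DataFrame(route_rows).to_csv(out / "preferred_routes.csv", index=False)
    log.info(
        "stage metrics: %d pair records, %d containment rows",
        len(records),
        len(containment_rows),
    )
    manifest["stages"]["metrics"] = {
        "n_pair_records": int(len(records)),
        "n_containment": len(containment_rows),
        "n_preferred_routes": len(route_rows),
    }

    # --- fitting ----------------------------------------------------------
    fit_rows = []
    fc = config.fitting
    fixed = DPMPParams(**{**{}, **config.constants})
    for group in groups:
        candidates = [t for t in kept_trials if t.profile_label == group]
        for t in candidates[: fc.n_fit_trials_per_group]:
            fit = fit_trajectory(
                t.trajectory,
                scen_by_id[t.scenario_id],
                bounds=fc.bounds,
                fixed=fixed,
                seed=config.seed,
                trajectory_id=f"{t.agent_id}_{t.scenario_id}_r{t.rep}",
                maxiter=fc.maxiter,
                popsize=fc.popsize,
                tol=fc.tol,
            )
            fit_rows.append(
                {
                    "trajectory_id": fit.trajectory_id,
                    "agent_id": t.agent_id,
                    "group": group,
                    "route_type": t.route_type,
                    "beta": fit.beta,
                    "gamma": fit.gamma,
                    "epsilon": fit.epsilon,
                    "dtw_error": fit.dtw_error,
                    "converged": fit.converged,
                }
            )
    fits_df = pd.DataFrame(fit_rows)
    fits_df.to_csv(out / "fits.csv", index=False)
    log.info("stage fit: %d fits", len(fit_rows))
    manifest["stages"]["fit"] = {"n_fits": len(fit_rows)}

    # --- summary ----------------------------------------------------------
    source = fits_df if len(fits_df) else trial_df.rename(columns={"profile": "group"})
    summary = summarize_params(source)
    summary.to_csv(out / "param_summary.csv", index=False)
    manifest["stages"]["summary"] = {"n_rows": len(summary)}

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.csv"))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
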