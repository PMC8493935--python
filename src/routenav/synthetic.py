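"""Synthetic obstacle configurations and trajectory populations.

Generates the statistical structure the analysis pipeline assumes: random
obstacle configurations (uniform rejection sampling with clearance
constraints), agents whose characteristic (beta, gamma, epsilon) are drawn
log-normally around a profile mean, and full trial tables (agent x scenario
x repetition) simulated either with the continuous steering dynamics or by
driving the game environment with the discretized scripted policy (keyboard
control) plus heading-rate noise. The shipped ``human_like`` profile has
larger between-agent and trial-to-trial parameter spread than ``drl_like``,
emulating the qualitative variability contrast between human players and
converged reinforcement-learning agents; the parameter means themselves are
generator knobs, not empirical estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dpmp import DPMPParams, Outcome, Trajectory, simulate
from .nav_env import KinematicsSpec, run_episode, scripted_dpmp_policy
from .scenario import (
    PAPER_STARTS,
    PAPER_TARGETS,
    FieldSpec,
    Obstacle,
    Scenario,
    enumerate_scenarios,
)

__all__ = [
    "PopulationProfile",
    "SyntheticAgent",
    "Trial",
    "default_profiles",
    "random_obstacle_config",
    "navigable_obstacle_configs",
    "DEFAULT_PARAM_MEANS",
    "sample_agent",
    "generate_dataset",
    "trials_to_dataframe",
]

#: Default characteristic-parameter means for generated populations. The
#: constants-file magnitudes describe walking-speed locomotion; at the game's
#: 10 m/s forward speed their goal attraction is too soft to capture the
#: 0.25 m target, so the generator defaults are rate-scaled values that
#: complete the task while lying inside the default fitting bounds.
DEFAULT_PARAM_MEANS: tuple[float, float, float] = (10.0, 100.0, 500.0)


@dataclass(frozen=True)
class PopulationProfile:
    """Statistical description of one trajectory population.

    ``param_means`` centers the log-normal distributions of the agents'
    characteristic (beta, gamma, epsilon); ``between_agent_cv`` and
    ``within_agent_cv`` are per-parameter coefficients of variation for the
    agent-level draw and the trial-to-trial jitter. ``control`` selects the
    continuous dynamics or keyboard-style discretization through the game
    environment, with Gaussian heading-rate noise of sd ``heading_noise_sd``
    (rad/s) applied at each keyboard decision.
    """

    label: str
    param_means: tuple[float, float, float] = DEFAULT_PARAM_MEANS
    between_agent_cv: tuple[float, float, float] = (0.3, 0.3, 0.3)
    within_agent_cv: tuple[float, float, float] = (0.15, 0.15, 0.15)
    control: str = "continuous"
    heading_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.control not in ("continuous", "keyboard"):
            raise ValueError(f"unknown control mode {self.control!r}")
        if any(c < 0 for c in self.between_agent_cv + self.within_agent_cv):
            raise ValueError("coefficients of variation must be non-negative")
        if self.heading_noise_sd < 0:
            raise ValueError("heading_noise_sd must be non-negative")


def default_profiles() -> tuple[PopulationProfile, PopulationProfile]:
    """The shipped human-like and DRL-like population profiles."""
    return (
        PopulationProfile(
            label="human_like",
            between_agent_cv=(0.3, 0.3, 0.3),
            within_agent_cv=(0.15, 0.15, 0.15),
            control="keyboard",
            heading_noise_sd=0.1,
        ),
        PopulationProfile(
            label="drl_like",
            between_agent_cv=(0.05, 0.05, 0.05),
            within_agent_cv=(0.02, 0.02, 0.02),
            control="keyboard",
            heading_noise_sd=0.02,
        ),
    )


@dataclass(frozen=True)
class SyntheticAgent:
    agent_id: str
    profile: PopulationProfile
    beta: float
    gamma: float
    epsilon: float


@dataclass
class Trial:
    agent_id: str
    profile_label: str
    scenario_id: str
    route_type: str
    rep: int
    params: DPMPParams
    trajectory: Trajectory | None
    outcome: Outcome | None
    n_retries: int
    excluded: bool = False


def random_obstacle_config(
    n_obstacles: int,
    field_spec: FieldSpec | None = None,
    min_clearance: float = 2.0,
    seed: int | np.random.Generator = 0,
    radius: float = 0.25,
    keep_clear: tuple[tuple[float, float], ...] = PAPER_STARTS + PAPER_TARGETS,
    max_rejections: int = 10_000,
) -> list[Obstacle]:
    """Uniform rejection sampling of obstacle positions.

    Obstacles keep ``min_clearance`` (center distance) from the walls, every
    point in ``keep_clear`` (starts and targets by default), and each other.
    Deterministic given the seed; raises if the packing is infeasible within
    ``max_rejections`` draws.
    """
    if n_obstacles < 0:
        raise ValueError("n_obstacles must be non-negative")
    field_spec = field_spec or FieldSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lim = field_spec.half_extent - min_clearance
    placed: list[Obstacle] = []
    rejections = 0
    while len(placed) < n_obstacles:
        x, y = rng.uniform(-lim, lim, size=2)
        ok = all(math.hypot(x - p[0], y - p[1]) >= min_clearance for p in keep_clear)
        ok = ok and all(
            math.hypot(x - ob.x, y - ob.y) >= min_clearance for ob in placed
        )
        if ok:
            placed.append(Obstacle(float(x), float(y), radius))
        else:
            rejections += 1
            if rejections > max_rejections:
                raise RuntimeError(
                    f"could not place {n_obstacles} obstacles with clearance "
                    f"{min_clearance} m after {max_rejections} rejections"
                )
    return placed


def navigable_obstacle_configs(
    n_configs: int,
    n_obstacles: int = 9,
    seed: int | np.random.Generator = 0,
    min_clearance: float = 2.0,
    params: DPMPParams | None = None,
    max_attempts_per_config: int = 50,
) -> list[list[Obstacle]]:
    """Random obstacle configurations that the steering dynamics can solve.

    Samples configurations with :func:`random_obstacle_config` and keeps one
    only if a continuous-control agent at the profile-mean parameters reaches
    the target in all six canonical start x target scenarios. This emulates
    the study design, where every configuration was completable by every
    player (the game required successful trials), and screens out
    pathological head-on placements for which the repulsion term vanishes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = params or DPMPParams().with_free(*DEFAULT_PARAM_MEANS)
    configs: list[list[Obstacle]] = []
    while len(configs) < n_configs:
        for attempt in range(max_attempts_per_config):
            cfg = random_obstacle_config(
                n_obstacles, min_clearance=min_clearance, seed=rng
            )
            scens = enumerate_scenarios([cfg], PAPER_STARTS, PAPER_TARGETS)
            if all(
                simulate(s, params).outcome == Outcome.REACHED_TARGET for s in scens
            ):
                configs.append(cfg)
                break
        else:
            raise RuntimeError(
                f"no navigable configuration found in {max_attempts_per_config} attempts"
            )
    return configs


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Log-normal draw with the given mean and coefficient of variation."""
    if cv == 0:
        return mean
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def sample_agent(
    profile: PopulationProfile, seed: int | np.random.Generator, agent_id: str = "agent"
) -> SyntheticAgent:
    """Draw one agent's characteristic parameters from the profile."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b, g, e = (
        _lognormal(rng, m, cv)
        for m, cv in zip(profile.param_means, profile.between_agent_cv)
    )
    return SyntheticAgent(
        agent_id=agent_id, profile=profile, beta=b, gamma=g, epsilon=e
    )


def _run_trial(
    agent: SyntheticAgent,
    scenario: Scenario,
    params: DPMPParams,
    rng: np.random.Generator,
) -> tuple[Trajectory, Outcome]:
    profile = agent.profile
    if profile.control == "continuous":
        traj = simulate(scenario, params, mode="continuous")
        return traj, traj.outcome
    policy = scripted_dpmp_policy(
        params, heading_noise_sd=profile.heading_noise_sd, rng=rng
    )
    result = run_episode(policy, scenario, KinematicsSpec())
    return result.trajectory, result.outcome


def generate_dataset(
    profiles: list[PopulationProfile] | None = None,
    n_agents_per_profile: int = 10,
    scenarios: list[Scenario] | None = None,
    reps: int = 6,
    seed: int = 0,
    max_retries: int = 10,
) -> list[Trial]:
    """Simulate a full trial table: agent x scenario x repetition.

    Each trial draws parameters around the agent's characteristic values
    (log-normal with the within-agent CV) and simulates under the profile's
    control mode. Trials that hit an obstacle are re-run with a fresh jitter
    draw, emulating the game's restart-on-collision rule, up to
    ``max_retries``; a trial that exhausts its retries is flagged excluded
    (never silently dropped). Fully reproducible given ``seed``.
    """
    if profiles is None:
        profiles = list(default_profiles())
    if scenarios is None:
        configs = navigable_obstacle_configs(
            3, seed=np.random.default_rng(seed + 1_000_000)
        )
        scenarios = enumerate_scenarios(configs, PAPER_STARTS, PAPER_TARGETS)
    if not scenarios:
        raise ValueError("scenarios must be non-empty")
    root = np.random.SeedSequence(seed)
    trials: list[Trial] = []
    for pi, profile in enumerate(profiles):
        for ai in range(n_agents_per_profile):
            agent_ss = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(pi, ai)
            )
            agent_rng = np.random.default_rng(agent_ss)
            agent = sample_agent(
                profile, agent_rng, agent_id=f"{profile.label}_{ai:02d}"
            )
            for scenario in scenarios:
                for rep in range(reps):
                    traj, outcome, retries = None, None, 0
                    params = None
                    while retries <= max_retries:
                        params = DPMPParams(
                            beta=_lognormal(
                                agent_rng, agent.beta, profile.within_agent_cv[0]
                            ),
                            gamma=_lognormal(
                                agent_rng, agent.gamma, profile.within_agent_cv[1]
                            ),
                            epsilon=_lognormal(
                                agent_rng, agent.epsilon, profile.within_agent_cv[2]
                            ),
                        )
                        traj, outcome = _run_trial(agent, scenario, params, agent_rng)
                        if outcome != Outcome.HIT_OBSTACLE:
                            break
                        retries += 1
                        # deterministic control cannot change on retry: give up
                        if (
                            profile.control == "continuous"
                            and max(profile.within_agent_cv) == 0
                        ):
                            break
                    excluded = outcome == Outcome.HIT_OBSTACLE
                    trials.append(
                        Trial(
                            agent_id=agent.agent_id,
                            profile_label=profile.label,
                            scenario_id=scenario.config_id,
                            route_type=scenario.route_type.value,
                            rep=rep,
                            params=params,
                            trajectory=traj,
                            outcome=outcome,
                            n_retries=retries,
                            excluded=excluded,
                        )
                    )
    return trials


def trials_to_dataframe(trials: list[Trial]) -> pd.DataFrame:
    """Tidy summary table of a generated dataset (one row per trial)."""
    return pd.DataFrame(
        [
            {
                "agent_id": t.agent_id,
                "profile": t.profile_label,
                "scenario_id": t.scenario_id,
                "route_type": t.route_type,
                "rep": t.rep,
                "beta": t.params.beta if t.params else math.nan,
                "gamma": t.params.gamma if t.params else math.nan,
                "epsilon": t.params.epsilon if t.params else math.nan,
                "outcome": t.outcome.value if t.outcome else "",
                "n_retries": t.n_retries,
                "excluded": t.excluded,
                "duration": t.trajectory.duration if t.trajectory else math.nan,
                "path_length": t.trajectory.path_length() if t.trajectory else math.nan,
            }
            for t in trials
        ]
    )
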