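"""Steppable navigation game: discrete actions, capped turning kinematics,

raycast observations, rewards, and episode logic.

The environment reproduces the route-selection game: an agent moving at a
fixed forward speed (10 m/s) with rate- and acceleration-capped turning
(25 deg/s, 62.5 deg/s^2), updated at 50 Hz, observed through 11 rays spanning
+-45 degrees that each report the class of the nearest object they hit
(target / obstacle / other / nothing) plus the egocentric target bearing and
distance (46 inputs total). Actions are a one-hot pair: move {forward, none}
and rotate {left, none, right} (5 outputs). An episode ends on target capture
(+1 reward), obstacle collision (-1), or a 30 s timeout (-1).

The ``reset``/``step`` surface follows the conventional RL API
(observation, reward, terminated, truncated, info) so external toolkits can
wrap it; this package drives it with a scripted steering-dynamics policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .dpmp import (
    AgentState,
    DPMPParams,
    Outcome,
    Trajectory,
    wrap_angle,
)
from .scenario import FieldSpec, Scenario

__all__ = [
    "KinematicsSpec",
    "RaySpec",
    "Action",
    "Observation",
    "EpisodeResult",
    "RAY_CLASSES",
    "cast_rays",
    "encode_observation",
    "step",
    "run_episode",
    "scripted_dpmp_policy",
    "curriculum_placement",
    "NavEnv",
]

#: Ray one-hot class order.
RAY_CLASSES = ("target", "obstacle", "other", "nothing")


@dataclass(frozen=True)
class KinematicsSpec:
    """Movement caps and timing of the game."""

    forward_speed: float = 10.0  # m/s
    max_turn_rate: float = 25.0  # deg/s
    turn_accel: float = 62.5  # deg/s^2
    frame_rate: float = 50.0  # Hz
    decision_interval: int = 5  # frames between policy queries

    def __post_init__(self) -> None:
        if min(self.forward_speed, self.max_turn_rate, self.turn_accel,
               self.frame_rate) <= 0:
            raise ValueError("kinematics values must be positive")
        if self.decision_interval < 1 or int(self.decision_interval) != self.decision_interval:
            raise ValueError("decision_interval must be an integer >= 1")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def max_turn_rate_rad(self) -> float:
        return math.radians(self.max_turn_rate)

    @property
    def turn_accel_rad(self) -> float:
        return math.radians(self.turn_accel)


@dataclass(frozen=True)
class RaySpec:
    """Geometry of the raycast fan: 11 rays over +-45 degrees by default."""

    n_side: int = 5  # rays per side, plus one straight ahead
    half_fan_deg: float = 45.0
    max_length: float | None = None  # default: field diagonal

    @property
    def angles_rad(self) -> np.ndarray:
        """Egocentric ray angles, ascending from -45 to +45 degrees."""
        step_deg = self.half_fan_deg / self.n_side
        k = np.arange(-self.n_side, self.n_side + 1)
        return np.radians(k * step_deg)

    @property
    def n_rays(self) -> int:
        return 2 * self.n_side + 1


@dataclass(frozen=True)
class Action:
    """One-hot move {forward, none} and rotate {left, none, right}."""

    move: str = "forward"
    rotate: str = "none"

    def __post_init__(self) -> None:
        if self.move not in ("forward", "none"):
            raise ValueError(f"invalid move action {self.move!r}")
        if self.rotate not in ("left", "none", "right"):
            raise ValueError(f"invalid rotate action {self.rotate!r}")

    def to_vector(self) -> np.ndarray:
        """5-dimensional one-hot encoding (2 move + 3 rotate)."""
        v = np.zeros(5)
        v[0 if self.move == "forward" else 1] = 1.0
        v[2 + ("left", "none", "right").index(self.rotate)] = 1.0
        return v

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "Action":
        v = np.asarray(v)
        if v.shape != (5,) or not np.isclose(v[:2].sum(), 1) or not np.isclose(
            v[2:].sum(), 1
        ):
            raise ValueError("action vector must be two concatenated one-hots (5 values)")
        return cls(
            move=("forward", "none")[int(np.argmax(v[:2]))],
            rotate=("left", "none", "right")[int(np.argmax(v[2:]))],
        )


@dataclass(frozen=True)
class Observation:
    """Raycast block (44 values) + target bearing (rad) + distance (m)."""

    ray_block: np.ndarray
    target_heading: float
    target_distance: float

    def to_vector(self) -> np.ndarray:
        """Flat 46-vector: 44 ray values, bearing, distance."""
        return np.concatenate(
            [self.ray_block, [self.target_heading, self.target_distance]]
        )


@dataclass
class EpisodeResult:
    trajectory: Trajectory
    reward: float
    outcome: Outcome


def _ray_circle_distance(
    px: float, py: float, dx: float, dy: float, cx: float, cy: float, r: float
) -> float:
    """Distance along ray (p, d) to the first intersection with the circle

    (c, r), or inf if it misses. ``d`` must be a unit vector.
    """
    fx, fy = px - cx, py - cy
    b = 2.0 * (fx * dx + fy * dy)
    c = fx * fx + fy * fy - r * r
    disc = b * b - 4.0 * c
    if disc < 0:
        return math.inf
    sq = math.sqrt(disc)
    t1 = (-b - sq) / 2.0
    if t1 >= 0:
        return t1
    t2 = (-b + sq) / 2.0
    return t2 if t2 >= 0 else math.inf


def _ray_wall_distance(
    px: float, py: float, dx: float, dy: float, half: float
) -> float:
    """Distance along the ray to the square boundary at +-half, or inf."""
    best = math.inf
    for d, p, lim in ((dx, px, half), (dx, px, -half), (dy, py, half), (dy, py, -half)):
        if d == 0.0:
            continue
        t = (lim - p) / d
        if t >= 0:
            # intersection point must be within the wall segment
            ox = px + t * dx
            oy = py + t * dy
            if abs(ox) <= half + 1e-9 and abs(oy) <= half + 1e-9:
                best = min(best, t)
    return best


def cast_rays(
    state: AgentState, scenario: Scenario, spec: RaySpec | None = None
) -> np.ndarray:
    """Classify the nearest object hit by each of the 11 rays.

    Returns a flat array of ``n_rays`` one-hot blocks of size 4 (44 values by
    default), ordered from the most clockwise (-45 deg) to the most
    counterclockwise (+45 deg) ray; class order is
    ``(target, obstacle, other, nothing)``. Walls are the only "other" object.
    """
    spec = spec or RaySpec()
    half = scenario.field.half_extent
    max_len = spec.max_length if spec.max_length is not None else 2.0 * half * math.sqrt(2)
    blocks = np.zeros((spec.n_rays, len(RAY_CLASSES)))
    for i, ang in enumerate(spec.angles_rad):
        a = state.phi + ang
        dx, dy = math.cos(a), math.sin(a)
        best_t, best_cls = math.inf, "nothing"
        t = _ray_circle_distance(
            state.x, state.y, dx, dy,
            scenario.target[0], scenario.target[1], scenario.target_radius,
        )
        if t < best_t:
            best_t, best_cls = t, "target"
        for ob in scenario.obstacles:
            t = _ray_circle_distance(state.x, state.y, dx, dy, ob.x, ob.y, ob.radius)
            if t < best_t:
                best_t, best_cls = t, "obstacle"
        if scenario.field.wall_present:
            t = _ray_wall_distance(state.x, state.y, dx, dy, half)
            if t < best_t:
                best_t, best_cls = t, "other"
        if best_t > max_len:
            best_cls = "nothing"
        blocks[i, RAY_CLASSES.index(best_cls)] = 1.0
    return blocks.ravel()


def encode_observation(
    state: AgentState, scenario: Scenario, spec: RaySpec | None = None
) -> Observation:
    """Full observation: ray block plus egocentric target bearing/distance."""
    ray_block = cast_rays(state, scenario, spec)
    dx = scenario.target[0] - state.x
    dy = scenario.target[1] - state.y
    heading = float(wrap_angle(math.atan2(dy, dx) - state.phi))
    return Observation(
        ray_block=ray_block,
        target_heading=heading,
        target_distance=math.hypot(dx, dy),
    )


def step(
    state: AgentState, action: Action, spec: KinematicsSpec, dt: float | None = None
) -> AgentState:
    """Advance the game kinematics one frame.

    The turning rate accelerates toward the commanded direction at
    ``turn_accel`` and is clamped to ``+-max_turn_rate``; with rotate=none it
    decays toward zero at the same rate. The heading then integrates the new
    turning rate, and the position advances ``forward_speed * dt`` along the
    heading iff move=forward. No backward motion exists.
    """
    dt = spec.dt if dt is None else dt
    a = spec.turn_accel_rad
    cap = spec.max_turn_rate_rad
    w = state.phi_dot
    if action.rotate == "left":
        w = min(cap, w + a * dt)
    elif action.rotate == "right":
        w = max(-cap, w - a * dt)
    else:  # decay toward zero without overshoot
        if w > 0:
            w = max(0.0, w - a * dt)
        elif w < 0:
            w = min(0.0, w + a * dt)
    phi = float(wrap_angle(state.phi + w * dt))
    x, y = state.x, state.y
    if action.move == "forward":
        x += spec.forward_speed * math.cos(phi) * dt
        y += spec.forward_speed * math.sin(phi) * dt
    return AgentState(x=x, y=y, phi=phi, phi_dot=w, speed=spec.forward_speed)


Policy = Callable[[Observation, AgentState], Action]


def scripted_dpmp_policy(
    p: DPMPParams,
    threshold: float = math.radians(2.0),
    heading_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    stop_bearing: float = math.radians(35.0),
) -> Policy:
    """Discretize the steering dynamics into the game's action space.

    At each decision the policy computes the heading acceleration from the
    full state (goal and obstacle bearings), integrates a desired turning
    rate over one decision interval, optionally perturbs it with Gaussian
    noise of sd ``heading_noise_sd`` (rad/s, emulating input granularity),
    and emits rotate=left/right when the desired rate exceeds ``threshold``
    in magnitude, else rotate=none. Movement is forward unless the goal
    bearing error exceeds ``stop_bearing``, in which case the policy stops
    and turns in place — the maneuver keyboard players use, since at full
    speed the capped turning radius is far too wide to recover from an
    overshoot.

    The scenario is read from ``state._scenario`` set by :func:`run_episode`
    / :class:`NavEnv`; the observation argument is accepted so that
    observation-only policies share the same signature.
    """
    rng = rng or np.random.default_rng()

    def policy(obs: Observation, state: AgentState) -> Action:
        scenario: Scenario = getattr(state, "_scenario")
        from .dpmp import egocentric_view, heading_acceleration, wrap_angle

        view = egocentric_view(state, scenario.target, scenario.obstacles)
        acc = heading_acceleration(state.phi, state.phi_dot, view, p)
        desired = state.phi_dot + acc * 0.1  # one decision interval ahead
        if heading_noise_sd > 0:
            desired += rng.normal(0.0, heading_noise_sd)
        if desired > threshold:
            rotate = "left"
        elif desired < -threshold:
            rotate = "right"
        else:
            rotate = "none"
        bearing_err = abs(float(wrap_angle(state.phi - view.theta_g)))
        move = "none" if bearing_err > stop_bearing else "forward"
        return Action(move=move, rotate=rotate)

    return policy


def run_episode(
    policy: Policy,
    scenario: Scenario,
    spec: KinematicsSpec | None = None,
    ray_spec: RaySpec | None = None,
    max_time: float = 30.0,
    start_phi: float = math.pi / 2,
    agent_radius: float = 0.25,
) -> EpisodeResult:
    """Run one episode under ``policy`` and record the full 50 Hz trajectory.

    The policy is queried every ``decision_interval`` frames with the current
    observation and state; its action is held between queries. Terminates on
    target capture (+1), obstacle collision (-1), or timeout (-1).
    """
    spec = spec or KinematicsSpec()
    env = NavEnv(scenario, spec=spec, ray_spec=ray_spec, max_time=max_time,
                 start_phi=start_phi, agent_radius=agent_radius)
    obs, _ = env.reset()
    action = policy(obs, env.state)
    terminated = truncated = False
    reward = 0.0
    while not (terminated or truncated):
        obs, reward, terminated, truncated, info = env.step(action)
        if not (terminated or truncated) and env.frame % spec.decision_interval == 0:
            action = policy(obs, env.state)
            if not isinstance(action, Action):
                raise TypeError("policy must return an Action")
    return EpisodeResult(
        trajectory=env.trajectory(), reward=reward, outcome=env.outcome
    )


def curriculum_placement(
    phase: str, rng_seed: int | np.random.Generator, field_spec: FieldSpec | None = None,
    margin: float = 1.0,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Start/target placement used across training phases.

    ``phase="early"``: both uniform random inside the field (``margin`` m from
    walls). ``phase="late"``: start x = -16 and target x = 16, y uniform
    random. Deterministic given the seed.
    """
    field_spec = field_spec or FieldSpec()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    lim = field_spec.half_extent - margin
    if phase == "early":
        start = tuple(rng.uniform(-lim, lim, size=2))
        target = tuple(rng.uniform(-lim, lim, size=2))
    elif phase == "late":
        start = (-16.0, float(rng.uniform(-lim, lim)))
        target = (16.0, float(rng.uniform(-lim, lim)))
    else:
        raise ValueError(f"unknown curriculum phase {phase!r}")
    return start, target


class NavEnv:
    """Steppable environment with the conventional RL reset/step surface."""

    def __init__(
        self,
        scenario: Scenario,
        spec: KinematicsSpec | None = None,
        ray_spec: RaySpec | None = None,
        max_time: float = 30.0,
        start_phi: float = math.pi / 2,
        agent_radius: float = 0.25,
    ) -> None:
        self.scenario = scenario
        self.spec = spec or KinematicsSpec()
        self.ray_spec = ray_spec or RaySpec()
        self.max_time = max_time
        self.start_phi = start_phi
        self.agent_radius = agent_radius
        self.reset()

    def reset(self, scenario: Scenario | None = None):
        if scenario is not None:
            self.scenario = scenario
        self.state = AgentState(
            x=self.scenario.start[0], y=self.scenario.start[1],
            phi=self.start_phi, phi_dot=0.0, speed=self.spec.forward_speed,
        )
        self.state._scenario = self.scenario
        self.frame = 0
        self.outcome = Outcome.TIMED_OUT
        self._ts = [0.0]
        self._xs = [self.state.x]
        self._ys = [self.state.y]
        self._phis = [self.state.phi]
        obs = encode_observation(self.state, self.scenario, self.ray_spec)
        return obs, {}

    def step(self, action: Action):
        if not isinstance(action, Action):
            raise TypeError("step expects an Action")
        dt = self.spec.dt
        self.state = step(self.state, action, self.spec)
        self.state._scenario = self.scenario
        self.frame += 1
        self._ts.append(self.frame * dt)
        self._xs.append(self.state.x)
        self._ys.append(self.state.y)
        self._phis.append(self.state.phi)
        terminated = truncated = False
        reward = 0.0
        tx, ty = self.scenario.target
        if (
            math.hypot(tx - self.state.x, ty - self.state.y)
            < self.scenario.target_radius + self.agent_radius
        ):
            self.outcome = Outcome.REACHED_TARGET
            reward, terminated = 1.0, True
        else:
            for ob in self.scenario.obstacles:
                if (
                    math.hypot(ob.x - self.state.x, ob.y - self.state.y)
                    < ob.radius + self.agent_radius
                ):
                    self.outcome = Outcome.HIT_OBSTACLE
                    reward, terminated = -1.0, True
                    break
        if not terminated and self.frame >= round(self.max_time * self.spec.frame_rate):
            self.outcome = Outcome.TIMED_OUT
            reward, truncated = -1.0, True
        obs = encode_observation(self.state, self.scenario, self.ray_spec)
        return obs, reward, terminated, truncated, {"outcome": self.outcome}

    def trajectory(self) -> Trajectory:
        return Trajectory(
            t=np.array(self._ts), x=np.array(self._xs), y=np.array(self._ys),
            phi=np.array(self._phis), dt=self.spec.dt, outcome=self.outcome,
        )
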