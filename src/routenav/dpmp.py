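"""Heading dynamics for goal-directed steering with obstacle avoidance.

The model treats the agent's heading direction phi as a damped mass-spring
system: a point attractor at the goal bearing and a repeller at each obstacle
bearing,

    phi'' = -beta*phi' - gamma*(phi - theta_g)*(exp(-c1*d_g) + c2)
            + sum_i epsilon*(phi - theta_Oi)*exp(-c3*|phi - theta_Oi|)
                          * exp(-c4*d_Oi)

with the agent translating at constant forward speed along its heading. All
angles are radians, world frame, counterclockwise from +x; every angle
difference is wrapped to (-pi, pi] before use. beta damps turning, gamma sets
the stiffness of the goal attraction (whose distance factor decays at rate c1
but never below the floor c2), and epsilon scales obstacle repulsion, which
decays with bearing difference at rate c3 and with distance at rate c4.

Routes emerge online from the interplay of attractor and repellers; nothing
is planned ahead of time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .scenario import Obstacle, Scenario

__all__ = [
    "DPMPParams",
    "AgentState",
    "EgocentricView",
    "Trajectory",
    "Outcome",
    "wrap_angle",
    "egocentric_view",
    "heading_acceleration",
    "simulate",
    "load_model_constants",
]


def load_model_constants() -> dict[str, float]:
    """Load the shipped model-constant configuration (c1..c4 and default

    beta/gamma/epsilon magnitudes). These are configuration values in the
    original route-selection formulation's units (radians, meters), not
    empirical estimates of this package.
    """
    text = resources.files("routenav.data").joinpath("fw_constants.json").read_text()
    d = json.loads(text)
    return {k: float(v) for k, v in d.items() if k != "comment"}


_FW = load_model_constants()


@dataclass(frozen=True)
class DPMPParams:
    """Model constants of the heading-dynamics equation.

    beta (1/s) damps the turning rate; gamma (1/s^2) is the goal-attraction
    stiffness; epsilon (1/s^2) the obstacle-repulsion strength. c1 (1/m) sets
    the decay of goal attraction with distance, c2 (dimensionless) its floor,
    c3 (1/rad) the angular decay of repulsion, and c4 (1/m) its distance
    decay. Defaults come from the shipped constants file.
    """

    beta: float = _FW["beta"]
    gamma: float = _FW["gamma"]
    epsilon: float = _FW["epsilon"]
    c1: float = _FW["c1"]
    c2: float = _FW["c2"]
    c3: float = _FW["c3"]
    c4: float = _FW["c4"]

    def __post_init__(self) -> None:
        for name in ("beta", "gamma", "epsilon", "c1", "c2", "c3", "c4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_free(self, beta: float, gamma: float, epsilon: float) -> "DPMPParams":
        """Copy with new free parameters, keeping the fixed constants."""
        return replace(self, beta=beta, gamma=gamma, epsilon=epsilon)


def wrap_angle(a):
    """Wrap angle(s) to the half-open interval (-pi, pi]."""
    return -(np.remainder(-np.asarray(a) + math.pi, 2.0 * math.pi) - math.pi)


@dataclass
class AgentState:
    """Planar pose plus heading dynamics: position, heading phi (rad,

    wrapped to (-pi, pi]), turning rate phi_dot (rad/s), forward speed (m/s).
    """

    x: float
    y: float
    phi: float
    phi_dot: float = 0.0
    speed: float = 10.0

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        self.phi = float(wrap_angle(self.phi))

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class EgocentricView:
    """World-frame bearings and distances to the goal and each obstacle."""

    theta_g: float
    d_g: float
    theta_o: np.ndarray  # shape (n_obstacles,)
    d_o: np.ndarray  # shape (n_obstacles,)


class Outcome(str, Enum):
    REACHED_TARGET = "reached_target"
    HIT_OBSTACLE = "hit_obstacle"
    TIMED_OUT = "timed_out"


@dataclass
class Trajectory:
    """Uniformly sampled path: time, position, and heading arrays."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phi: np.ndarray
    dt: float
    outcome: Outcome = Outcome.TIMED_OUT

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.phi) == n):
            raise ValueError("t, x, y, phi must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    @property
    def points(self) -> np.ndarray:
        """(n, 2) array of xy positions."""
        return np.column_stack([self.x, self.y])

    def path_length(self) -> float:
        """Cumulative Euclidean arc length in meters."""
        return float(np.sum(np.hypot(np.diff(self.x), np.diff(self.y))))

    def mirrored_x(self) -> "Trajectory":
        """Reflection about the y-axis (x -> -x, phi -> pi - phi)."""
        return Trajectory(
            t=self.t.copy(),
            x=-self.x,
            y=self.y.copy(),
            phi=wrap_angle(math.pi - self.phi),
            dt=self.dt,
            outcome=self.outcome,
        )

    # ---- CSV + sidecar I/O ----------------------------------------------

    def to_csv(self, path: str | Path, metadata: dict | None = None) -> None:
        """Write ``t,x,y,phi`` rows; metadata goes to a ``.json`` sidecar."""
        path = Path(path)
        arr = np.column_stack([self.t, self.x, self.y, self.phi])
        header = "t,x,y,phi"
        np.savetxt(path, arr, delimiter=",", header=header, comments="")
        side = {"dt": self.dt, "outcome": self.outcome.value}
        if metadata:
            side.update(metadata)
        path.with_suffix(".json").write_text(json.dumps(side, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        side_path = path.with_suffix(".json")
        dt = float(np.median(np.diff(arr[:, 0]))) if len(arr) > 1 else 0.0
        outcome = Outcome.TIMED_OUT
        if side_path.exists():
            side = json.loads(side_path.read_text())
            dt = side.get("dt", dt)
            outcome = Outcome(side.get("outcome", outcome.value))
        return cls(
            t=arr[:, 0], x=arr[:, 1], y=arr[:, 2], phi=arr[:, 3], dt=dt,
            outcome=outcome,
        )


def egocentric_view(
    state: AgentState,
    target: tuple[float, float],
    obstacles: Sequence[Obstacle],
) -> EgocentricView:
    """Bearings and distances from the agent to the target and obstacles.

    Raises ``ValueError`` if the agent coincides with the target or an
    obstacle center (bearing undefined).
    """
    dx, dy = target[0] - state.x, target[1] - state.y
    d_g = math.hypot(dx, dy)
    if d_g == 0.0:
        raise ValueError("agent position coincides with the target")
    theta_g = math.atan2(dy, dx)
    if obstacles:
        ox = np.array([ob.x for ob in obstacles]) - state.x
        oy = np.array([ob.y for ob in obstacles]) - state.y
        d_o = np.hypot(ox, oy)
        if np.any(d_o == 0.0):
            raise ValueError("agent position coincides with an obstacle center")
        theta_o = np.arctan2(oy, ox)
    else:
        d_o = np.empty(0)
        theta_o = np.empty(0)
    return EgocentricView(theta_g=theta_g, d_g=d_g, theta_o=theta_o, d_o=d_o)


def heading_acceleration(
    phi: float, phi_dot: float, view: EgocentricView, p: DPMPParams
) -> float:
    """Angular acceleration of the heading under the steering dynamics.

    Every bearing difference phi - theta is wrapped to (-pi, pi] before
    entering the stiffness and exponential terms.
    """
    dg = float(wrap_angle(phi - view.theta_g))
    acc = -p.beta * phi_dot - p.gamma * dg * (math.exp(-p.c1 * view.d_g) + p.c2)
    if len(view.d_o):
        do = wrap_angle(phi - view.theta_o)
        acc += float(
            np.sum(
                p.epsilon
                * do
                * np.exp(-p.c3 * np.abs(do))
                * np.exp(-p.c4 * view.d_o)
            )
        )
    return acc


def simulate(
    scenario: Scenario,
    p: DPMPParams,
    start_phi: float = math.pi / 2,
    speed: float = 10.0,
    dt: float = 0.02,
    t_max: float = 20.0,
    mode: str = "continuous",
    agent_radius: float = 0.25,
    max_turn_rate: float = math.radians(25.0),
    turn_accel: float = math.radians(62.5),
) -> Trajectory:
    """Integrate the steering dynamics into a full planar trajectory.

    Explicit Euler at step ``dt`` (default 0.02 s, the game's 50 Hz). In
    ``mode="game"`` the turning rate and angular acceleration are clamped to
    the game kinematics caps; ``mode="continuous"`` integrates the raw
    dynamics. The run terminates when the agent disc (radius ``agent_radius``)
    touches the target (``reached_target``), touches an obstacle
    (``hit_obstacle``), or ``t_max`` elapses (``timed_out``). Fully
    deterministic.

    Raises
    ------
    FloatingPointError
        If the state becomes non-finite (parameter blow-up), naming the step.
    """
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be positive")
    if mode not in ("continuous", "game"):
        raise ValueError(f"unknown mode {mode!r}")
    game = mode == "game"
    tx, ty = scenario.target
    capture = scenario.target_radius + agent_radius
    obs = scenario.obstacles
    n_obs = len(obs)
    ox = np.array([ob.x for ob in obs])
    oy = np.array([ob.y for ob in obs])
    hit_r = np.array([ob.radius for ob in obs]) + agent_radius

    n_steps = int(round(t_max / dt))
    x, y = float(scenario.start[0]), float(scenario.start[1])
    phi = float(wrap_angle(start_phi))
    phi_dot = 0.0
    ts, xs, ys, phis = [0.0], [x], [y], [phi]
    outcome = Outcome.TIMED_OUT

    for k in range(n_steps):
        dgx, dgy = tx - x, ty - y
        d_g = math.hypot(dgx, dgy)
        theta_g = math.atan2(dgy, dgx)
        wg = float(wrap_angle(phi - theta_g))
        acc = -p.beta * phi_dot - p.gamma * wg * (math.exp(-p.c1 * d_g) + p.c2)
        if n_obs:
            do = wrap_angle(phi - np.arctan2(oy - y, ox - x))
            d_o = np.hypot(ox - x, oy - y)
            acc += float(
                np.sum(
                    p.epsilon * do * np.exp(-p.c3 * np.abs(do)) * np.exp(-p.c4 * d_o)
                )
            )
        if game:
            acc = max(-turn_accel, min(turn_accel, acc))
        new_phi_dot = phi_dot + acc * dt
        if game:
            new_phi_dot = max(-max_turn_rate, min(max_turn_rate, new_phi_dot))
        new_phi = float(wrap_angle(phi + phi_dot * dt))
        x += speed * math.cos(phi) * dt
        y += speed * math.sin(phi) * dt
        phi, phi_dot = new_phi, new_phi_dot
        if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(phi_dot)):
            raise FloatingPointError(
                f"non-finite state at step {k + 1} (parameter blow-up)"
            )
        ts.append((k + 1) * dt)
        xs.append(x)
        ys.append(y)
        phis.append(phi)
        if math.hypot(tx - x, ty - y) < capture:
            outcome = Outcome.REACHED_TARGET
            break
        if n_obs and bool(np.any(np.hypot(ox - x, oy - y) < hit_r)):
            outcome = Outcome.HIT_OBSTACLE
            break

    return Trajectory(
        t=np.array(ts), x=np.array(xs), y=np.array(ys), phi=np.array(phis),
        dt=dt, outcome=outcome,
    )
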