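"""Model fitting: differential evolution over (beta, gamma, epsilon)

minimizing the dynamic time warping (DTW) distance between an observed
trajectory and the trajectory the steering dynamics simulate in the same
scenario. The fixed constants c1..c4 are never fitted. Per-agent
*characteristic parameters* are the means of that agent's fitted values, and
a recovery study validates the whole loop on synthetic trajectories with
known generating parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import differential_evolution
from scipy.spatial.distance import cdist

from .dpmp import DPMPParams, Trajectory, simulate
from .scenario import Obstacle, Scenario

__all__ = [
    "FitResult",
    "CharacteristicParams",
    "DEFAULT_BOUNDS",
    "DEFAULT_RECOVERY_GRID",
    "dtw_distance",
    "fit_trajectory",
    "characteristic_params",
    "simulate_characteristic",
    "recovery_study",
    "default_recovery_scenario",
]

#: Default search brackets for the free parameters, wide around the original
#: formulation's magnitudes. All configurable.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "beta": (0.1, 20.0),
    "gamma": (0.5, 400.0),
    "epsilon": (1.0, 1000.0),
}

#: In-bounds parameter points for the default recovery study, spanning the
#: soft-to-stiff range over which the default scenario is completable.
DEFAULT_RECOVERY_GRID: tuple[tuple[float, float, float], ...] = (
    (6.0, 60.0, 300.0),
    (6.0, 80.0, 250.0),
    (10.0, 100.0, 500.0),
    (13.0, 150.0, 600.0),
    (16.0, 200.0, 800.0),
)

_PENALTY = 1e9  # finite cost for candidates whose simulation blows up


@njit(cache=True)
def _dtw_accumulate(cost: np.ndarray) -> float:
    n, m = cost.shape
    acc = np.empty((n, m))
    acc[0, 0] = cost[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        for j in range(1, m):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = cost[i, j] + best
    return acc[n - 1, m - 1]


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Classic dynamic time warping cost between two point sequences.

    Local cost is the Euclidean distance between points (1-D sequences are
    treated as points on a line); the step pattern is the symmetric
    match/insert/delete set, boundary-anchored at both ends. Returns the
    accumulated cost along the optimal warping path.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sequence")
    if a.shape[1] != b.shape[1]:
        raise ValueError("sequences must share a point dimension")
    return float(_dtw_accumulate(cdist(a, b)))


@dataclass(frozen=True)
class FitResult:
    trajectory_id: str
    beta: float
    gamma: float
    epsilon: float
    fixed: dict = field(default_factory=dict)  # c1..c4 used
    dtw_error: float = math.nan
    seed: int | None = None
    n_iterations: int = 0
    converged: bool = False

    @property
    def params(self) -> DPMPParams:
        return DPMPParams(
            beta=self.beta, gamma=self.gamma, epsilon=self.epsilon, **self.fixed
        )


@dataclass(frozen=True)
class CharacteristicParams:
    """Per-agent means of the fitted free parameters."""

    agent_id: str
    beta: float
    gamma: float
    epsilon: float
    n_fits: int


def _objective_factory(
    observed: Trajectory,
    scenario: Scenario,
    fixed: DPMPParams,
    sim_kwargs: dict,
):
    obs_pts = observed.points

    def objective(theta: np.ndarray) -> float:
        p = fixed.with_free(float(theta[0]), float(theta[1]), float(theta[2]))
        try:
            sim = simulate(scenario, p, **sim_kwargs)
        except FloatingPointError:
            return _PENALTY
        return dtw_distance(obs_pts, sim.points)

    return objective


def fit_trajectory(
    observed: Trajectory,
    scenario: Scenario,
    bounds: dict[str, tuple[float, float]] | None = None,
    fixed: DPMPParams | None = None,
    seed: int | None = None,
    trajectory_id: str = "",
    mode: str = "continuous",
    speed: float = 10.0,
    maxiter: int = 60,
    popsize: int = 12,
    tol: float = 0.01,
    polish: bool = True,
) -> FitResult:
    """Fit (beta, gamma, epsilon) to one observed trajectory.

    Runs a seeded differential-evolution search minimizing the DTW distance
    between the observed path and the path simulated from candidate
    parameters in the same scenario (same dt, speed, and initial heading as
    the observation). Candidates whose simulation blows up receive a large
    finite penalty so the population can move away from unstable regions.
    Collapsed bounds (lower == upper) pin that parameter.
    """
    if len(observed) < 2:
        raise ValueError("observed trajectory too short to fit")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    for name, (lo, hi) in bounds.items():
        if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi:
            raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")
    fixed = fixed or DPMPParams()
    sim_kwargs = dict(
        start_phi=float(observed.phi[0]),
        speed=speed,
        dt=observed.dt,
        t_max=max(observed.duration, observed.dt),
        mode=mode,
    )
    objective = _objective_factory(observed, scenario, fixed, sim_kwargs)
    names = ("beta", "gamma", "epsilon")
    free = [n for n in names if bounds[n][0] < bounds[n][1]]
    pinned = {n: bounds[n][0] for n in names if n not in free}

    def full_theta(theta_free: np.ndarray) -> np.ndarray:
        vals = dict(zip(free, theta_free))
        return np.array([vals.get(n, pinned.get(n)) for n in names])

    if not free:
        theta = full_theta(np.empty(0))
        cost = objective(theta)
        n_it, converged = 0, True
    else:
        res = differential_evolution(
            lambda th: objective(full_theta(th)),
            [bounds[n] for n in free],
            seed=seed,
            maxiter=maxiter,
            popsize=popsize,
            tol=tol,
            polish=polish,
            init="latinhypercube",
        )
        theta = full_theta(res.x)
        cost, n_it, converged = float(res.fun), int(res.nit), bool(res.success)
    if cost >= _PENALTY:
        raise RuntimeError("every candidate simulation blew up; widen the bounds")
    fixed_cs = {k: getattr(fixed, k) for k in ("c1", "c2", "c3", "c4")}
    return FitResult(
        trajectory_id=trajectory_id,
        beta=float(theta[0]),
        gamma=float(theta[1]),
        epsilon=float(theta[2]),
        fixed=fixed_cs,
        dtw_error=cost,
        seed=seed,
        n_iterations=n_it,
        converged=converged,
    )


def characteristic_params(
    fits: Sequence[FitResult], agent_id: str
) -> CharacteristicParams:
    """Arithmetic mean of an agent's fitted (beta, gamma, epsilon)."""
    if not fits:
        raise ValueError(f"no fits for agent {agent_id!r}")
    return CharacteristicParams(
        agent_id=agent_id,
        beta=float(np.mean([f.beta for f in fits])),
        gamma=float(np.mean([f.gamma for f in fits])),
        epsilon=float(np.mean([f.epsilon for f in fits])),
        n_fits=len(fits),
    )


def simulate_characteristic(
    cp: CharacteristicParams,
    scenarios: Sequence[Scenario],
    fixed: DPMPParams | None = None,
    **sim_kwargs,
) -> list[Trajectory]:
    """One deterministic simulation per scenario at the agent's

    characteristic parameters.
    """
    fixed = fixed or DPMPParams()
    p = fixed.with_free(cp.beta, cp.gamma, cp.epsilon)
    return [simulate(s, p, **sim_kwargs) for s in scenarios]


def default_recovery_scenario() -> Scenario:
    """A far-side scenario with obstacles straddling the direct path, so the

    trajectory is sensitive to all three free parameters (the repulsion
    strength in particular is only identifiable when obstacles are engaged).
    """
    return Scenario(
        config_id="recovery",
        obstacles=(
            Obstacle(1.0, -8.0),
            Obstacle(-3.5, 0.0),
            Obstacle(-8.0, 8.0),
        ),
        start=(5.0, -16.0),
        target=(-12.0, 16.0),
    )


def recovery_study(
    true_param_grid: Sequence[tuple[float, float, float]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    scenario: Scenario | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    fixed: DPMPParams | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Simulate-then-fit validation over a grid of known parameters.

    For each (beta, gamma, epsilon) in the grid: simulate the scenario,
    optionally perturb x/y with additive Gaussian noise of sd ``noise_sd``
    meters, fit, and record true vs recovered values, relative errors, and
    the achieved DTW cost. Returns a tidy table.
    """
    if true_param_grid is None:
        true_param_grid = DEFAULT_RECOVERY_GRID
    scenario = scenario or default_recovery_scenario()
    fixed = fixed or DPMPParams()
    rng = np.random.default_rng(seed)
    rows = []
    for gi, (b, g, e) in enumerate(true_param_grid):
        p = fixed.with_free(b, g, e)
        truth = simulate(scenario, p)
        observed = truth
        if noise_sd > 0:
            observed = Trajectory(
                t=truth.t,
                x=truth.x + rng.normal(0, noise_sd, len(truth)),
                y=truth.y + rng.normal(0, noise_sd, len(truth)),
                phi=truth.phi,
                dt=truth.dt,
                outcome=truth.outcome,
            )
        fit = fit_trajectory(
            observed,
            scenario,
            bounds=bounds,
            fixed=fixed,
            seed=seed + gi,
            trajectory_id=f"grid{gi}",
            **fit_kwargs,
        )
        rows.append(
            {
                "grid_index": gi,
                "true_beta": b,
                "true_gamma": g,
                "true_epsilon": e,
                "fit_beta": fit.beta,
                "fit_gamma": fit.gamma,
                "fit_epsilon": fit.epsilon,
                "rel_err_beta": abs(fit.beta - b) / b,
                "rel_err_gamma": abs(fit.gamma - g) / g,
                "rel_err_epsilon": abs(fit.epsilon - e) / e,
                "dtw_error": fit.dtw_error,
                "noise_sd": noise_sd,
                "outcome": truth.outcome.value,
            }
        )
    return pd.DataFrame(rows)
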