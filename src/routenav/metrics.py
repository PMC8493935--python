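"""Trajectory-comparison statistics.

Pairwise binned distance (mean absolute x-difference over the 160 y-bins),
per-bin group means and empirical 95% confidence bands, CI containment of a
reference trajectory, automated route signatures (which side each obstacle is
passed on), and preferred-route counting at a 10% share threshold. Within-
group distances never pair two trials of the same participant/agent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .dpmp import Trajectory
from .preprocess import BinnedTrajectory
from .scenario import RouteType, Scenario

__all__ = [
    "DistanceRecord",
    "CIBand",
    "RouteSignature",
    "trajectory_distance",
    "group_mean",
    "ci_band",
    "ci_containment",
    "route_signature",
    "preferred_routes",
    "aggregate_distances",
    "BinnedTrial",
]


@dataclass(frozen=True)
class DistanceRecord:
    scenario_id: str
    trial_a: str
    trial_b: str
    group_pairing: str  # "between_group" | "within_group"
    distance: float


@dataclass
class CIBand:
    """Per-bin empirical percentile band of a group of binned trajectories."""

    lower: np.ndarray
    upper: np.ndarray
    group_size: int

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower and upper must share a shape")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound in some bin")


@dataclass(frozen=True)
class RouteSignature:
    """Which side of the travel direction each obstacle lies on at closest

    approach (``"left"``/``"right"``), plus the closest-approach distance.
    Obstacles never approached within the relevance radius are masked to
    ``"-"`` when grouping routes.
    """

    sides: tuple[str, ...]
    min_distances: tuple[float, ...]

    def key(self, relevance_radius: float = 3.0) -> tuple[str, ...]:
        """Grouping key with far-off obstacles masked out."""
        return tuple(
            s if d <= relevance_radius else "-"
            for s, d in zip(self.sides, self.min_distances)
        )


def trajectory_distance(a: BinnedTrajectory, b: BinnedTrajectory) -> float:
    """Mean absolute x-difference over the shared y-grid (meters)."""
    if not a.same_grid(b):
        raise ValueError("binned trajectories are on different y-grids")
    return float(np.mean(np.abs(a.x_values - b.x_values)))


def group_mean(group: Sequence[BinnedTrajectory]) -> BinnedTrajectory:
    """Per-bin arithmetic mean trajectory of a group."""
    if not group:
        raise ValueError("empty group")
    ref = group[0]
    for g in group[1:]:
        if not ref.same_grid(g):
            raise ValueError("group members are on different y-grids")
    xs = np.mean([g.x_values for g in group], axis=0)
    return BinnedTrajectory(y_grid=ref.y_grid.copy(), x_values=xs, source_id="mean")


def ci_band(group: Sequence[BinnedTrajectory], level: float = 95.0) -> CIBand:
    """Per-bin empirical percentile band.

    Percentiles are computed with linear interpolation between order
    statistics (numpy's default), at ``(100 - level)/2`` and
    ``100 - (100 - level)/2``; at the default level 95, the 2.5th and 97.5th.
    """
    if len(group) < 2:
        raise ValueError("need at least 2 trajectories for a confidence band")
    ref = group[0]
    for g in group[1:]:
        if not ref.same_grid(g):
            raise ValueError("group members are on different y-grids")
    xs = np.array([g.x_values for g in group])
    lo = (100.0 - level) / 2.0
    lower, upper = np.percentile(xs, [lo, 100.0 - lo], axis=0, method="linear")
    return CIBand(lower=lower, upper=upper, group_size=len(group))


def ci_containment(reference: BinnedTrajectory, band: CIBand) -> float:
    """Fraction of bins where the reference lies inside the band, in [0, 1]."""
    if reference.x_values.shape != band.lower.shape:
        raise ValueError("reference and band are on different grids")
    x = reference.x_values
    inside = (x >= band.lower) & (x <= band.upper)
    return float(np.mean(inside))


def route_signature(traj: Trajectory, scenario: Scenario) -> RouteSignature:
    """Automated route classification: per obstacle, the side of the travel

    direction on which the obstacle lies at the point of closest approach
    (positive cross product of travel direction with the agent-to-obstacle
    vector = left). Raises if the closest approach is inside an obstacle disc
    (a collision, not a route).
    """
    pts = traj.points
    if len(pts) < 2:
        raise ValueError("trajectory too short for a route signature")
    # travel direction by central differences
    d = np.gradient(pts, axis=0)
    sides, dists = [], []
    for ob in scenario.obstacles:
        rel = np.array([ob.x, ob.y]) - pts
        dist = np.hypot(rel[:, 0], rel[:, 1])
        i = int(np.argmin(dist))
        if dist[i] < ob.radius:
            raise ValueError(
                f"closest approach {dist[i]:.3f} m is inside the obstacle at "
                f"({ob.x}, {ob.y})"
            )
        cross = d[i, 0] * rel[i, 1] - d[i, 1] * rel[i, 0]
        sides.append("left" if cross > 0 else "right")
        dists.append(float(dist[i]))
    return RouteSignature(sides=tuple(sides), min_distances=tuple(dists))


def preferred_routes(
    signatures: Sequence[RouteSignature],
    threshold: float = 0.10,
    relevance_radius: float = 3.0,
) -> list[tuple[tuple[str, ...], float]]:
    """Group identical route signatures and return those whose share of all

    trajectories is at least ``threshold``, sorted by share descending.
    Obstacles never approached within ``relevance_radius`` are masked from
    the grouping key so far-off obstacles do not split routes spuriously.
    """
    if not signatures:
        raise ValueError("empty signature list")
    counts: dict[tuple[str, ...], int] = {}
    for sig in signatures:
        k = sig.key(relevance_radius)
        counts[k] = counts.get(k, 0) + 1
    n = len(signatures)
    out = [(k, c / n) for k, c in counts.items() if c / n >= threshold]
    return sorted(out, key=lambda kv: (-kv[1], kv[0]))


@dataclass(frozen=True)
class BinnedTrial:
    """One preprocessed trial with the labels the aggregation needs."""

    binned: BinnedTrajectory
    agent_id: str
    group: str  # population label, e.g. "human_like" / "drl_like"
    scenario_id: str
    route_type: RouteType


def _pair_records(trials: Sequence[BinnedTrial]) -> pd.DataFrame:
    """All admissible pair distances, labelled between/within group.

    Within-group pairs exclude two trials of the same agent.
    """
    rows = []
    by_scenario: dict[str, list[BinnedTrial]] = {}
    for t in trials:
        by_scenario.setdefault(t.scenario_id, []).append(t)
    for sid, ts in by_scenario.items():
        for a, b in combinations(ts, 2):
            if a.group == b.group:
                if a.agent_id == b.agent_id:
                    continue
                pairing = "within_group"
            else:
                pairing = "between_group"
            rows.append(
                {
                    "scenario_id": sid,
                    "route_type": a.route_type.value,
                    "group_a": a.group,
                    "agent_a": a.agent_id,
                    "trial_a": a.binned.source_id,
                    "group_b": b.group,
                    "agent_b": b.agent_id,
                    "trial_b": b.binned.source_id,
                    "pairing": pairing,
                    "distance": trajectory_distance(a.binned, b.binned),
                }
            )
    return pd.DataFrame(rows)


def aggregate_distances(
    trials: Sequence[BinnedTrial],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise distances and per-agent route-type averages.

    Returns ``(records, aggregates)``. ``records`` holds one row per pair of
    binned trajectories within a scenario (between-group pairs across the two
    populations; within-group pairs excluding same-agent pairs).
    ``aggregates`` averages each agent's pair distances per route type and
    pairing, ready for external mixed-model statistics; agents with no
    admissible pairs for a route type appear with ``n_pairs = 0`` and NaN
    distance rather than being dropped.
    """
    records = _pair_records(trials)
    agents = sorted({(t.agent_id, t.group) for t in trials})
    route_types = sorted({t.route_type.value for t in trials})
    rows = []
    for agent_id, group in agents:
        for rt in route_types:
            for pairing in ("between_group", "within_group"):
                if len(records):
                    mask = (
                        (records["route_type"] == rt)
                        & (records["pairing"] == pairing)
                        & (
                            (records["agent_a"] == agent_id)
                            | (records["agent_b"] == agent_id)
                        )
                    )
                    if pairing == "within_group":
                        mask &= (records["group_a"] == group) & (
                            records["group_b"] == group
                        )
                    sub = records[mask]
                else:
                    sub = records
                rows.append(
                    {
                        "agent_id": agent_id,
                        "group": group,
                        "route_type": rt,
                        "pairing": pairing,
                        "mean_distance": float(sub["distance"].mean())
                        if len(sub)
                        else math.nan,
                        "n_pairs": int(len(sub)),
                    }
                )
    return records, pd.DataFrame(rows)
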