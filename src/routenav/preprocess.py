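"""Trajectory pre-processing: resampling, discard filters, and y-binning.

Raw 50 Hz trajectories are (i) linearly interpolated in time to a standard
length of 1,000 samples, (ii) screened by two discard rules — cumulative path
length more than 1.2x the scenario's mean, or duration above 20 s — and
(iii) reduced to one x-value per 20 cm bin of y over [-16, 16) m, i.e. 160
points, the unit of every downstream comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dpmp import Trajectory, wrap_angle

__all__ = [
    "BinnedTrajectory",
    "resample_to_n",
    "filter_trials",
    "bin_by_y",
    "N_BINS",
    "Y_MIN",
    "Y_MAX",
    "BIN_WIDTH",
]

Y_MIN = -16.0
Y_MAX = 16.0
BIN_WIDTH = 0.2
N_BINS = int(round((Y_MAX - Y_MIN) / BIN_WIDTH))  # 160


def y_grid(y_min: float = Y_MIN, y_max: float = Y_MAX, bin_width: float = BIN_WIDTH) -> np.ndarray:
    """Bin centers of the fixed y-grid."""
    n = int(round((y_max - y_min) / bin_width))
    return y_min + (np.arange(n) + 0.5) * bin_width


@dataclass
class BinnedTrajectory:
    """A path reduced to one x-value per y-bin on the fixed study grid."""

    y_grid: np.ndarray
    x_values: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.y_grid = np.asarray(self.y_grid, dtype=float)
        self.x_values = np.asarray(self.x_values, dtype=float)
        if self.y_grid.shape != self.x_values.shape:
            raise ValueError("y_grid and x_values must have the same shape")
        if not np.all(np.isfinite(self.x_values)):
            raise ValueError("binned x-values must be finite")

    def __len__(self) -> int:
        return len(self.x_values)

    def same_grid(self, other: "BinnedTrajectory") -> bool:
        return self.y_grid.shape == other.y_grid.shape and np.allclose(
            self.y_grid, other.y_grid
        )


def resample_to_n(traj: Trajectory, n: int = 1000) -> Trajectory:
    """Linear interpolation of x, y, and heading at ``n`` evenly spaced times.

    Heading is interpolated on the unwrapped angle and re-wrapped, so paths
    that cross the +-pi seam interpolate correctly.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 samples to resample")
    t_new = np.linspace(traj.t[0], traj.t[-1], n)
    phi_unwrapped = np.unwrap(traj.phi)
    return Trajectory(
        t=t_new,
        x=np.interp(t_new, traj.t, traj.x),
        y=np.interp(t_new, traj.t, traj.y),
        phi=wrap_angle(np.interp(t_new, traj.t, phi_unwrapped)),
        dt=float(t_new[1] - t_new[0]),
        outcome=traj.outcome,
    )


def filter_trials(
    trials: list[Trajectory],
    per_scenario_mean_length: float | None = None,
    max_duration: float = 20.0,
    length_factor: float = 1.2,
) -> tuple[list[Trajectory], list[tuple[Trajectory, str]]]:
    """Apply the two discard rules to one scenario's trials.

    A trial is discarded when its cumulative path length exceeds
    ``length_factor`` times the scenario mean (computed over *all* supplied
    trials when not given), or when its duration exceeds ``max_duration``
    seconds. Returns ``(kept, discarded)`` where each discard carries a
    machine-readable reason (``"length"`` or ``"duration"``).
    """
    if not trials:
        raise ValueError("empty trial list")
    lengths = [t.path_length() for t in trials]
    mean_len = (
        per_scenario_mean_length
        if per_scenario_mean_length is not None
        else float(np.mean(lengths))
    )
    kept, discarded = [], []
    for traj, plen in zip(trials, lengths):
        if traj.duration > max_duration:
            discarded.append((traj, "duration"))
        elif plen > length_factor * mean_len:
            discarded.append((traj, "length"))
        else:
            kept.append(traj)
    return kept, discarded


def bin_by_y(
    traj: Trajectory,
    y_min: float = Y_MIN,
    y_max: float = Y_MAX,
    bin_width: float = BIN_WIDTH,
    source_id: str = "",
    min_span_fraction: float = 0.5,
) -> BinnedTrajectory:
    """Reduce a trajectory to one x-value per half-open y-bin.

    Each bin ``[y_min + k*w, y_min + (k+1)*w)`` takes the mean x of all
    samples whose y falls inside it (averaging over every visit when the path
    backtracks). Empty interior bins are filled by linear interpolation
    between the nearest non-empty neighbors; empty boundary bins by
    nearest-value extrapolation.

    Raises
    ------
    ValueError
        If the trajectory spans less than ``min_span_fraction`` of the y
        range (binning would be meaningless).
    """
    n = int(round((y_max - y_min) / bin_width))
    y = np.asarray(traj.y, dtype=float)
    x = np.asarray(traj.x, dtype=float)
    span = y.max() - y.min()
    if span < min_span_fraction * (y_max - y_min):
        raise ValueError(
            f"trajectory spans {span:.2f} m of y, less than "
            f"{min_span_fraction:.0%} of the {y_max - y_min:.0f} m range"
        )
    idx = np.floor((y - y_min) / bin_width).astype(int)
    inside = (idx >= 0) & (idx < n)
    sums = np.bincount(idx[inside], weights=x[inside], minlength=n)
    counts = np.bincount(idx[inside], minlength=n)
    filled = counts > 0
    centers = y_min + (np.arange(n) + 0.5) * bin_width
    xs = np.full(n, np.nan)
    xs[filled] = sums[filled] / counts[filled]
    if not filled.any():
        raise ValueError("no samples fall inside the binning range")
    # interior gaps: linear interpolation; boundaries: nearest value
    xs = np.interp(centers, centers[filled], xs[filled])
    return BinnedTrajectory(y_grid=centers, x_values=xs, source_id=source_id)
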