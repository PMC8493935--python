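import math

import numpy as np
import pytest

from routenav import (
    DPMPParams,
    Obstacle,
    Scenario,
    Trajectory,
)


@pytest.fixture
def empty_scenario():
    """Obstacle-free middle route: start at the bottom, target straight up."""
    return Scenario("empty", (), (0.0, -16.0), (0.0, 16.0))


@pytest.fixture
def far_side_scenario():
    """Far-side route with two obstacles near the direct path."""
    return Scenario(
        "far",
        (Obstacle(1.0, -5.0), Obstacle(-3.0, 4.0)),
        (5.0, -16.0),
        (-12.0, 16.0),
    )


@pytest.fixture
def stiff_params():
    """Parameters that complete the task at the game's 10 m/s."""
    return DPMPParams(beta=10.0, gamma=100.0, epsilon=500.0)


@pytest.fixture
def straight_trajectory():
    """Uniform vertical path from y=-16 to y=16 at x=3."""
    t = np.arange(0, 3.21, 0.02)
    y = np.linspace(-16.0, 16.0, len(t))
    return Trajectory(
        t=t, x=np.full(len(t), 3.0), y=y, phi=np.full(len(t), math.pi / 2), dt=0.02
    )


def mirror_scenario(s: Scenario) -> Scenario:
    """Reflect a scenario about the y-axis."""
    return Scenario(
        config_id=s.config_id + "_mirror",
        obstacles=tuple(Obstacle(-o.x, o.y, o.radius) for o in s.obstacles),
        start=(-s.start[0], s.start[1]),
        target=(-s.target[0], s.target[1]),
        target_radius=s.target_radius,
        field=s.field,
    )
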