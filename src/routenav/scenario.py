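"""Task geometry: field, obstacles, scenarios, and route-type classification.

The navigation task takes place on a 40 x 40 m square field centered on the
origin, with +y pointing from the start wall toward the target wall. A
*scenario* is one obstacle configuration combined with one start and one
target position. The canonical study design uses two starts (+-5, -16) and
three targets ((+-12, 16) and (0, 16)), so each obstacle configuration yields
six scenarios.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

Point = tuple[float, float]

#: Canonical start positions (m), right and left of the bottom wall.
PAPER_STARTS: tuple[Point, ...] = ((5.0, -16.0), (-5.0, -16.0))
#: Canonical target positions (m): top right, top middle, top left.
PAPER_TARGETS: tuple[Point, ...] = ((12.0, 16.0), (0.0, 16.0), (-12.0, 16.0))


class RouteType(str, Enum):
    """Lateral relation between start and target.

    ``near_side``: start and target on the same side of the midline;
    ``far_side``: opposite sides; ``middle``: target on the midline.
    """

    NEAR_SIDE = "near_side"
    MIDDLE = "middle"
    FAR_SIDE = "far_side"


@dataclass(frozen=True)
class FieldSpec:
    """Square playing field centered on the origin.

    Parameters
    ----------
    half_extent : float
        Half the side length in meters (default 20, i.e. a 40 x 40 m field).
    wall_present : bool
        Whether the bounding wall exists (it is an opaque object for raycasts).
    """

    half_extent: float = 20.0
    wall_present: bool = True

    def __post_init__(self) -> None:
        if self.half_extent <= 0:
            raise ValueError("half_extent must be positive")

    def contains(self, p: Point) -> bool:
        """True if ``p`` lies strictly inside the field."""
        return abs(p[0]) < self.half_extent and abs(p[1]) < self.half_extent


@dataclass(frozen=True)
class Obstacle:
    """A cylindrical obstacle, treated as a 2-D disc of radius 0.25 m."""

    x: float
    y: float
    radius: float = 0.25

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("obstacle radius must be positive")

    @property
    def center(self) -> Point:
        return (self.x, self.y)


def classify_route_type(start: Point, target: Point) -> RouteType:
    """Classify the route type of a start/target pair.

    The target on the midline (x == 0) is a *middle* route; otherwise the
    route is *near-side* when start and target share the sign of x and
    *far-side* when the signs are opposite.

    Raises
    ------
    ValueError
        If the start is not below the target, or if the start lies on the
        midline while the target does not (ambiguous; outside the design).
    """
    if not start[1] < target[1]:
        raise ValueError("start must lie below the target (start.y < target.y)")
    if target[0] == 0:
        return RouteType.MIDDLE
    if start[0] == 0:
        raise ValueError(
            "route type undefined: start on the midline with an off-center target"
        )
    same = math.copysign(1.0, start[0]) == math.copysign(1.0, target[0])
    return RouteType.NEAR_SIDE if same else RouteType.FAR_SIDE


@dataclass(frozen=True)
class Scenario:
    """One obstacle configuration plus a start and a target position."""

    config_id: str
    obstacles: tuple[Obstacle, ...]
    start: Point
    target: Point
    target_radius: float = 0.25
    field: FieldSpec = field(default_factory=FieldSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "obstacles", tuple(self.obstacles))
        object.__setattr__(self, "start", tuple(self.start))
        object.__setattr__(self, "target", tuple(self.target))
        if self.target_radius <= 0:
            raise ValueError("target_radius must be positive")
        for name, p in (("start", self.start), ("target", self.target)):
            if not self.field.contains(p):
                raise ValueError(f"{name} {p} lies outside the field")
        for ob in self.obstacles:
            if not self.field.contains(ob.center):
                raise ValueError(f"obstacle at {ob.center} lies outside the field")

    @property
    def route_type(self) -> RouteType:
        return classify_route_type(self.start, self.target)

    @property
    def is_paper_faithful(self) -> bool:
        """True when start and target belong to the canonical study design."""
        return self.start in PAPER_STARTS and self.target in PAPER_TARGETS

    # ---- JSON round-trip -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config_id": self.config_id,
            "obstacles": [
                {"x": ob.x, "y": ob.y, "radius": ob.radius} for ob in self.obstacles
            ],
            "start": list(self.start),
            "target": list(self.target),
            "target_radius": self.target_radius,
            "half_extent": self.field.half_extent,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(
            config_id=d["config_id"],
            obstacles=tuple(Obstacle(**ob) for ob in d["obstacles"]),
            start=tuple(d["start"]),
            target=tuple(d["target"]),
            target_radius=d.get("target_radius", 0.25),
            field=FieldSpec(half_extent=d.get("half_extent", 20.0)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Scenario":
        return cls.from_dict(json.loads(Path(path).read_text()))


def enumerate_scenarios(
    configs: Sequence[tuple[str, Sequence[Obstacle]]] | Sequence[Sequence[Obstacle]],
    starts: Sequence[Point],
    targets: Sequence[Point],
    field_spec: FieldSpec | None = None,
) -> list[Scenario]:
    """Cartesian product of obstacle configurations, starts, and targets.

    ``configs`` may be bare obstacle lists (auto-named ``cfg00`` ...) or
    ``(name, obstacles)`` pairs. Ordering is deterministic: configuration
    major, then start, then target, in input order. The canonical design
    (18 configurations x 2 starts x 3 targets) yields 108 scenarios.
    """
    if not configs or not starts or not targets:
        raise ValueError("configs, starts, and targets must all be non-empty")
    field_spec = field_spec or FieldSpec()
    named: list[tuple[str, tuple[Obstacle, ...]]] = []
    for i, cfg in enumerate(configs):
        if len(cfg) == 2 and isinstance(cfg[0], str):
            named.append((cfg[0], tuple(cfg[1])))
        else:
            named.append((f"cfg{i:02d}", tuple(cfg)))
    out = []
    for (name, obstacles), (si, start), (ti, target) in itertools.product(
        named, enumerate(starts), enumerate(targets)
    ):
        out.append(
            Scenario(
                config_id=f"{name}_s{si}_t{ti}",
                obstacles=obstacles,
                start=start,
                target=target,
                field=field_spec,
            )
        )
    return out


def validate_scenario(s: Scenario, min_clearance: float = 0.5) -> list[str]:
    """Report geometry violations; an empty list means the scenario is clean.

    Checks that obstacles keep at least ``min_clearance`` (surface to surface,
    or surface to point for start/target) from each other and from the start
    and target. Report-only: never raises.
    """
    violations: list[str] = []
    obs = s.obstacles
    for i in range(len(obs)):
        for j in range(i + 1, len(obs)):
            gap = (
                math.dist(obs[i].center, obs[j].center)
                - obs[i].radius
                - obs[j].radius
            )
            if gap < min_clearance:
                violations.append(
                    f"obstacles {i} and {j} separated by {gap:.3f} m "
                    f"(< {min_clearance} m)"
                )
    for name, p in (("start", s.start), ("target", s.target)):
        for i, ob in enumerate(obs):
            gap = math.dist(ob.center, p) - ob.radius
            if gap < min_clearance:
                violations.append(
                    f"obstacle {i} within {gap:.3f} m of {name} (< {min_clearance} m)"
                )
    return violations


def write_scenarios(scenarios: Iterable[Scenario], directory: str | Path) -> list[Path]:
    """Write one JSON file per scenario into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in scenarios:
        p = directory / f"{s.config_id}.json"
        s.to_json(p)
        paths.append(p)
    return paths


def read_scenarios(directory: str | Path) -> list[Scenario]:
    """Read every ``*.json`` scenario file in ``directory`` (sorted by name)."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"scenario directory not found: {directory}")
    return [Scenario.from_json(p) for p in sorted(directory.glob("*.json"))]
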