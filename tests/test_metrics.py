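import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from routenav import (
    BinnedTrial,
    Obstacle,
    RouteType,
    Scenario,
    Trajectory,
    aggregate_distances,
    ci_band,
    ci_containment,
    group_mean,
    preferred_routes,
    route_signature,
    trajectory_distance,
)
from routenav.metrics import RouteSignature
from routenav.preprocess import BinnedTrajectory, y_grid


def binned(x, source_id=""):
    x = np.asarray(x, dtype=float)
    if x.size == 1:
        x = np.full(160, float(x))
    return BinnedTrajectory(y_grid=y_grid(), x_values=x, source_id=source_id)


class TestTrajectoryDistance:
    def test_identity_zero(self):
        a = binned(2.0)
        assert trajectory_distance(a, a) == 0.0

    def test_constant_offset(self):
        assert trajectory_distance(binned(1.0), binned(1.5)) == pytest.approx(0.5)

    def test_linear_ramp_mean(self):
        grid = y_grid()
        ramp = (grid + 16.0) / 16.0  # 0 at bottom edge to 2 at top edge
        assert trajectory_distance(binned(0.0), binned(ramp)) == pytest.approx(1.0)

    def test_grid_mismatch_rejected(self):
        a = binned(0.0)
        b = BinnedTrajectory(y_grid=y_grid() + 0.5, x_values=np.zeros(160))
        with pytest.raises(ValueError):
            trajectory_distance(a, b)

    @given(
        x=arrays(float, 160, elements=st.floats(-20, 20)),
        y=arrays(float, 160, elements=st.floats(-20, 20)),
        z=arrays(float, 160, elements=st.floats(-20, 20)),
    )
    @settings(max_examples=30, derandomize=True)
    def test_pseudometric(self, x, y, z):
        a, b, c = binned(x), binned(y), binned(z)
        dab = trajectory_distance(a, b)
        assert dab >= 0
        assert dab == pytest.approx(trajectory_distance(b, a))
        assert trajectory_distance(a, c) <= dab + trajectory_distance(b, c) + 1e-9


class TestGroupStatistics:
    def test_mean_of_identical_is_identity(self):
        group = [binned(1.5)] * 4
        np.testing.assert_allclose(group_mean(group).x_values, 1.5)

    def test_mirror_pair_mean_is_zero(self):
        ramp = (y_grid() + 16.0) / 16.0
        assert np.allclose(group_mean([binned(ramp), binned(-ramp)]).x_values, 0.0)

    def test_three_constant_lines(self):
        group = [binned(0.0), binned(1.0), binned(2.0)]
        np.testing.assert_allclose(group_mean(group).x_values, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_mean([])

    def test_band_of_identical_group_collapses(self):
        band = ci_band([binned(2.0)] * 5)
        np.testing.assert_allclose(band.lower, 2.0)
        np.testing.assert_allclose(band.upper, 2.0)

    def test_percentiles_linear_interpolation(self):
        group = [binned(float(v)) for v in range(101)]
        band = ci_band(group)
        np.testing.assert_allclose(band.lower, 2.5)
        np.testing.assert_allclose(band.upper, 97.5)

    def test_widening_level_widens_band(self):
        rng = np.random.default_rng(0)
        group = [binned(rng.normal(size=160)) for _ in range(30)]
        b90 = ci_band(group, level=90)
        b99 = ci_band(group, level=99)
        assert np.all(b99.lower <= b90.lower) and np.all(b99.upper >= b90.upper)

    def test_band_needs_two(self):
        with pytest.raises(ValueError):
            ci_band([binned(0.0)])


class TestCIContainment:
    def test_symmetric_group_mean_fully_contained(self):
        rng = np.random.default_rng(1)
        group = [binned(rng.normal(0, 1, 160)) for _ in range(40)]
        band = ci_band(group)
        assert ci_containment(group_mean(group), band) == 1.0

    def test_far_reference_zero(self):
        group = [binned(float(v)) for v in range(10)]
        band = ci_band(group)
        assert ci_containment(binned(1e6), band) == 0.0

    def test_half_inside_split(self):
        x = np.zeros(160)
        x[:80] = 100.0  # outside in exactly 80 bins
        band = ci_band([binned(-1.0), binned(1.0)])
        assert ci_containment(binned(x), band) == pytest.approx(0.5)

    def test_median_always_contained(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            group = [binned(rng.normal(0, 3, 160)) for _ in range(25)]
            band = ci_band(group)
            med = binned(np.median([g.x_values for g in group], axis=0))
            assert ci_containment(med, band) == 1.0


def straight_traj(x0, y0, x1, y1, n=321):
    return Trajectory(
        t=np.arange(n) * 0.02,
        x=np.linspace(x0, x1, n),
        y=np.linspace(y0, y1, n),
        phi=np.full(n, math.atan2(y1 - y0, x1 - x0)),
        dt=0.02,
    )


class TestRouteSignature:
    def test_obstacle_right_of_upward_path(self):
        s = Scenario("s", (Obstacle(1.0, 0.0),), (0, -16), (0, 16))
        sig = route_signature(straight_traj(0, -16, 0, 16), s)
        assert sig.sides == ("right",)

    def test_mirrored_side_flips(self):
        s = Scenario("s", (Obstacle(-1.0, 0.0),), (0, -16), (0, 16))
        sig = route_signature(straight_traj(0, -16, 0, 16), s)
        assert sig.sides == ("left",)

    def test_weave_between_two_obstacles(self):
        # S-shaped path passing right of the first, left of the second
        n = 1601
        y = np.linspace(-16.0, 16.0, n)
        x = -2.0 * np.tanh(y / 2.0)
        traj = Trajectory(t=np.arange(n) * 0.01, x=x, y=y,
                          phi=np.full(n, math.pi / 2), dt=0.01)
        s = Scenario("s", (Obstacle(3.0, -6.0), Obstacle(-3.0, 6.0)), (0, -16), (0, 16))
        sig = route_signature(traj, s)
        assert sig.sides == ("right", "left")

    def test_collision_rejected(self):
        s = Scenario("s", (Obstacle(0.0, 0.0),), (0, -16), (0, 16))
        with pytest.raises(ValueError):
            route_signature(straight_traj(0, -16, 0, 16), s)


class TestPreferredRoutes:
    def sig(self, *sides, d=1.0):
        return RouteSignature(sides=sides, min_distances=tuple([d] * len(sides)))

    def test_single_route_full_share(self):
        out = preferred_routes([self.sig("left")] * 7)
        assert out == [(("left",), 1.0)]

    def test_boundary_share_included(self):
        sigs = [self.sig("left")] * 9 + [self.sig("right")]
        out = preferred_routes(sigs)
        assert (("left",), 0.9) in out and (("right",), 0.1) in out

    def test_below_threshold_excluded(self):
        sigs = [self.sig("left")] * 19 + [self.sig("right")]
        out = preferred_routes(sigs)
        assert out == [(("left",), 0.95)]

    def test_far_obstacles_masked(self):
        sigs = [self.sig("left", d=10.0), self.sig("right", d=20.0)]
        out = preferred_routes(sigs, relevance_radius=3.0)
        assert out == [(("-",), 1.0)]  # one merged route, not two

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            preferred_routes([])


class TestAggregateDistances:
    def trial(self, x, agent, group, scenario="sc0", rt=RouteType.MIDDLE, tid=""):
        return BinnedTrial(
            binned=binned(x, source_id=tid or f"{agent}-{scenario}"),
            agent_id=agent, group=group, scenario_id=scenario, route_type=rt,
        )

    def test_identical_groups_all_zero(self):
        trials = [
            self.trial(1.0, "h1", "human_like"),
            self.trial(1.0, "d1", "drl_like"),
        ]
        records, agg = aggregate_distances(trials)
        assert (records["distance"] == 0.0).all()
        assert (records["pairing"] == "between_group").all()

    def test_single_participant_within_group_flagged_empty(self):
        trials = [
            self.trial(0.0, "h1", "human_like", tid="a"),
            self.trial(1.0, "h1", "human_like", tid="b"),
        ]
        records, agg = aggregate_distances(trials)
        assert len(records) == 0  # same-participant pair excluded
        wg = agg[agg["pairing"] == "within_group"]
        assert (wg["n_pairs"] == 0).all()
        assert wg["mean_distance"].isna().all()

    def test_between_group_pair_count(self):
        trials = [
            self.trial(0.0, "h1", "human_like"),
            self.trial(0.0, "h2", "human_like"),
            self.trial(0.0, "d1", "drl_like"),
            self.trial(0.0, "d2", "drl_like"),
        ]
        records, _ = aggregate_distances(trials)
        bg = records[records["pairing"] == "between_group"]
        assert len(bg) == 4  # 2 humans x 2 drl

    def test_within_group_excludes_same_agent(self):
        trials = [
            self.trial(0.0, "h1", "human_like", tid="h1a"),
            self.trial(1.0, "h1", "human_like", tid="h1b"),
            self.trial(2.0, "h2", "human_like", tid="h2a"),
        ]
        records, _ = aggregate_distances(trials)
        wg = records[records["pairing"] == "within_group"]
        assert len(wg) == 2  # h1a-h2a and h1b-h2a only
        assert not ((wg["agent_a"] == "h1") & (wg["agent_b"] == "h1")).any()
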