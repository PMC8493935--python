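import math

import numpy as np
import pytest

from routenav import (
    Action,
    AgentState,
    KinematicsSpec,
    NavEnv,
    Obstacle,
    Outcome,
    RaySpec,
    Scenario,
    cast_rays,
    curriculum_placement,
    encode_observation,
    run_episode,
    scripted_dpmp_policy,
)
from routenav.nav_env import RAY_CLASSES, step

from conftest import mirror_scenario


def ray_march_oracle(state, scenario, spec):
    """Brute-force ray classifier: march each ray in 1 cm steps and report

    the first object the sample point enters. Independent of the analytic
    ray-intersection code.
    """
    half = scenario.field.half_extent
    max_len = spec.max_length or 2 * half * math.sqrt(2)
    out = []
    for ang in spec.angles_rad:
        a = state.phi + ang
        dx, dy = math.cos(a), math.sin(a)
        cls = "nothing"
        r = 0.0
        while r <= max_len:
            px, py = state.x + r * dx, state.y + r * dy
            if math.hypot(px - scenario.target[0], py - scenario.target[1]) <= scenario.target_radius:
                cls = "target"
                break
            hit_ob = any(
                math.hypot(px - ob.x, py - ob.y) <= ob.radius for ob in scenario.obstacles
            )
            if hit_ob:
                cls = "obstacle"
                break
            if scenario.field.wall_present and (abs(px) >= half or abs(py) >= half):
                cls = "other"
                break
            r += 0.01
        out.append(cls)
    return out


def decode_ray_block(block):
    blocks = np.asarray(block).reshape(-1, 4)
    return [RAY_CLASSES[int(i)] for i in np.argmax(blocks, axis=1)]


class TestObservations:
    def test_ray_block_length_44(self, empty_scenario):
        state = AgentState(0, 0, math.pi / 2)
        assert len(cast_rays(state, empty_scenario)) == 44

    def test_observation_length_46(self, empty_scenario):
        state = AgentState(0, 0, math.pi / 2)
        assert len(encode_observation(state, empty_scenario).to_vector()) == 46

    def test_one_hot_blocks_sum_to_one(self, far_side_scenario):
        state = AgentState(0, 0, 1.0)
        blocks = cast_rays(state, far_side_scenario).reshape(11, 4)
        np.testing.assert_array_equal(blocks.sum(axis=1), np.ones(11))

    def test_nothing_when_out_of_range(self):
        s = Scenario("s", (), (0, -16), (0, 16), field=__import__("routenav").FieldSpec())
        state = AgentState(0, 0, math.pi / 2)
        spec = RaySpec(max_length=0.5)  # too short to reach anything
        classes = decode_ray_block(cast_rays(state, s, spec))
        assert classes == ["nothing"] * 11

    def test_center_ray_sees_inline_obstacle(self):
        s = Scenario("s", (Obstacle(0.0, 5.0),), (0, -16), (0, 16))
        state = AgentState(0, 0, math.pi / 2)
        classes = decode_ray_block(cast_rays(state, s))
        assert classes[5] == "obstacle"  # center ray, obstacle closer than target

    def test_target_heading_zero_when_facing_target(self, empty_scenario):
        state = AgentState(0, 0, math.pi / 2)
        obs = encode_observation(state, empty_scenario)
        assert obs.target_heading == pytest.approx(0.0)
        assert obs.target_distance == pytest.approx(16.0)

    def test_wall_classified_as_other(self):
        s = Scenario("s", (), (0, -16), (0, 16))
        state = AgentState(0, 10, math.pi / 2)  # facing the top wall past target? no: target behind
        # heading +y from (0,10): target at (0,16) is ahead -> center ray sees target
        classes = decode_ray_block(cast_rays(state, s))
        assert classes[5] == "target"
        assert "other" in classes  # oblique rays end on the wall

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_ray_march_oracle(self, seed):
        from routenav import random_obstacle_config

        rng = np.random.default_rng(seed)
        obstacles = random_obstacle_config(6, seed=rng, min_clearance=2.0)
        s = Scenario("s", tuple(obstacles), (5, -16), (-12, 16))
        state = AgentState(
            float(rng.uniform(-10, 10)), float(rng.uniform(-10, 10)),
            float(rng.uniform(-math.pi, math.pi)),
        )
        spec = RaySpec()
        assert decode_ray_block(cast_rays(state, s, spec)) == ray_march_oracle(
            state, s, spec
        )


class TestAction:
    def test_vector_dimension_5(self):
        assert len(Action("forward", "left").to_vector()) == 5

    def test_round_trip(self):
        for move in ("forward", "none"):
            for rotate in ("left", "none", "right"):
                a = Action(move, rotate)
                assert Action.from_vector(a.to_vector()) == a

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            Action("backward", "left")
        with pytest.raises(ValueError):
            Action.from_vector(np.ones(5))


class TestStep:
    def test_rotation_accelerates_by_one_frame(self):
        spec = KinematicsSpec()
        state = AgentState(0, 0, 0, phi_dot=0.0)
        out = step(state, Action("none", "left"), spec)
        assert math.degrees(out.phi_dot) == pytest.approx(62.5 * 0.02)

    def test_forward_displacement_one_frame(self):
        spec = KinematicsSpec()
        state = AgentState(0, 0, 0.0, phi_dot=0.0)
        out = step(state, Action("forward", "none"), spec)
        assert out.x == pytest.approx(10 * 0.02)
        assert out.y == pytest.approx(0.0)

    def test_idle_action_is_identity(self):
        spec = KinematicsSpec()
        state = AgentState(1.0, 2.0, 0.5, phi_dot=0.0)
        out = step(state, Action("none", "none"), spec)
        assert (out.x, out.y, out.phi, out.phi_dot) == (1.0, 2.0, 0.5, 0.0)

    def test_turn_rate_clamped(self):
        spec = KinematicsSpec()
        state = AgentState(0, 0, 0, phi_dot=spec.max_turn_rate_rad)
        out = step(state, Action("none", "left"), spec)
        assert out.phi_dot == pytest.approx(spec.max_turn_rate_rad)

    def test_rate_decays_without_command(self):
        spec = KinematicsSpec()
        state = AgentState(0, 0, 0, phi_dot=math.radians(1.0))
        out = step(state, Action("none", "none"), spec)
        assert 0.0 <= out.phi_dot < math.radians(1.0)
        # and does not overshoot past zero
        out2 = step(AgentState(0, 0, 0, phi_dot=math.radians(0.5)), Action("none", "none"), spec)
        assert out2.phi_dot == 0.0


class TestEpisodes:
    def test_idle_policy_times_out_at_1500_frames(self, empty_scenario):
        policy = lambda obs, state: Action("none", "none")
        result = run_episode(policy, empty_scenario)
        assert result.outcome is Outcome.TIMED_OUT
        assert result.reward == -1.0
        assert len(result.trajectory) == 1501  # 30 s x 50 Hz steps + initial

    def test_forward_into_obstacle(self):
        s = Scenario("s", (Obstacle(0.0, 0.0),), (0, -16), (0, 16))
        policy = lambda obs, state: Action("forward", "none")
        result = run_episode(policy, s)
        assert result.outcome is Outcome.HIT_OBSTACLE
        assert result.reward == -1.0

    def test_scripted_policy_reaches_obstacle_free_target(self, empty_scenario, stiff_params):
        result = run_episode(scripted_dpmp_policy(stiff_params), empty_scenario)
        assert result.outcome is Outcome.REACHED_TARGET
        assert result.reward == 1.0

    def test_turn_rate_capped_throughout(self, far_side_scenario, stiff_params):
        result = run_episode(scripted_dpmp_policy(stiff_params), far_side_scenario)
        spec = KinematicsSpec()
        rate = np.abs(np.diff(np.unwrap(result.trajectory.phi))) / spec.dt
        assert rate.max() <= spec.max_turn_rate_rad + 1e-9

    def test_scripted_policy_turns_toward_goal(self, stiff_params):
        s = Scenario("s", (), (0, -16), (-12, 16))  # goal up and to the left
        env = NavEnv(s)
        obs, _ = env.reset()
        action = scripted_dpmp_policy(stiff_params)(obs, env.state)
        assert action.rotate == "left"

    def test_mirrored_scenario_mirrors_actions(self, far_side_scenario, stiff_params):
        policy = scripted_dpmp_policy(stiff_params)
        flip = {"left": "right", "right": "left", "none": "none"}
        env_a = NavEnv(far_side_scenario)
        env_b = NavEnv(mirror_scenario(far_side_scenario), start_phi=math.pi - math.pi / 2)
        obs_a, _ = env_a.reset()
        obs_b, _ = env_b.reset()
        for _ in range(40):
            act_a = policy(obs_a, env_a.state)
            act_b = policy(obs_b, env_b.state)
            assert act_b.rotate == flip[act_a.rotate]
            assert act_b.move == act_a.move
            for _ in range(5):
                obs_a, *_ = env_a.step(act_a)
                obs_b, *_ = env_b.step(act_b)


class TestCurriculum:
    def test_late_phase_pins_x(self):
        for seed in (0, 7):
            start, target = curriculum_placement("late", seed)
            assert start[0] == -16.0 and target[0] == 16.0

    def test_early_phase_reproducible(self):
        assert curriculum_placement("early", 3) == curriculum_placement("early", 3)

    def test_different_seeds_differ(self):
        assert curriculum_placement("early", 1) != curriculum_placement("early", 2)

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError):
            curriculum_placement("mid", 0)
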