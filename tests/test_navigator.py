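"""Control-law operations and trial simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fishnav.navigator import (
    AgentState,
    ControlParams,
    HPBias,
    Strategy,
    attractor_term,
    axis_speed_update,
    bvc_drive,
    compose_velocity,
    error_update,
    fold_potential,
    hp_bias,
    relative_distance,
    rotate,
    run_trial,
    steer,
    visual_scene,
)

P = ControlParams()


class TestComposeVelocity:
    @pytest.mark.parametrize(
        "s,theta,expected",
        [
            (0.5, 0.0, (0.5, 0.0)),
            (0.5, math.pi / 2, (0.0, 0.5)),
            (0.0, 1.2, (0.0, 0.0)),
        ],
    )
    def test_examples(self, s, theta, expected):
        assert compose_velocity(s, theta) == pytest.approx(expected, abs=1e-12)


class TestVisualScene:
    def test_empty_arena_all_clear(self, empty_env):
        state = AgentState(p=np.array([0.0, 0.0]), v=np.zeros(2), theta=0.0, s=0.0)
        scene = visual_scene(empty_env, state, P)
        assert not np.any(np.isfinite(scene.d))
        assert not scene.target_visible

    def test_visibility_radius(self, empty_env):
        p = empty_env.target - np.array([0.29, 0.0])
        state = AgentState(p=p, v=np.zeros(2), theta=0.0, s=0.0)
        assert visual_scene(empty_env, state, P).target_visible

    def test_forward_distance_oracle(self, single_coral_env):
        state = AgentState(p=np.zeros(2), v=np.zeros(2), theta=0.0, s=0.0)
        scene = visual_scene(single_coral_env, state, P)
        assert scene.d0 == pytest.approx(0.85, abs=1e-12)


class TestBvcDrive:
    def test_all_clear_zero(self, empty_env):
        state = AgentState(p=np.zeros(2), v=np.zeros(2), theta=0.0, s=0.0)
        scene = visual_scene(empty_env, state, P)
        assert np.all(bvc_drive(scene) == 0)

    def test_contact_is_maximal(self, single_coral_env):
        state = AgentState(
            p=np.array([0.85, 0.0]), v=np.zeros(2), theta=0.0, s=0.0
        )
        scene = visual_scene(single_coral_env, state, P)
        drive = bvc_drive(scene)
        assert drive[0] == pytest.approx(drive.max())
        assert drive[0] == pytest.approx(1.0)

    def test_monotone_in_distance(self, single_coral_env):
        values = []
        for d in np.linspace(0.2, 1.39, 25):
            state = AgentState(
                p=np.array([1.0 - 0.15 - d, 0.0]), v=np.zeros(2), theta=0.0, s=0.0
            )
            scene = visual_scene(single_coral_env, state, P)
            values.append(bvc_drive(scene)[0])
        assert np.all(np.diff(values) <= 1e-12)


class TestAttractor:
    def test_outside_radius(self):
        assert np.all(attractor_term(np.zeros(2), np.array([0.5, 0.0])) == 0)

    def test_at_goal(self):
        assert np.all(attractor_term(np.ones(2), np.ones(2)) == 0)

    def test_inside_radius(self):
        g = np.array([0.1, 0.1])
        out = attractor_term(np.zeros(2), g)
        assert out == pytest.approx([0.1, 0.1])


class TestSpeedLaw:
    def test_relative_distance_endpoints(self):
        assert relative_distance(0.4) == 1.0
        assert relative_distance(0.03) == 0.0
        assert relative_distance(0.215) == pytest.approx(0.5)

    def test_acceleration_capped(self):
        assert axis_speed_update(0.5, 1.0, P) == 0.5

    def test_acceleration_arithmetic(self):
        assert axis_speed_update(0.1, 1.0, P) == pytest.approx(0.4)

    def test_full_stop_at_safety_distance(self):
        assert axis_speed_update(0.3, 0.03, P) == 0.0

    def test_fold_clips(self):
        assert fold_potential(0.7) == 0.5
        assert fold_potential(-0.7) == -0.5
        assert fold_potential(0.0) == 0.0
        assert fold_potential(-0.3) == -0.3


class TestSteering:
    def test_fixed_point(self):
        assert steer(0.4, 0.4) == pytest.approx(0.4)

    def test_blend_arithmetic(self):
        assert steer(1.0, 0.0) == pytest.approx(0.9)

    @given(
        new=st.floats(-math.pi / 2, math.pi / 2),
        old=st.floats(-math.pi / 2, math.pi / 2),
    )
    @settings(max_examples=50, deadline=None)
    def test_convex_combination_stays_in_range(self, new, old):
        assert abs(steer(new, old)) <= math.pi / 2 + 1e-12

    def test_rotation(self):
        v = np.array([1.0, 0.0])
        assert rotate(v, 0.0) == pytest.approx([1.0, 0.0])
        assert rotate(v, math.pi / 2) == pytest.approx([0.0, 1.0], abs=1e-12)

    @given(
        vx=st.floats(-1, 1), vz=st.floats(-1, 1), theta=st.floats(-math.pi, math.pi)
    )
    @settings(max_examples=50, deadline=None)
    def test_rotation_preserves_norm(self, vx, vz, theta):
        v = np.array([vx, vz])
        assert np.linalg.norm(rotate(v, theta)) == pytest.approx(
            np.linalg.norm(v), abs=1e-12
        )


class TestHPBias:
    BIAS = HPBias(theta_hp=0.0, target_depth=1.0)

    def test_within_band_uses_horizontal_prior(self):
        assert hp_bias(0.9, 1.0, self.BIAS) == 0.0

    def test_at_target_depth(self):
        assert hp_bias(1.0, 1.0, self.BIAS) == 0.0

    def test_deep_below_climbs(self):
        assert hp_bias(0.0, 1.0, self.BIAS) == pytest.approx(math.pi / 2)

    def test_above_dives(self):
        assert hp_bias(2.0, 1.0, self.BIAS) == pytest.approx(-math.pi / 2)


class TestErrorUpdate:
    def test_fixed_point(self):
        v = np.array([0.2, -0.1])
        assert error_update(v, v) == pytest.approx(v)

    def test_step_response_closed_form(self):
        x = np.zeros(1)
        for _ in range(100):  # one tau2 worth of steps
            x = error_update(x, np.ones(1), 0.1, 0.001)
        assert x[0] == pytest.approx(1 - math.exp(-1), abs=1e-9)

    def test_heading_wraps_through_pi(self):
        # 3.0 rad toward -3.0 rad: the shortest arc passes through pi
        theta = 3.0
        for _ in range(50):
            theta = error_update(theta, -3.0, 0.1, 0.001)
        assert theta > 3.0  # moved upward toward pi, not down toward 0


class TestRunTrial:
    def test_straight_line_time(self, empty_env):
        traj, res = run_trial(empty_env, "azimuth", P, "rate", 0)
        assert res.reached == 1
        expected = (1.0 - P.capture_radius) / P.v_max
        assert res.t_reach == pytest.approx(expected, rel=0.2)

    def test_deterministic_without_noise(self, default_env):
        params = ControlParams(t_max=5.0)
        a, ra = run_trial(default_env, "hp", params, "rate", 7)
        b, rb = run_trial(default_env, "hp", params, "rate", 7)
        assert np.array_equal(a.xy, b.xy)
        assert ra.reached == rb.reached

    def test_timeout_folds_score_to_zero(self, single_coral_env):
        # a wall-facing null agent with a tiny time budget cannot reach
        params = ControlParams(t_max=1.0)
        _, res = run_trial(single_coral_env, "null", params, "rate", 3)
        assert res.reached == 0
        assert res.total_score == 0.0

    def test_speed_never_exceeds_vmax(self, default_env):
        params = ControlParams(t_max=5.0)
        traj, _ = run_trial(default_env, "hp", params, "rate", 1)
        v = np.diff(traj.xy, axis=0) / params.dt
        speeds = np.linalg.norm(v, axis=1)
        assert speeds.max() <= params.v_max + 1e-6

    def test_agent_stays_in_bounds(self):
        from fishnav.arena import ArenaConfig, generate_environment

        params = ControlParams(t_max=3.0)
        for seed in range(20):
            env = generate_environment(ArenaConfig(n_corals=15), seed=seed)
            traj, _ = run_trial(env, "null", params, "rate", seed)
            assert np.all(np.abs(traj.xy) <= 2.0 + 1e-9)

    def test_single_coral_no_collision(self, single_coral_env):
        params = ControlParams(t_max=10.0)
        collided = []
        for seed in range(10):
            traj, res = run_trial(single_coral_env, "azimuth", params, "rate", seed)
            collided.append(res.collision_rate)
        assert np.all(np.array(collided) == 0.0)

    def test_save_trial_roundtrip(self, empty_env, tmp_path):
        import json
        import pandas as pd
        from fishnav.navigator import save_trial

        traj, res = run_trial(empty_env, "azimuth", P, "rate", 0)
        out = tmp_path / "trial.csv"
        save_trial(traj, res, out)
        frame = pd.read_csv(out)
        assert list(frame.columns) == ["t", "x", "z", "collision_flag"]
        meta = json.loads(out.with_suffix(".json").read_text())
        assert meta["reached"] == 1 and meta["strategy"] == "azimuth"

    def test_unknown_strategy(self, empty_env):
        with pytest.raises(ValueError):
            run_trial(empty_env, Strategy(kind="teleport"), P, "rate", 0)


class TestSpikingMode:
    def test_spiking_reaches_target_obstacle_free(self, empty_env):
        _, res = run_trial(empty_env, "azimuth", P, "spiking", 0)
        assert res.reached == 1

    def test_spiking_velocity_tracks_rate_mode(self):
        """Executed velocity traces of spiking and rate mode agree within
        10% RMS (relative to v_max) on an obstacle-free trial at the
        default kinematic population scale; the first 0.5 s of spiking
        spin-up (filters and membranes start empty) is excluded."""
        from fishnav.arena import ArenaConfig, Environment

        env = Environment(
            config=ArenaConfig(n_corals=0),
            coral_centers=np.empty((0, 2)),
            start=np.array([-1.5, -1.3]),
            target=np.array([1.1, 1.3]),
        )
        tr, _ = run_trial(env, "azimuth", P, "rate", 0)
        ts, _ = run_trial(env, "azimuth", P, "spiking", 0)
        n = min(len(tr.t), len(ts.t))
        k0 = 500  # 0.5 s spin-up
        vr = np.diff(tr.xy[:n], axis=0)[k0:] / P.dt
        vs = np.diff(ts.xy[:n], axis=0)[k0:] / P.dt
        rms = np.sqrt(np.mean((vr - vs) ** 2))
        assert rms / P.v_max < 0.10
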