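"""Arena generation and geometric queries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fishnav.arena import (
    CLEAR,
    ArenaConfig,
    Environment,
    affected_bins,
    check_collision,
    coral_aperture,
    distance_along_direction,
    generate_environment,
)


class TestGeneration:
    def test_empty_obstacle_case(self):
        env = generate_environment(ArenaConfig(n_corals=0), seed=3)
        assert env.coral_centers.shape == (0, 2)
        # start and target sit in opposite quadrants
        assert np.all(np.sign(env.start) == -np.sign(env.target))

    def test_corals_inside_bounds(self):
        env = generate_environment(ArenaConfig(n_corals=30), seed=7)
        assert np.all(np.abs(env.coral_centers) <= 2.0)

    def test_seeded_determinism(self):
        cfg = ArenaConfig(n_corals=25)
        a = generate_environment(cfg, seed=11)
        b = generate_environment(cfg, seed=11)
        assert np.array_equal(a.coral_centers, b.coral_centers)
        assert np.array_equal(a.start, b.start)
        assert np.array_equal(a.target, b.target)

    @pytest.mark.parametrize("seed", range(10))
    def test_endpoints_clear_of_corals(self, seed):
        env = generate_environment(ArenaConfig(n_corals=30), seed=seed)
        r = env.config.coral_radius
        for pt in (env.start, env.target):
            d = np.linalg.norm(env.coral_centers - pt, axis=1)
            assert np.all(d > r)

    def test_json_roundtrip(self, tmp_path):
        env = generate_environment(ArenaConfig(n_corals=5), seed=2)
        path = tmp_path / "env.json"
        env.to_json(path)
        back = Environment.from_json(path)
        assert np.allclose(back.coral_centers, env.coral_centers)
        assert np.allclose(back.start, env.start)


class TestAperture:
    def test_far_coral_vanishes(self):
        assert coral_aperture(1e9, 0.15) < 1e-8

    def test_distance_equals_radius(self):
        assert coral_aperture(0.15, 0.15) == pytest.approx(math.pi / 2)

    def test_arithmetic_oracle(self):
        # 2 * arctan(0.15 / 1.4), computed independently
        assert coral_aperture(1.4, 0.15) == pytest.approx(
            2 * math.atan(0.15 / 1.4), abs=1e-12
        )
        assert coral_aperture(1.4, 0.15) == pytest.approx(0.2135, abs=5e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            coral_aperture(0.0, 0.15)

    @given(
        d1=st.floats(0.2, 10.0),
        d2=st.floats(0.2, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_distance(self, d1, d2):
        if d1 == d2:
            return
        lo, hi = sorted([d1, d2])
        assert coral_aperture(lo, 0.15) > coral_aperture(hi, 0.15)


class TestRayDistance:
    def test_clear_when_nothing_in_range(self, empty_env):
        env = empty_env
        assert distance_along_direction(env, np.zeros(2), 0.0, 1.4) == CLEAR

    def test_ray_circle_oracle(self, single_coral_env):
        # coral radius 0.15 centered 1.0 m dead ahead -> 0.85 m
        d = distance_along_direction(single_coral_env, np.zeros(2), 0.0, 1.4)
        assert d == pytest.approx(0.85, abs=1e-12)

    def test_on_perimeter_looking_in(self, single_coral_env):
        d = distance_along_direction(
            single_coral_env, np.array([0.85, 0.0]), 0.0, 1.4
        )
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_wall_visible(self, empty_env):
        d = distance_along_direction(empty_env, np.array([1.0, 0.0]), 0.0, 1.4)
        assert d == pytest.approx(1.0, abs=1e-12)  # wall at x = 2

    def test_never_exceeds_max_range(self, default_env):
        rng = np.random.default_rng(0)
        for _ in range(100):
            pos = rng.uniform(-1.9, 1.9, 2)
            ang = rng.uniform(-math.pi, math.pi)
            d = distance_along_direction(default_env, pos, ang, 1.4)
            assert d == CLEAR or d <= 1.4 + 1e-12

    def test_matches_dense_sampling_oracle(self, default_env):
        # brute-force: march along the ray and find first boundary crossing
        env = default_env
        rng = np.random.default_rng(1)
        r = env.config.coral_radius
        for _ in range(20):
            pos = rng.uniform(-1.5, 1.5, 2)
            if check_collision(env, pos):
                continue
            ang = rng.uniform(-math.pi, math.pi)
            d = distance_along_direction(env, pos, ang, 1.4)
            ts = np.linspace(0, 1.4, 2801)
            pts = pos + ts[:, None] * np.array([math.cos(ang), math.sin(ang)])
            inside_coral = (
                np.linalg.norm(
                    pts[:, None, :] - env.coral_centers[None], axis=2
                ).min(axis=1)
                < r
            )
            outside_walls = np.any(np.abs(pts) > 2.0, axis=1)
            hits = np.nonzero(inside_coral | outside_walls)[0]
            if len(hits) == 0:
                assert d == CLEAR or d > 1.4 - 2e-3
            else:
                assert d == pytest.approx(ts[hits[0]], abs=2e-3)


class TestAffectedBins:
    def test_out_of_range_coral(self, single_coral_env):
        out = affected_bins(
            single_coral_env, np.array([-1.5, 0.0]), np.array([1.0, 0.0])
        )
        assert out == {}

    def test_narrow_coral_single_bin(self, single_coral_env):
        # aperture at 1.3 m ~ 13 deg < 15 deg bin width, centered on bin 0
        out = affected_bins(
            single_coral_env, np.array([-0.3, 0.0]), np.array([1.0, 0.0])
        )
        assert set(out) == {0}

    def test_aperture_arithmetic_oracle(self, single_coral_env):
        # r=0.15 at d=0.5: aperture covers +-16.7 deg -> 3 bins of 15 deg
        out = affected_bins(
            single_coral_env, np.array([0.5, 0.0]), np.array([1.0, 0.0])
        )
        assert set(out) == {0, 1, 23}

    def test_distances_agree_with_ray_cast(self, single_coral_env):
        env = single_coral_env
        pos = np.array([0.4, 0.1])
        out = affected_bins(env, pos, env.coral_centers[0])
        assert out
        for i, d in out.items():
            ang = i * 2 * math.pi / 24
            assert d == pytest.approx(
                distance_along_direction(env, pos, ang, 1.4), abs=1e-9
            )


class TestCollision:
    def test_at_center(self, single_coral_env):
        assert check_collision(single_coral_env, np.array([1.0, 0.0]))

    def test_exactly_at_radius_is_clear(self):
        env = Environment(
            config=ArenaConfig(n_corals=1),
            coral_centers=np.array([[0.0, 0.0]]),
            start=np.array([-1.0, -1.0]),
            target=np.array([1.0, 1.0]),
        )
        # 0.15 is exactly representable relative to a center at 0
        assert not check_collision(env, np.array([0.15, 0.0]))

    def test_empty_coral_list(self, empty_env):
        assert not check_collision(empty_env, np.zeros(2))


def test_config_invariants():
    with pytest.raises(ValueError):
        ArenaConfig(width=-1)
    with pytest.raises(ValueError):
        ArenaConfig(n_corals=-1)
    with pytest.raises(ValueError):
        ArenaConfig(coral_radius=0)
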