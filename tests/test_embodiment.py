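import math

import numpy as np
import pytest

import magnet
from magnet import embodiment as em
from magnet import netcore


@pytest.fixture()
def behavior():
    return magnet.BehaviorParams()


class TestArena:
    def test_three_zone_layout_is_an_equilateral_triangle(self):
        arena = em.three_zone_layout()
        c = [z.center_cm for z in arena.zones]
        sides = [np.hypot(*(c[i] - c[(i + 1) % 3])) for i in range(3)]
        assert np.allclose(sides, 35.0)
        assert all(z.radius_cm == 3.0 for z in arena.zones)
        assert arena.radius_cm == 33.5

    def test_central_layout(self):
        arena = em.central_zone_layout()
        assert np.allclose(arena.zones[0].center_cm, 0.0)
        assert arena.zones[0].radius_cm == 5.0

    def test_zone_outside_arena_rejected(self):
        with pytest.raises(ValueError):
            em.Arena("circle", radius_cm=20.0,
                     zones=[em.Zone(np.array([25.0, 0.0]), 3.0)])

    def test_containment_and_clamp(self):
        arena = em.Arena("circle", radius_cm=30.0)
        assert arena.contains((29.0, 0.0))
        assert not arena.contains((25.0, 25.0))
        p = arena.clamp(np.array([40.0, 40.0]))
        assert arena.contains(p)
        sq = em.Arena("square", side_cm=70.0)
        assert sq.contains((34.0, -34.0))
        assert not sq.contains((36.0, 0.0))
        assert np.all(np.abs(sq.clamp(np.array([50.0, -50.0]))) <= 35.0)


class TestDecode:
    def test_equal_rates_select_uniformly(self, default_net):
        pm = default_net.place_map
        rng = np.random.default_rng(0)
        rates = np.full(400, 7.0)
        counts = np.zeros(400)
        for _ in range(4000):
            _, idx = em.decode_goal(rates, pm, 0.3, rng)
            counts[idx] += 1
        # every neuron equally likely: chi-square-ish sanity bound
        assert counts.max() < 40
        assert (counts > 0).sum() > 350

    def test_argmax_limit_at_high_beta(self, default_net):
        pm = default_net.place_map
        rng = np.random.default_rng(1)
        rates = np.zeros(400)
        rates[123] = 10.0
        for _ in range(50):
            goal, idx = em.decode_goal(rates, pm, 50.0, rng)
            assert idx == 123
            assert np.allclose(goal, pm.positions_cm[123])

    def test_softmax_frequencies_match_enumeration(self):
        pm = netcore.PlaceFieldMap(np.array([[0.0, 0], [1, 0], [2, 0]]))
        rates = np.array([2.0, 1.0, 0.0])
        beta = 1.0
        probs = np.exp(beta * rates)
        probs /= probs.sum()
        rng = np.random.default_rng(2)
        n = 20_000
        counts = np.zeros(3)
        for _ in range(n):
            _, idx = em.decode_goal(rates, pm, beta, rng)
            counts[idx] += 1
        for k in range(3):
            sd = math.sqrt(n * probs[k] * (1 - probs[k]))
            assert abs(counts[k] - n * probs[k]) < 3 * sd

    def test_non_finite_rates_rejected(self, default_net):
        with pytest.raises(ValueError):
            em.decode_goal(np.full(400, np.nan), default_net.place_map, 0.3,
                           np.random.default_rng(0))


class TestDrives:
    def test_wall_aligned_pose_is_a_default_fixed_point(self, behavior):
        arena = em.Arena("circle", radius_cm=33.5)
        pose = em.Pose(np.array([33.5 - behavior.wall_gap_cm, 0.0]),
                       math.pi / 2, 10.0)
        v, ang, weight = em.default_drive(pose, arena, behavior, circ_dir=1)
        assert weight > 0.9
        assert abs(ang) < 0.3

    def test_default_weight_vanishes_in_the_interior(self, behavior):
        arena = em.Arena("circle", radius_cm=33.5)
        pose = em.Pose(np.zeros(2), 0.4, 5.0)
        _, _, weight = em.default_drive(pose, arena, behavior)
        assert weight < 0.15
        # not wall-aligned and not heading outward: even smaller
        pose = em.Pose(np.array([5.0, 0.0]), math.pi, 5.0)
        _, _, weight = em.default_drive(pose, arena, behavior)
        assert weight < 0.02

    def test_head_on_approach_converges_to_tangent(self, behavior):
        arena = em.Arena("circle", radius_cm=33.5)
        pose = em.Pose(np.array([25.0, 0.0]), 0.0, 12.0)  # heading at the wall
        for _ in range(200):
            dcmd = em.default_drive(pose, arena, behavior, circ_dir=1)
            pose = em.pose_step(pose, dcmd, (0.0, 0.0), 0.05, arena, behavior)
        tangent = arena.outward_bearing(pose.position_cm) + math.pi / 2
        err = (pose.heading_rad - tangent + math.pi) % (2 * math.pi) - math.pi
        assert abs(err) < 0.35
        assert arena.wall_distance(pose.position_cm) < 8.0

    def test_goal_drive_fixed_point_and_turn(self, behavior):
        pose = em.Pose(np.array([3.0, 4.0]), 1.0, 0.0)
        v, ang = em.goal_drive(pose, (3.0, 4.0), behavior)
        assert v == 0.0 and ang == 0.0
        v, ang = em.goal_drive(pose, pose.position_cm
                               + 20 * np.array([math.cos(1.0 + math.pi),
                                                math.sin(1.0 + math.pi)]),
                               behavior)
        assert abs(ang) == behavior.max_turn_rad_s
        assert v == 0.0  # goal directly behind: turn in place

    def test_goal_pursuit_decreases_distance_monotonically(self, behavior):
        arena = em.Arena("circle", radius_cm=33.5)
        goal = np.array([0.0, 0.0])
        pose = em.Pose(np.array([25.0, 0.0]), math.pi, 0.0)  # aligned
        d_prev = 25.0
        for _ in range(100):
            gcmd = em.goal_drive(pose, goal, behavior)
            pose = em.pose_step(pose, (0.0, 0.0, 0.0), gcmd, 0.05, arena,
                                behavior)
            d = float(np.hypot(*pose.position_cm))
            # strictly decreasing until arrival (small motor-inertia overshoot
            # through the goal is allowed below 3 cm)
            assert d <= d_prev + 1e-9 or max(d, d_prev) < 3.0
            d_prev = d
        assert d_prev < 2.0

    def test_pose_step_containment_and_rest(self, behavior):
        arena = em.Arena("circle", radius_cm=33.5)
        pose = em.Pose(np.array([33.0, 0.0]), 0.0, 35.0)  # sprinting at wall
        for _ in range(40):
            pose = em.pose_step(pose, (35.0, 0.0, 1.0), (0.0, 0.0), 0.05,
                                arena, behavior)
            assert arena.contains(pose.position_cm)
        still = em.Pose(np.array([5.0, 5.0]), 0.3, 0.0)
        moved = em.pose_step(still, (0.0, 0.0, 1.0), (0.0, 0.0), 0.05, arena,
                             behavior)
        assert np.allclose(moved.position_cm, still.position_cm)

    def test_wall_following_stays_in_an_annulus(self, behavior):
        arena = em.Arena("circle", radius_cm=33.5)
        pose = em.Pose(np.array([33.5 - behavior.wall_gap_cm, 0.0]),
                       math.pi / 2, behavior.v_default_cms)
        radii = []
        for _ in range(600):
            dcmd = em.default_drive(pose, arena, behavior, circ_dir=1)
            pose = em.pose_step(pose, dcmd, (0.0, 0.0), 0.05, arena, behavior)
            radii.append(float(np.hypot(*pose.position_cm)))
        assert min(radii) > 33.5 - 10.0


class TestClosedLoop:
    def test_zero_duration_yields_empty_records(self, default_net):
        res = em.run_closed_loop(
            default_net, magnet.DAParams(), magnet.PlasticityParams(),
            magnet.central_zone_layout(),
            magnet.Protocol("central_conditioning"), 0.0, seed=0)
        assert len(res.times_s) == 0
        assert res.reward_count == 0
        assert len(res.weight_snapshots) == 2  # initial + final, identical
        assert np.array_equal(res.weight_snapshots[0][1],
                              res.weight_snapshots[1][1])

    def test_sessions_are_deterministic_given_seed(self, default_net):
        w0 = default_net.ee_weights.copy()
        args = (default_net, magnet.DAParams(), magnet.PlasticityParams(),
                magnet.central_zone_layout(),
                magnet.Protocol("central_conditioning", plasticity_on=False))
        a = em.run_closed_loop(*args, 20.0, seed=5)
        default_net.set_ee_weights(w0)
        b = em.run_closed_loop(*args, 20.0, seed=5)
        assert np.array_equal(a.positions_cm, b.positions_cm)
        assert np.array_equal(a.da_trace, b.da_trace)
        assert a.events == b.events

    def test_weights_frozen_when_plasticity_off(self, default_net):
        w0 = default_net.ee_weights.copy()
        em.run_closed_loop(
            default_net, magnet.DAParams(), magnet.PlasticityParams(),
            magnet.central_zone_layout(),
            magnet.Protocol("central_conditioning", plasticity_on=False),
            30.0, seed=3)
        assert np.array_equal(default_net.ee_weights, w0)

    def test_protocol_arena_mismatch_raises(self, default_net):
        with pytest.raises(ValueError):
            em.Protocol("bogus_kind")

    def test_stim_requires_peripheral_protocol(self, default_net):
        with pytest.raises(ValueError):
            em.stim_test(default_net, magnet.DAParams(),
                         magnet.PlasticityParams(),
                         magnet.central_zone_layout(),
                         magnet.Protocol("central_conditioning"), 4, 0)
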