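import math

import numpy as np
import pytest

import magnet
from magnet import embodiment


@pytest.fixture(scope="session")
def default_net():
    """A default network, shared read-mostly across tests."""
    return magnet.build_network(magnet.NetworkParams(), seed=1)


@pytest.fixture()
def tiny_net():
    """Smallest legal network (4 E / 1 I) with full connectivity."""
    params = magnet.NetworkParams(n_exc=4, n_inh=1, p_connect=1.0)
    pm = magnet.netcore.PlaceFieldMap(
        np.array([[-10.0, -10.0], [10.0, -10.0], [-10.0, 10.0], [10.0, 10.0]]))
    return magnet.build_network(params, seed=0, place_map=pm)


def condition_network(seed=1, n_sessions=5, session_s=240.0, reward_cap=8,
                      net=None):
    """Single-reward conditioning to criterion under DA-plasticity: phasic
    DA delivered at chance zone entries consolidates the place-reward
    assembly; delivery stops at the visit criterion.  Returns the trained
    network and the per-session reward counts."""
    net = net or magnet.build_network(magnet.NetworkParams(), seed=seed)
    da = magnet.DAParams()
    pp = magnet.PlasticityParams()
    arena = magnet.central_zone_layout()
    beh = magnet.BehaviorParams()
    pose = None
    rewards = []
    total = 0
    for sess in range(n_sessions):
        proto = magnet.Protocol("central_conditioning",
                                excitability_on=False,
                                max_rewards=max(0, reward_cap - total))
        res = embodiment.run_closed_loop(net, da, pp, arena, proto, session_s,
                                         seed=100 + sess, behavior=beh,
                                         start_pose=pose)
        rewards.append(res.reward_count)
        total += res.reward_count
        pose = res.final_pose
        if total >= reward_cap:
            break
    return net, rewards


@pytest.fixture(scope="session")
def conditioned():
    """Conditioned network shared by the behaviour-level acceptance tests.

    Returns (network, naive weight vector, conditioned weight vector).
    """
    net = magnet.build_network(magnet.NetworkParams(), seed=1)
    w_naive = net.ee_weights.copy()
    net, _ = condition_network(net=net)
    return net, w_naive, net.ee_weights.copy()


def run_probe(net, excitability_on, probe_index, horizon_s=30.0,
              start_radius_cm=30.0):
    """One convergence probe from a random peripheral start with a commanded
    DA train at t = 1 s; returns (hit, start distance, time-to-hit or nan)."""
    da = magnet.DAParams()
    pp = magnet.PlasticityParams()
    arena = magnet.central_zone_layout()
    beh = magnet.BehaviorParams()
    proto = magnet.Protocol("free_run", plasticity_on=False,
                            excitability_on=excitability_on)
    rng = np.random.default_rng(5000 + probe_index)
    ang = rng.uniform(-math.pi, math.pi)
    pose = embodiment.Pose(
        np.array([start_radius_cm * math.cos(ang),
                  start_radius_cm * math.sin(ang)]),
        rng.uniform(-math.pi, math.pi), 0.0)
    res = embodiment.run_closed_loop(
        net, da, pp, arena, proto, horizon_s, seed=9000 + probe_index,
        behavior=beh, start_pose=pose, initial_events=(("stimulation", 1.0),),
        stop_on_zone_entry=True)
    d = np.hypot(*res.positions_cm.T)
    n_expected = int(round(horizon_s * 1000.0 / beh.frame_ms))
    # a truncated record means the session ended on zone entry
    hit = len(res.times_s) < n_expected or bool(
        (d <= arena.zones[0].radius_cm).any())
    t_hit = float(res.times_s[-1]) if hit else math.nan
    return hit, float(d[0]), t_hit
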