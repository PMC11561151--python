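"""Action-perception loop: arena, navigation drives, closed-loop sessions.

The agent ("e-mouse") navigates a 2-D arena.  Its position feeds Gaussian
place-field currents into the recurrent network; the network's instantaneous
rates are decoded into an internal goal by a stochastic soft-max over the
neurons' preferred positions; linear-speed and angular commands blend a
default wall-following behaviour with goal-directed convergence; entering a
rewarded zone triggers a phasic dopamine train under the protocol's re-arm
rules.  Dopamine in turn gates plasticity (slowly building a goal-encoding
assembly) and transiently scales NMDA conductances (igniting that assembly,
which moves the decoded goal to the rewarded location and elicits a directed,
energized run).

Behaviour is updated on 50-ms frames (matching 20-fps video tracking); the
network is sub-stepped at 0.5 ms between frames.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import damod, netcore, plasticity

__all__ = [
    "Zone",
    "Arena",
    "Pose",
    "Protocol",
    "BehaviorParams",
    "SessionResult",
    "decode_goal",
    "default_drive",
    "goal_drive",
    "pose_step",
    "run_closed_loop",
    "stim_test",
    "align_events",
    "three_zone_layout",
    "central_zone_layout",
]


@dataclass
class Zone:
    center_cm: np.ndarray
    radius_cm: float

    def contains(self, position_cm) -> bool:
        return float(np.hypot(*(np.asarray(position_cm) - self.center_cm))) \
            <= self.radius_cm


@dataclass
class Arena:
    """Circular or square open field with optional reward zones."""

    shape: str = "circle"          # "circle" | "square"
    radius_cm: float = 33.5        # circle: 67-cm diameter open field
    side_cm: float = 70.0          # square: 70-cm side
    zones: list = field(default_factory=list)
    context_id: str = "R"

    def __post_init__(self):
        if self.shape not in ("circle", "square"):
            raise ValueError("arena shape must be 'circle' or 'square'")
        for z in self.zones:
            z.center_cm = np.asarray(z.center_cm, dtype=float)
            if not self.contains(z.center_cm):
                raise ValueError("reward zone lies outside the arena")

    @property
    def half_extent_cm(self) -> float:
        return self.radius_cm if self.shape == "circle" else self.side_cm / 2.0

    def contains(self, position_cm) -> bool:
        p = np.asarray(position_cm, dtype=float)
        if self.shape == "circle":
            return float(np.hypot(*p)) <= self.radius_cm + 1e-9
        h = self.side_cm / 2.0
        return bool(np.all(np.abs(p) <= h + 1e-9))

    def clamp(self, position_cm: np.ndarray, margin_cm: float = 0.5) -> np.ndarray:
        p = np.asarray(position_cm, dtype=float)
        if self.shape == "circle":
            r = float(np.hypot(*p))
            rmax = self.radius_cm - margin_cm
            if r > rmax:
                p = p * (rmax / r)
            return p
        h = self.side_cm / 2.0 - margin_cm
        return np.clip(p, -h, h)

    def wall_distance(self, position_cm) -> float:
        p = np.asarray(position_cm, dtype=float)
        if self.shape == "circle":
            return self.radius_cm - float(np.hypot(*p))
        h = self.side_cm / 2.0
        return float(min(h - abs(p[0]), h - abs(p[1])))

    def outward_bearing(self, position_cm) -> float:
        """Bearing (rad, ccw from +x) of the nearest wall from this position."""
        p = np.asarray(position_cm, dtype=float)
        if self.shape == "circle":
            if np.hypot(*p) < 1e-9:
                return 0.0
            return math.atan2(p[1], p[0])
        h = self.side_cm / 2.0
        gaps = [h - p[0], p[0] + h, h - p[1], p[1] + h]  # +x, -x, +y, -y walls
        return (0.0, math.pi, math.pi / 2.0, -math.pi / 2.0)[int(np.argmin(gaps))]


def three_zone_layout(radius_cm: float = 33.5, side_cm: float = 35.0,
                      zone_radius_cm: float = 3.0) -> Arena:
    """Circular arena with three zones on an equilateral triangle."""
    circum = side_cm / math.sqrt(3.0)
    zones = [Zone(np.array([circum * math.cos(a), circum * math.sin(a)]),
                  zone_radius_cm)
             for a in (math.pi / 2, math.pi / 2 + 2 * math.pi / 3,
                       math.pi / 2 + 4 * math.pi / 3)]
    return Arena("circle", radius_cm=radius_cm, zones=zones)


def central_zone_layout(radius_cm: float = 33.5,
                        zone_radius_cm: float = 5.0) -> Arena:
    """Circular arena with a single central reward zone."""
    return Arena("circle", radius_cm=radius_cm,
                 zones=[Zone(np.zeros(2), zone_radius_cm)])


@dataclass
class Pose:
    position_cm: np.ndarray
    heading_rad: float
    speed_cms: float = 0.0


@dataclass
class Protocol:
    """Session protocol: reward/stimulation policy and condition flags.

    ``plasticity_on`` gates consolidation of eligibility traces (weights are
    frozen when off); ``excitability_on`` gates the DA -> NMDA coupling (the
    gain is pinned at 1 when off).  DA release events themselves always occur.
    """

    kind: str  # three_location_conditioning | central_conditioning |
               # peripheral_stim_test | photoinhibition_test | free_run
    plasticity_on: bool = True
    excitability_on: bool = True
    rearm_distance_cm: float = 10.0
    stim_min_distance_cm: float = 10.0
    sham_prob: float = 0.5
    stim_interval_s: float = 12.0
    inhibition_interval_s: float = 8.0
    rewards_enabled: bool = True
    reward_pause_s: float = 2.5    # consummatory pause at the rewarded site
    max_rewards: int | None = None  # conditioning-to-criterion: delivery stops
                                    # after this many rewards in the session

    KINDS = ("three_location_conditioning", "central_conditioning",
             "peripheral_stim_test", "photoinhibition_test", "free_run")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")


@dataclass
class BehaviorParams:
    """Free parameters of the motor layer; the defaults were calibrated to
    produce mouse-like open-field statistics (wall-following at a moderate
    pace with interior incursions, ballistic goal runs)."""

    frame_ms: float = 50.0
    dt_ms: float = 0.5
    beta: float = 0.3                 # soft-max inverse temperature (per Hz)
    rate_tau_ms: float = 150.0        # exponential rate-estimate window
    v_max_cms: float = 35.0
    v_default_cms: float = 12.0
    decel_distance_cm: float = 8.0    # goal approach deceleration scale
    tau_speed_s: float = 0.25         # speed command low-pass (motor inertia)
    k_turn: float = 6.0               # angular gain (rad/s per rad of error)
    max_turn_rad_s: float = 8.0
    wall_lambda_cm: float = 6.0       # proximity scale of the default weight
    approach_lambda_cm: float = 14.0  # range of the heading-toward-wall term
    wall_gap_cm: float = 3.0          # preferred circling gap from the wall
    k_gap: float = 0.08               # gap-error to steering correction (rad/cm)
    goal_deadzone_cm: float = 5.0     # decoded goals closer than this are
                                      # treated as "goal = own position"
    goal_salience_cm: float = 5.0     # additional separation for full override
    goal_persistence_frames: int = 6  # goal drive engages only after the
                                      # decoded goal has stayed salient this
                                      # many consecutive frames
    goal_release_frames: int = 10     # and disengages only after this many
                                      # consecutive non-salient frames
                                      # (behavioural commitment)
    goal_commit_floor: float = 0.4    # minimum goal weight while committed
    incursion_rate_hz: float = 0.12  # random heading perturbations (interior forays)
    incursion_hold_s: float = 3.5
    elig_every: int = 8               # eligibility substep (in units of dt)


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def decode_goal(rates_hz: np.ndarray, place_map: netcore.PlaceFieldMap,
                beta: float, rng: np.random.Generator):
    """Stochastic soft-max goal decode over preferred positions.

    Neuron i is selected with probability exp(beta * rate_i) normalized over
    the population; the internal goal is its preferred position.  Returns
    (goal position, selected neuron index).
    """
    r = np.asarray(rates_hz, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite rates passed to decode_goal")
    logits = beta * r
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    idx = int(rng.choice(len(p), p=p))
    return place_map.positions_cm[idx].copy(), idx


def default_drive(pose: Pose, arena: Arena, params: BehaviorParams,
                  circ_dir: int = 1):
    """Wall-following drive: (speed command, angular command, weight).

    The weight is near 1 on the wall or when heading toward a nearby wall and
    decays to ~0 in the interior with non-wall headings.  The angular command
    steers toward the wall tangent (in the persistent circling direction)
    with a small correction that maintains a preferred gap from the wall.
    """
    d_wall = arena.wall_distance(pose.position_cm)
    outward = arena.outward_bearing(pose.position_cm)
    prox = math.exp(-max(d_wall - params.wall_gap_cm, 0.0) / params.wall_lambda_cm)
    approach = max(0.0, math.cos(pose.heading_rad - outward)) * \
        math.exp(-max(d_wall - params.wall_gap_cm, 0.0) / params.approach_lambda_cm)
    weight = min(1.0, max(prox, approach))

    tangent = outward + circ_dir * math.pi / 2.0
    gap_err = d_wall - params.wall_gap_cm            # positive: too far from wall
    correction = max(-math.pi / 3, min(math.pi / 3, params.k_gap * gap_err))
    desired = tangent - circ_dir * correction        # steer outward when too far
    ang = params.k_turn * _wrap_angle(desired - pose.heading_rad)
    ang = max(-params.max_turn_rad_s, min(params.max_turn_rad_s, ang))
    return params.v_default_cms, ang, weight


def goal_drive(pose: Pose, goal_cm, params: BehaviorParams):
    """Goal-directed drive: (speed command, angular command).

    Speed follows a ballistic profile: proportional to heading alignment with
    the goal, saturating at v_max far away, decelerating within
    ``decel_distance_cm`` and zero at the goal.
    """
    g = np.asarray(goal_cm, dtype=float)
    delta = g - pose.position_cm
    dist = float(np.hypot(*delta))
    if dist < 1e-9:
        return 0.0, 0.0
    bearing = math.atan2(delta[1], delta[0])
    err = _wrap_angle(bearing - pose.heading_rad)
    ang = params.k_turn * err
    ang = max(-params.max_turn_rad_s, min(params.max_turn_rad_s, ang))
    speed = params.v_max_cms * min(1.0, dist / params.decel_distance_cm) * \
        max(0.0, math.cos(err))
    return speed, ang


def pose_step(pose: Pose, default_cmd, goal_cmd, dt_s: float, arena: Arena,
              params: BehaviorParams, weight: float | None = None) -> Pose:
    """Blend the two drives by the default weight and integrate the pose.

    ``default_cmd`` is (speed, angular, weight) from :func:`default_drive`
    (the weight can be overridden), ``goal_cmd`` is (speed, angular).  The
    position is always projected back inside the arena.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    v_def, w_def, w = default_cmd
    if weight is not None:
        w = weight
    v_goal, w_goal = goal_cmd
    v_cmd = w * v_def + (1.0 - w) * v_goal
    ang = w * w_def + (1.0 - w) * w_goal

    speed = pose.speed_cms + (v_cmd - pose.speed_cms) * min(
        1.0, dt_s / params.tau_speed_s)
    speed = max(0.0, min(params.v_max_cms, speed))
    heading = _wrap_angle(pose.heading_rad + ang * dt_s)
    pos = pose.position_cm + speed * dt_s * np.array(
        [math.cos(heading), math.sin(heading)])
    pos = arena.clamp(pos)
    return Pose(pos, heading, speed)


@dataclass
class SessionResult:
    """Time-aligned record of one closed-loop session (50-ms frames)."""

    times_s: np.ndarray
    positions_cm: np.ndarray          # (n_frames, 2)
    goals_cm: np.ndarray              # (n_frames, 2)
    da_trace: np.ndarray              # concentration per frame
    gain_trace: np.ndarray            # effective NMDA gain per frame
    events: list                      # (time_s, kind, info) tuples
    spikes: netcore.SpikeRecord | None
    weight_snapshots: list            # (time_s, ee_weight vector) pairs
    seed: int
    final_pose: Pose
    reward_count: int

    def trajectory_frame(self):
        """Trajectory as a tidy DataFrame (time_s, x_cm, y_cm, event)."""
        import pandas as pd

        ev = np.full(len(self.times_s), "", dtype=object)
        marker = {"reward": "reward_entry", "stim": "stim", "sham": "sham",
                  "inhibition": "inhibition"}
        dt = self.times_s[1] - self.times_s[0] if len(self.times_s) > 1 else 0.05
        for t, kind, _ in self.events:
            if kind in marker and len(self.times_s):
                i = min(len(self.times_s) - 1, max(0, int(round(t / dt))))
                ev[i] = marker[kind]
        return pd.DataFrame({"time_s": self.times_s,
                             "x_cm": self.positions_cm[:, 0],
                             "y_cm": self.positions_cm[:, 1],
                             "event": ev})


class _ProtocolState:
    """Zone arming, scheduled experimenter events, incursion timer."""

    def __init__(self, protocol: Protocol, arena: Arena,
                 rng: np.random.Generator):
        self.protocol = protocol
        self.arena = arena
        self.rng = rng
        self.central_armed = True
        self.last_rewarded_zone = -1
        self.next_stim_s = rng.exponential(protocol.stim_interval_s) \
            if protocol.kind == "peripheral_stim_test" else math.inf
        self.next_inhib_s = protocol.inhibition_interval_s \
            if protocol.kind == "photoinhibition_test" else math.inf

    def _reference_center(self) -> np.ndarray:
        if self.arena.zones:
            return self.arena.zones[0].center_cm
        return np.zeros(2)

    def check_rewards(self, pos: np.ndarray) -> int | None:
        """Returns the zone index rewarded at this frame, or None."""
        if not (self.protocol.rewards_enabled and self.arena.zones):
            return None
        if self.protocol.kind in ("central_conditioning", "peripheral_stim_test",
                                  "photoinhibition_test", "free_run"):
            zone = self.arena.zones[0]
            d_center = float(np.hypot(*(pos - zone.center_cm)))
            if d_center >= self.protocol.rearm_distance_cm:
                self.central_armed = True
            if self.central_armed and zone.contains(pos):
                self.central_armed = False
                return 0
            return None
        # three-location alternation: the zone just rewarded is disarmed
        for zi, zone in enumerate(self.arena.zones):
            if zone.contains(pos):
                if zi != self.last_rewarded_zone:
                    self.last_rewarded_zone = zi
                    return zi
                return None
        return None

    def check_stim(self, t_s: float, pos: np.ndarray) -> str | None:
        """Experimenter stimulation with the >10-cm distance rule, 50% sham."""
        if t_s < self.next_stim_s:
            return None
        d = float(np.hypot(*(pos - self._reference_center())))
        if d <= self.protocol.stim_min_distance_cm:
            return None                   # wait until the rule is satisfied
        self.next_stim_s = t_s + self.rng.exponential(
            self.protocol.stim_interval_s)
        return "sham" if self.rng.random() < self.protocol.sham_prob else "stim"

    def check_inhibition(self, t_s: float) -> bool:
        if t_s < self.next_inhib_s:
            return False
        self.next_inhib_s = t_s + self.protocol.inhibition_interval_s
        return True


def run_closed_loop(net: netcore.Network,
                    da_params: damod.DAParams,
                    plast_params: plasticity.PlasticityParams,
                    arena: Arena,
                    protocol: Protocol,
                    duration_s: float,
                    seed: int,
                    behavior: BehaviorParams | None = None,
                    start_pose: Pose | None = None,
                    net_state: netcore.NetworkState | None = None,
                    da_state: damod.DAState | None = None,
                    elig: plasticity.EligibilityState | None = None,
                    record_spikes: bool = False,
                    snapshot_interval_s: float | None = None,
                    initial_events: tuple = (),
                    stop_on_zone_entry: bool = False) -> SessionResult:
    """Run one closed-loop session and return its time-aligned record.

    Sessions can be chained by passing the previous session's states back in;
    the network's plastic weights live in ``net`` and persist across calls.
    ``initial_events`` may schedule commanded DA events, e.g.
    ``(("stimulation", 1.0),)`` delivers a stimulation train at t = 1 s.
    With ``stop_on_zone_entry`` the session ends at the first zone entry
    (used for convergence probes; the records are truncated accordingly).
    """
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    behavior = behavior or BehaviorParams()
    da_params.validate()
    plast_params.validate()

    ss = np.random.SeedSequence(seed)
    rng_bg, rng_decode, rng_proto, rng_da, rng_init = [
        np.random.default_rng(s) for s in ss.spawn(5)]

    p = net.params
    ne = p.n_exc
    dt = behavior.dt_ms
    substeps = int(round(behavior.frame_ms / dt))
    n_frames = int(round(duration_s * 1000.0 / behavior.frame_ms))
    delay_steps = max(1, int(round(p.synaptic_delay_ms / dt)))

    if net_state is None:
        net_state = netcore.NetworkState.initial(net, dt, rng_init)
    if da_state is None:
        da_state = damod.DAState.at_baseline(da_params)
    if elig is None:
        elig = plasticity.EligibilityState(net.ee_pre, net.ee_post, ne)
    if start_pose is None:
        ang = rng_init.uniform(-math.pi, math.pi)
        r = arena.half_extent_cm - 3.0
        start_pose = Pose(np.array([r * math.cos(ang), r * math.sin(ang)]),
                          _wrap_angle(ang + math.pi / 2), 0.0)
    pose = start_pose

    for kind, t_s in initial_events:
        damod.command_phasic(da_state, da_params, kind, t_s * 1000.0)

    proto_state = _ProtocolState(protocol, arena, rng_proto)
    rate = np.zeros(p.n_total)                      # exponential rate estimate, Hz
    rate_decay = math.exp(-dt / behavior.rate_tau_ms)
    rate_jump = 1000.0 / behavior.rate_tau_ms
    pre_queue = deque([np.empty(0, dtype=np.int64)] * delay_steps,
                      maxlen=delay_steps)
    ee_w = net.ee_weights
    i_ff = np.zeros(p.n_total)

    times = np.arange(n_frames) * behavior.frame_ms * 1e-3
    positions = np.zeros((n_frames, 2))
    goals = np.zeros((n_frames, 2))
    da_trace = np.zeros(n_frames)
    gain_trace = np.ones(n_frames)
    events: list = []
    spike_chunks: list = []
    snapshots: list = [(0.0, ee_w.copy())]
    reward_count = 0
    incursion_until_s = -1.0
    pause_until_s = -1.0
    goal_far_frames = 0
    goal_near_frames = 0
    goal_engaged = False
    circ_dir = 1 if rng_init.random() < 0.5 else -1
    p_spont = da_params.spontaneous_rate_hz * dt * 1e-3

    for f in range(n_frames):
        t_s = f * behavior.frame_ms * 1e-3
        i_ff[:ne] = netcore.place_input(pose.position_cm, net.place_map)

        for sub in range(substeps):
            evs = ()
            if p_spont > 0.0 and rng_da.random() < p_spont:
                evs = (("spontaneous", da_params.pulse_amplitude),)
            damod.da_step(da_state, da_params, dt, evs)
            gain = damod.nmda_gain(da_state.concentration, da_params) \
                if protocol.excitability_on else 1.0
            spikers = netcore.network_step(net, net_state, i_ff, gain, dt, rng_bg)
            rate *= rate_decay
            if spikers.size:
                rate[spikers] += rate_jump
                if record_spikes:
                    spike_chunks.append(
                        (spikers.copy(),
                         np.full(spikers.size, net_state.t_ms - dt)))
            if protocol.plasticity_on:
                exc_spikers = spikers[spikers < ne]
                delivered = pre_queue[0]
                pre_queue.append(exc_spikers)
                plasticity.calcium_step(elig, plast_params, delivered,
                                        exc_spikers, dt)
                if (sub + 1) % behavior.elig_every == 0:
                    dt_e = behavior.elig_every * dt
                    plasticity.eligibility_step(elig, plast_params, dt_e)
                    da_eff = max(da_state.concentration
                                 - plast_params.consolidation_threshold, 0.0)
                    ee_w = plasticity.consolidate_step(
                        ee_w, elig, plast_params, da_eff, dt_e, True)
        if protocol.plasticity_on:
            # weights drift slowly; pushing them into the dense propagation
            # matrix once per behaviour frame is sufficient
            net.set_ee_weights(ee_w)

        positions[f] = pose.position_cm
        da_trace[f] = da_state.concentration
        gain_trace[f] = damod.nmda_gain(da_state.concentration, da_params) \
            if protocol.excitability_on else 1.0

        goal, _ = decode_goal(rate[:ne], net.place_map, behavior.beta, rng_decode)
        goals[f] = goal

        dcmd = default_drive(pose, arena, behavior, circ_dir)
        gcmd = goal_drive(pose, goal, behavior)
        goal_sep = float(np.hypot(*(goal - pose.position_cm)))
        salience = min(1.0, max(0.0, goal_sep - behavior.goal_deadzone_cm)
                       / behavior.goal_salience_cm)
        # behavioural commitment with hysteresis: a goal must stay salient
        # for several consecutive frames before it takes over from the
        # default drive (transient decode flickers do not move the e-mouse),
        # and an engaged approach survives brief non-salient flickers so it
        # can be carried through to the goal
        if salience > 0.0:
            goal_far_frames += 1
            goal_near_frames = 0
        else:
            goal_far_frames = 0
            goal_near_frames += 1
        if not goal_engaged and \
                goal_far_frames >= behavior.goal_persistence_frames:
            goal_engaged = True
        elif goal_engaged and \
                goal_near_frames >= behavior.goal_release_frames:
            goal_engaged = False
        if not goal_engaged:
            salience = 0.0
        else:
            salience = max(salience, behavior.goal_commit_floor)
        w_eff = dcmd[2] * (1.0 - salience)
        if t_s < incursion_until_s:
            # interior foray: a straight dash replaces wall following at full
            # weight; a salient distant goal can still take over
            dcmd = (1.5 * behavior.v_default_cms, 0.0, 1.0)
            w_eff = 1.0 - salience
        elif rng_proto.random() < behavior.incursion_rate_hz * behavior.frame_ms * 1e-3:
            # heading perturbation starting a straight dash; no re-trigger
            # while a dash is in progress
            incursion_until_s = t_s + behavior.incursion_hold_s
            pose = Pose(pose.position_cm,
                        rng_proto.uniform(-math.pi, math.pi), pose.speed_cms)
        if t_s < pause_until_s:
            dcmd = (0.0, 0.0, 1.0)
            gcmd = (0.0, 0.0)
            w_eff = 1.0
        pose = pose_step(pose, dcmd, gcmd, behavior.frame_ms * 1e-3, arena,
                         behavior, weight=w_eff)

        zone_hit = proto_state.check_rewards(pose.position_cm)
        if zone_hit is not None and protocol.max_rewards is not None \
                and reward_count >= protocol.max_rewards:
            zone_hit = None
        if zone_hit is not None:
            reward_count += 1
            pause_until_s = t_s + protocol.reward_pause_s
            events.append((t_s, "reward", zone_hit))
            damod.command_phasic(da_state, da_params, "stimulation",
                                 net_state.t_ms)
            da_state.events[-1] = damod.DAEvent(net_state.t_ms, "reward",
                                                da_params.pulse_amplitude)
        first_entry = (stop_on_zone_entry and arena.zones
                       and arena.zones[0].contains(pose.position_cm))
        if first_entry:
            n_frames = f + 1
            times = times[:n_frames]
            positions = positions[:n_frames]
            goals = goals[:n_frames]
            da_trace = da_trace[:n_frames]
            gain_trace = gain_trace[:n_frames]
            break
        stim_kind = proto_state.check_stim(t_s, pose.position_cm)
        if stim_kind is not None:
            d_trig = float(np.hypot(*(pose.position_cm
                                      - proto_state._reference_center())))
            events.append((t_s, stim_kind, d_trig))
            if stim_kind == "stim":
                damod.command_phasic(da_state, da_params, "stimulation",
                                     net_state.t_ms)
        if proto_state.check_inhibition(t_s):
            events.append((t_s, "inhibition", None))
            damod.command_phasic(da_state, da_params, "inhibition",
                                 net_state.t_ms)

        if snapshot_interval_s and (f + 1) % int(round(
                snapshot_interval_s * 1000 / behavior.frame_ms)) == 0:
            snapshots.append((t_s, net.ee_weights.copy()))

    snapshots.append((duration_s, net.ee_weights.copy()))
    spikes = netcore.SpikeRecord.from_chunks(spike_chunks) if record_spikes else None
    return SessionResult(times, positions, goals, da_trace, gain_trace,
                         events, spikes, snapshots, seed, pose, reward_count)


def align_events(result: SessionResult, kinds=("stim", "sham"),
                 pre_s: float = 5.0, post_s: float = 10.0) -> list:
    """Extract event-aligned trajectory windows from a session record.

    Each returned dict holds the event kind, its time, the trigger distance
    stored by the protocol, and views of the position / DA / goal series over
    [t - pre_s, t + post_s] together with the within-window index of the
    event frame.  Events whose window overflows the session are dropped.
    """
    frame_s = result.times_s[1] - result.times_s[0] if len(result.times_s) > 1 \
        else 0.05
    n_pre = int(round(pre_s / frame_s))
    n_post = int(round(post_s / frame_s))
    out = []
    for t, kind, info in result.events:
        if kind not in kinds:
            continue
        i = int(round(t / frame_s))
        if i - n_pre < 0 or i + n_post >= len(result.times_s):
            continue
        sl = slice(i - n_pre, i + n_post + 1)
        out.append({
            "kind": kind,
            "time_s": t,
            "trigger_distance_cm": info,
            "event_index": n_pre,
            "times_s": result.times_s[sl] - t,
            "positions_cm": result.positions_cm[sl],
            "da": result.da_trace[sl],
        })
    return out


def stim_test(net: netcore.Network,
              da_params: damod.DAParams,
              plast_params: plasticity.PlasticityParams,
              arena: Arena,
              protocol: Protocol,
              n_events: int,
              seed: int,
              behavior: BehaviorParams | None = None,
              pre_s: float = 5.0,
              post_s: float = 10.0,
              max_duration_s: float = 1200.0):
    """Run a peripheral-stimulation test session and align its events.

    Stimulations are triggered only when the agent is more than the
    protocol's minimum distance from the reference (rewarded/central) point,
    and half of them are shams.  Returns ``(session, aligned)`` where
    ``aligned`` is the list produced by :func:`align_events`, truncated to
    ``n_events``.
    """
    if protocol.kind != "peripheral_stim_test":
        raise ValueError("stim_test requires a peripheral_stim_test protocol")
    duration = min(max_duration_s,
                   (n_events + 2) * protocol.stim_interval_s + pre_s + post_s)
    session = run_closed_loop(net, da_params, plast_params, arena, protocol,
                              duration, seed, behavior=behavior)
    aligned = align_events(session, ("stim", "sham"), pre_s, post_s)
    return session, aligned[:n_events]
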