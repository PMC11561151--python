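"""Recurrent spiking network: LIF dynamics, synaptic currents, inputs.

The goal-encoding circuit is a sparse recurrent network of leaky
integrate-and-fire neurons, 4 excitatory (E) cells per inhibitory (I) cell,
with conductance-based AMPA/NMDA recurrent excitation and GABA-A/GABA-B
recurrent inhibition, a uniform conduction delay, and E/I current balance
enforced at each postsynaptic neuron when the network is built.

Excitatory neurons are arranged on a square lattice of place fields covering
the arena: each receives a feed-forward AMPA current proportional to a
Gaussian of the distance between the agent and the neuron's preferred
position, and in turn biases the decoded internal goal toward that position.
A second feed-forward stream is an exponentially filtered Gaussian noise
(Ornstein-Uhlenbeck) background current.  Excitatory cells also carry a
spike-triggered adaptive threshold.

Units: time ms, voltage mV, conductance nS, capacitance pF, current pA,
space cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MembraneParams",
    "AdaptiveThresholdParams",
    "ReceptorParams",
    "BackgroundParams",
    "PlaceFieldMap",
    "NetworkParams",
    "Network",
    "NetworkState",
    "SpikeRecord",
    "build_network",
    "build_place_map",
    "place_input",
    "background_input_step",
    "network_step",
    "firing_rates",
    "lif_isi_closed_form",
]


@dataclass
class MembraneParams:
    capacitance_pf: float = 250.0
    leak_ns: float = 12.5              # tau_m = 20 ms
    leak_reversal_mv: float = -70.0
    reset_mv: float = -60.0
    threshold_mv: float = -50.0
    refractory_ms: float = 2.0


@dataclass
class AdaptiveThresholdParams:
    """Spike-triggered threshold increment of excitatory neurons."""

    increment_mv: float = 0.2
    tau_ms: float = 1200.0


@dataclass
class ReceptorParams:
    gbar_ns: float
    reversal_mv: float
    tau_ms: float


@dataclass
class BackgroundParams:
    """Exponentially filtered Gaussian noise current (OU process)."""

    mean_pa: float = 200.0
    sd_pa: float = 45.0
    tau_ms: float = 10.0


@dataclass
class PlaceFieldMap:
    """Preferred positions of excitatory neurons on a square lattice.

    The lattice covers the bounding square of the arena; ``sigma_cm`` is the
    Gaussian receptive-field width and ``gain_pa`` the peak feed-forward
    current a neuron receives when the agent sits on its preferred position.
    """

    positions_cm: np.ndarray     # (n_exc, 2)
    sigma_cm: float = 5.0
    gain_pa: float = 500.0

    def __post_init__(self):
        if self.sigma_cm <= 0:
            raise ValueError("place-field width must be positive")


@dataclass
class NetworkParams:
    n_exc: int = 400
    n_inh: int = 100
    p_connect: float = 0.2
    membrane: MembraneParams = field(default_factory=MembraneParams)
    adaptive_threshold: AdaptiveThresholdParams = field(
        default_factory=AdaptiveThresholdParams)
    ampa: ReceptorParams = field(
        default_factory=lambda: ReceptorParams(0.30, 0.0, 2.0))
    nmda: ReceptorParams = field(
        default_factory=lambda: ReceptorParams(0.18, 0.0, 100.0))
    nmda_saturation: float = 0.63  # per-release channel-occupancy increment;
                                   # NMDA gating saturates at 1 per presynaptic
                                   # neuron, making rate transfer sublinear
    gaba_a: ReceptorParams = field(
        default_factory=lambda: ReceptorParams(4.0, -70.0, 5.0))
    gaba_b: ReceptorParams = field(
        default_factory=lambda: ReceptorParams(0.02, -90.0, 150.0))
    synaptic_delay_ms: float = 1.5
    background: BackgroundParams = field(default_factory=BackgroundParams)
    background_inh_mean_pa: float = 200.0  # I cells sit slightly closer to threshold
    heterogeneity_pa: float = 15.0  # quenched spread of background means,
                                    # desynchronizes population responses
    w_init: float = 0.3
    w_max: float = 8.0
    e_to_i_factor: float = 3.0   # E->I synapses are stronger than E->E base
                                 # weights, recruiting feedback inhibition early
    inh_nmda: bool = False       # fast-spiking interneurons are AMPA-dominated;
                                 # recurrent NMDA (and its DA modulation) then
                                 # acts on excitatory cells only
    mg_block: bool = False       # optional NMDA voltage dependence, off by default
    balance_rate_ratio: float = 0.6   # assumed E-to-I rate ratio in the balance rule

    def validate(self) -> None:
        if self.n_inh <= 0 or self.n_exc != 4 * self.n_inh:
            raise ValueError("E/I ratio must be 4 (n_exc = 4 * n_inh)")
        if not 0.0 < self.p_connect <= 1.0:
            raise ValueError("p_connect must lie in (0, 1]")
        if self.membrane.refractory_ms < 0:
            raise ValueError("refractory period must be >= 0")
        for r in (self.ampa, self.nmda, self.gaba_a, self.gaba_b):
            if r.tau_ms <= 0:
                raise ValueError("receptor time constants must be positive")
        if self.synaptic_delay_ms <= 0:
            raise ValueError("synaptic delay must be positive")

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh


@dataclass
class Network:
    """Built network: weights, plastic-edge list, place map."""

    params: NetworkParams
    W_exc: np.ndarray            # dense (n_total, n_exc), 0 where unconnected
    W_inh: np.ndarray            # dense (n_total, n_inh), balance-scaled, fixed
    ee_pre: np.ndarray           # plastic E->E edge presynaptic indices
    ee_post: np.ndarray          # plastic E->E edge postsynaptic indices
    place_map: PlaceFieldMap
    bg_offset_pa: np.ndarray | None = None   # quenched per-neuron drive offsets

    @property
    def ee_weights(self) -> np.ndarray:
        return self.W_exc[self.ee_post, self.ee_pre]

    def set_ee_weights(self, values: np.ndarray) -> None:
        self.W_exc[self.ee_post, self.ee_pre] = values


class SpikeRecord:
    """Flat record of (neuron id, spike time in ms) events."""

    def __init__(self, neuron_ids=(), times_ms=()):
        self.neuron_ids = np.asarray(neuron_ids, dtype=np.int32)
        self.times_ms = np.asarray(times_ms, dtype=np.float64)

    @classmethod
    def from_chunks(cls, chunks) -> "SpikeRecord":
        ids = [c[0] for c in chunks]
        ts = [c[1] for c in chunks]
        if not ids:
            return cls()
        return cls(np.concatenate(ids), np.concatenate(ts))

    def __len__(self) -> int:
        return len(self.times_ms)


def build_place_map(n_exc: int, arena_half_extent_cm: float,
                    sigma_cm: float = 5.0, gain_pa: float = 500.0) -> PlaceFieldMap:
    """Square lattice of preferred positions covering the arena bounding box."""
    side = int(round(math.sqrt(n_exc)))
    if side * side != n_exc:
        raise ValueError("n_exc must be a perfect square for the lattice")
    coords = np.linspace(-arena_half_extent_cm, arena_half_extent_cm, side)
    xx, yy = np.meshgrid(coords, coords)
    pos = np.column_stack([xx.ravel(), yy.ravel()])
    return PlaceFieldMap(pos, sigma_cm, gain_pa)


def build_network(params: NetworkParams, seed: int,
                  place_map: PlaceFieldMap | None = None,
                  arena_half_extent_cm: float = 33.5) -> Network:
    """Draw Bernoulli connectivity and balance inhibition.

    Every ordered pair (no self-connections) is connected independently with
    probability ``p_connect``.  Excitatory weights start at ``w_init``;
    inhibitory weights are rescaled once, per postsynaptic neuron, so that the
    expected inhibitory recurrent current cancels the expected excitatory
    recurrent current at a reference voltage midway between rest and
    threshold (E/I current balance in expectation).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    ne, ni, n = params.n_exc, params.n_inh, params.n_total

    conn_e = rng.random((n, ne)) < params.p_connect
    conn_i = rng.random((n, ni)) < params.p_connect
    idx = np.arange(ne)
    conn_e[idx, idx] = False                       # no E self-connections
    conn_i[ne + np.arange(ni), np.arange(ni)] = False  # no I self-connections

    W_exc = np.where(conn_e, params.w_init, 0.0)
    W_exc[ne:, :] *= params.e_to_i_factor
    W_inh = np.where(conn_i, 1.0, 0.0)

    # E/I current balance: scale each neuron's inhibitory row so expected
    # inhibitory charge matches expected excitatory charge at V_ref.
    m = params.membrane
    v_ref = 0.5 * (m.leak_reversal_mv + m.threshold_mv)
    q_ampa = params.ampa.gbar_ns * params.ampa.tau_ms * \
        (params.ampa.reversal_mv - v_ref)
    q_nmda = params.nmda.gbar_ns * params.nmda.tau_ms * \
        (params.nmda.reversal_mv - v_ref)
    q_exc = np.full(n, q_ampa + q_nmda)
    if not params.inh_nmda:
        q_exc[ne:] = q_ampa
    q_inh = (params.gaba_a.gbar_ns * params.gaba_a.tau_ms *
             (params.gaba_a.reversal_mv - v_ref) +
             params.gaba_b.gbar_ns * params.gaba_b.tau_ms *
             (params.gaba_b.reversal_mv - v_ref))
    exc_drive = W_exc.sum(axis=1) * q_exc
    inh_drive = W_inh.sum(axis=1) * q_inh * params.balance_rate_ratio
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(inh_drive < 0, exc_drive / (-inh_drive), 0.0)
    W_inh *= scale[:, None]

    ee_post, ee_pre = np.nonzero(conn_e[:ne, :])
    if place_map is None:
        place_map = build_place_map(ne, arena_half_extent_cm)
    bg_offset = params.heterogeneity_pa * rng.standard_normal(n)
    return Network(params, W_exc, W_inh,
                   ee_pre.astype(np.int32), ee_post.astype(np.int32), place_map,
                   bg_offset)


def place_input(position_cm, place_map: PlaceFieldMap) -> np.ndarray:
    """Gaussian place-field currents for an agent at ``position_cm``.

    current_i = gain * exp(-||position - pref_i||^2 / (2 sigma^2))
    """
    pos = np.asarray(position_cm, dtype=float)
    d2 = np.sum((place_map.positions_cm - pos) ** 2, axis=1)
    return place_map.gain_pa * np.exp(-d2 / (2.0 * place_map.sigma_cm ** 2))


def background_input_step(bg: np.ndarray, params: BackgroundParams,
                          dt_ms: float, rng: np.random.Generator,
                          mean_pa: np.ndarray | float | None = None) -> np.ndarray:
    """One exact-discretization step of the OU background current (in place).

    Uses the stationary update x <- mu + (x - mu) a + sd sqrt(1 - a^2) z with
    a = exp(-dt/tau), so the stationary mean and sd are exactly ``mean_pa``
    and ``sd_pa`` at any dt.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    mu = params.mean_pa if mean_pa is None else mean_pa
    a = math.exp(-dt_ms / params.tau_ms)
    if params.sd_pa == 0.0:
        bg[:] = mu
    else:
        noise = rng.standard_normal(bg.shape)
        bg[:] = mu + (bg - mu) * a + params.sd_pa * math.sqrt(1.0 - a * a) * noise
    return bg


@dataclass
class NetworkState:
    """Mutable per-neuron state plus the conduction-delay ring buffer."""

    V: np.ndarray
    theta_adapt: np.ndarray        # adaptive threshold component (0 for I cells)
    refrac_steps: np.ndarray       # remaining refractory steps
    s_ampa: np.ndarray             # recurrent AMPA gating drive
    s_nmda: np.ndarray
    x_nmda: np.ndarray             # per-presynaptic saturating NMDA occupancy
    s_gaba_a: np.ndarray
    s_gaba_b: np.ndarray
    bg: np.ndarray                 # OU background current
    bg_mu: np.ndarray              # stationary background mean per neuron
    ring: list                     # delay buffer of spiker index arrays
    ring_ptr: int
    t_ms: float
    dt_ms: float

    @classmethod
    def initial(cls, net: Network, dt_ms: float,
                rng: np.random.Generator | None = None) -> "NetworkState":
        p = net.params
        if dt_ms > p.synaptic_delay_ms:
            raise ValueError("dt must not exceed the synaptic delay")
        n = p.n_total
        delay_steps = max(1, int(round(p.synaptic_delay_ms / dt_ms)))
        V0 = np.full(n, p.membrane.leak_reversal_mv)
        if rng is not None:  # desynchronize initial conditions
            V0 += rng.uniform(0.0, 5.0, n)
        mean = np.full(n, p.background.mean_pa)
        mean[p.n_exc:] = p.background_inh_mean_pa
        if net.bg_offset_pa is not None:
            mean = mean + net.bg_offset_pa
        return cls(
            V=V0,
            theta_adapt=np.zeros(n),
            refrac_steps=np.zeros(n, dtype=np.int32),
            s_ampa=np.zeros(n), s_nmda=np.zeros(n),
            x_nmda=np.zeros(p.n_exc),
            s_gaba_a=np.zeros(n), s_gaba_b=np.zeros(n),
            bg=mean.copy(),
            bg_mu=mean,
            ring=[np.empty(0, dtype=np.int64) for _ in range(delay_steps)],
            ring_ptr=0,
            t_ms=0.0,
            dt_ms=dt_ms,
        )


def network_step(net: Network, state: NetworkState, I_ff: np.ndarray,
                 nmda_gain: float, dt_ms: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Advance the network by one time step; returns indices of new spikes.

    Order per step: deliver spikes whose conduction delay has elapsed onto
    postsynaptic gating variables; decay gating variables (exact exponential);
    integrate V (forward Euler) with leak, feed-forward, background and
    recurrent currents; apply refractoriness; detect threshold crossings,
    reset, start refractory periods and increment adaptive thresholds of
    excitatory spikers; enqueue the new spikes in the delay buffer.
    """
    if nmda_gain < 0:
        raise ValueError("nmda_gain must be >= 0")
    p = net.params
    m = p.membrane
    ne = p.n_exc

    delivered = state.ring[state.ring_ptr]
    if delivered.size:
        exc = delivered[delivered < ne]
        inh = delivered[delivered >= ne]
        if exc.size:
            state.s_ampa += net.W_exc[:, exc].sum(axis=1)
            inc = p.nmda_saturation * (1.0 - state.x_nmda[exc])
            state.s_nmda += net.W_exc[:, exc] @ inc
            state.x_nmda[exc] += inc
        if inh.size:
            drive = net.W_inh[:, inh - ne].sum(axis=1)
            state.s_gaba_a += drive
            state.s_gaba_b += drive

    state.s_ampa *= math.exp(-dt_ms / p.ampa.tau_ms)
    nmda_decay = math.exp(-dt_ms / p.nmda.tau_ms)
    state.s_nmda *= nmda_decay
    state.x_nmda *= nmda_decay
    state.s_gaba_a *= math.exp(-dt_ms / p.gaba_a.tau_ms)
    state.s_gaba_b *= math.exp(-dt_ms / p.gaba_b.tau_ms)

    V = state.V
    # scratch buffers avoid per-step allocations; every expression below
    # reproduces the plain formula's operation order exactly
    try:
        t1, t2, i_syn = state._scratch
    except AttributeError:
        t1, t2, i_syn = state._scratch = (np.empty_like(V), np.empty_like(V),
                                          np.empty_like(V))
    # AMPA
    np.multiply(state.s_ampa, p.ampa.gbar_ns, out=i_syn)
    np.subtract(p.ampa.reversal_mv, V, out=t2)
    i_syn *= t2
    # NMDA (DA-scaled; excitatory cells only unless inh_nmda)
    np.multiply(state.s_nmda, p.nmda.gbar_ns * nmda_gain, out=t1)
    if not p.inh_nmda:
        t1[p.n_exc:] = 0.0
    if p.mg_block:
        t1 /= 1.0 + 0.28 * np.exp(-0.062 * V)
    np.subtract(p.nmda.reversal_mv, V, out=t2)
    t1 *= t2
    i_syn += t1
    # GABA-A
    np.multiply(state.s_gaba_a, p.gaba_a.gbar_ns, out=t1)
    np.subtract(p.gaba_a.reversal_mv, V, out=t2)
    t1 *= t2
    i_syn += t1
    # GABA-B
    np.multiply(state.s_gaba_b, p.gaba_b.gbar_ns, out=t1)
    np.subtract(p.gaba_b.reversal_mv, V, out=t2)
    t1 *= t2
    i_syn += t1

    background_input_step(state.bg, p.background, dt_ms, rng, mean_pa=state.bg_mu)

    # dV = (dt/C) * (g_L (E_L - V) + I_syn + I_ff + bg)
    np.subtract(m.leak_reversal_mv, V, out=t1)
    t1 *= m.leak_ns
    t1 += i_syn
    t1 += I_ff
    t1 += state.bg
    t1 *= dt_ms / m.capacitance_pf
    refractory = state.refrac_steps > 0
    t1[refractory] = 0.0
    V += t1
    state.refrac_steps[refractory] -= 1

    if not math.isfinite(float(V.sum())):
        raise FloatingPointError(
            f"non-finite membrane potential at t = {state.t_ms:.2f} ms")

    threshold = m.threshold_mv + state.theta_adapt
    spiked = (V >= threshold) & ~refractory
    spikers = np.nonzero(spiked)[0]
    if spikers.size:
        V[spikers] = m.reset_mv
        state.refrac_steps[spikers] = int(round(m.refractory_ms / dt_ms))
        exc_spikers = spikers[spikers < ne]
        state.theta_adapt[exc_spikers] += p.adaptive_threshold.increment_mv
    state.theta_adapt *= math.exp(-dt_ms / p.adaptive_threshold.tau_ms)

    state.ring[state.ring_ptr] = spikers
    state.ring_ptr = (state.ring_ptr + 1) % len(state.ring)
    state.t_ms += dt_ms
    return spikers


def firing_rates(spikes: SpikeRecord, window_ms: float, n_neurons: int,
                 t_now_ms: float | None = None) -> np.ndarray:
    """Per-neuron firing rate (Hz) over a trailing window."""
    if window_ms <= 0:
        raise ValueError("window must be positive")
    if t_now_ms is None:
        t_now_ms = spikes.times_ms.max() if len(spikes) else 0.0
    mask = (spikes.times_ms > t_now_ms - window_ms) & (spikes.times_ms <= t_now_ms)
    counts = np.bincount(spikes.neuron_ids[mask], minlength=n_neurons)
    return counts / (window_ms * 1e-3)


def lif_isi_closed_form(params: MembraneParams, current_pa: float) -> float:
    """Analytic inter-spike interval (ms) of an isolated LIF under constant drive."""
    m = params
    v_inf = m.leak_reversal_mv + current_pa / m.leak_ns
    if v_inf <= m.threshold_mv:
        return math.inf
    tau_m = m.capacitance_pf / m.leak_ns
    return m.refractory_ms + tau_m * math.log(
        (v_inf - m.reset_mv) / (v_inf - m.threshold_mv))
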