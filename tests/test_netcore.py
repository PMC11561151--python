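import math

import numpy as np
import pytest

import magnet
from magnet import netcore


def test_full_connectivity_has_all_ordered_pairs_minus_self(tiny_net):
    n = tiny_net.params.n_total
    edges = int((tiny_net.W_exc > 0).sum() + (tiny_net.W_inh > 0).sum())
    assert edges == n * (n - 1)
    assert np.all(np.diag(tiny_net.W_exc[:4, :4]) == 0)


def test_build_is_deterministic():
    p = magnet.NetworkParams()
    a = magnet.build_network(p, seed=42)
    b = magnet.build_network(p, seed=42)
    assert np.array_equal(a.W_exc, b.W_exc)
    assert np.array_equal(a.W_inh, b.W_inh)
    c = magnet.build_network(p, seed=43)
    assert not np.array_equal(a.W_exc, c.W_exc)


def test_connection_count_matches_binomial(default_net):
    p = default_net.params
    n_pairs = p.n_total * p.n_exc - p.n_exc + p.n_total * p.n_inh - p.n_inh
    realized = int((default_net.W_exc > 0).sum() + (default_net.W_inh > 0).sum())
    mean = p.p_connect * n_pairs
    sd = math.sqrt(n_pairs * p.p_connect * (1 - p.p_connect))
    assert abs(realized - mean) < 3 * sd


def test_invalid_parameters_are_rejected():
    with pytest.raises(ValueError):
        magnet.build_network(magnet.NetworkParams(n_exc=100, n_inh=30), seed=0)
    with pytest.raises(ValueError):
        magnet.build_network(magnet.NetworkParams(p_connect=0.0), seed=0)


def test_place_input_gaussian_profile(default_net):
    pm = default_net.place_map
    i0 = 17
    pos = pm.positions_cm[i0]
    cur = netcore.place_input(pos, pm)
    assert cur[i0] == pytest.approx(pm.gain_pa)
    shifted = pos + np.array([pm.sigma_cm, 0.0])
    cur = netcore.place_input(shifted, pm)
    assert cur[i0] == pytest.approx(pm.gain_pa * math.exp(-0.5), rel=1e-9)
    far = netcore.place_input(pos + np.array([15 * pm.sigma_cm, 0.0]), pm)
    assert far[i0] < 1e-9 * pm.gain_pa
    assert np.all(cur >= 0)


def test_background_ou_closed_form_statistics():
    params = netcore.BackgroundParams(mean_pa=100.0, sd_pa=20.0, tau_ms=10.0)
    rng = np.random.default_rng(11)
    x = np.array([100.0])
    dt = 0.5
    n = 50_000
    samples = np.empty(n)
    for i in range(n):
        netcore.background_input_step(x, params, dt, rng)
        samples[i] = x[0]
    assert abs(samples.mean() - 100.0) < 0.8
    assert abs(samples.std() - 20.0) < 0.8
    lag = int(params.tau_ms / dt)
    rho = np.corrcoef(samples[:-lag], samples[lag:])[0, 1]
    assert abs(rho - math.exp(-1.0)) < 0.02

    y = np.array([50.0])
    netcore.background_input_step(
        y, netcore.BackgroundParams(mean_pa=80.0, sd_pa=0.0), dt, rng)
    assert y[0] == 80.0

    a = np.array([0.0]); b = np.array([0.0])
    netcore.background_input_step(a, params, dt, np.random.default_rng(5))
    netcore.background_input_step(b, params, dt, np.random.default_rng(5))
    assert a[0] == b[0]


def _isolated_net():
    params = magnet.NetworkParams(n_exc=4, n_inh=1, p_connect=0.5)
    params.background.sd_pa = 0.0
    params.background.mean_pa = 0.0
    params.background_inh_mean_pa = 0.0
    params.adaptive_threshold.increment_mv = 0.0
    params.heterogeneity_pa = 0.0
    pm = netcore.PlaceFieldMap(np.zeros((4, 2)), gain_pa=0.0)
    net = magnet.build_network(params, seed=3, place_map=pm)
    net.W_exc[:] = 0.0
    net.W_inh[:] = 0.0
    return net


def test_leaky_decay_without_input():
    net = _isolated_net()
    state = netcore.NetworkState.initial(net, 0.5)
    state.V[:] = -55.0
    rng = np.random.default_rng(0)
    i_ff = np.zeros(5)
    prev = state.V.copy()
    for _ in range(2000):
        spikes = netcore.network_step(net, state, i_ff, 1.0, 0.5, rng)
        assert spikes.size == 0
        assert np.all(state.V <= prev + 1e-12)
        prev = state.V.copy()
    assert np.allclose(state.V, net.params.membrane.leak_reversal_mv, atol=0.01)


def test_constant_drive_isi_matches_closed_form():
    net = _isolated_net()
    m = net.params.membrane
    current = 300.0
    state = netcore.NetworkState.initial(net, 0.1)
    state.V[:] = m.reset_mv
    rng = np.random.default_rng(0)
    i_ff = np.full(5, current)
    spike_times = []
    for i in range(30000):
        if netcore.network_step(net, state, i_ff, 1.0, 0.1, rng).size:
            spike_times.append(i * 0.1)
    isis = np.diff(spike_times[2:])
    expected = netcore.lif_isi_closed_form(m, current)
    assert abs(np.mean(isis) - expected) < 0.3  # forward-Euler discretization


def test_voltage_trace_matches_fine_timestep_reference():
    """Coarse-step integration of a passive neuron under a current ramp stays
    close to an independent fine-step Euler reference."""
    net = _isolated_net()
    m = net.params.membrane
    state = netcore.NetworkState.initial(net, 0.5)
    state.V[:] = m.leak_reversal_mv
    rng = np.random.default_rng(0)
    ts = np.arange(0, 200.0, 0.5)
    current = np.minimum(ts, 100.0)  # sub-threshold ramp, pA
    coarse = []
    for c in current:
        netcore.network_step(net, state, np.full(5, c), 1.0, 0.5, rng)
        coarse.append(state.V[0])
    # reference: independent Euler at dt = 0.01 ms
    v = m.leak_reversal_mv
    fine = []
    for c in current:
        for _ in range(50):
            v += (0.01 / m.capacitance_pf) * (
                m.leak_ns * (m.leak_reversal_mv - v) + c)
        fine.append(v)
    assert np.max(np.abs(np.asarray(coarse) - np.asarray(fine))) < 0.05


def test_synaptic_delay_contract(tiny_net):
    net = tiny_net
    p = net.params
    p.background.sd_pa = 0.0
    p.background.mean_pa = 0.0
    p.background_inh_mean_pa = 0.0
    state = netcore.NetworkState.initial(net, 0.5)
    rng = np.random.default_rng(0)
    i_ff = np.zeros(5)
    # force neuron 0 above threshold on the first step
    state.V[0] = p.membrane.threshold_mv + 1.0
    delay_steps = int(round(p.synaptic_delay_ms / 0.5))
    gate_before = []
    for step in range(delay_steps + 1):
        gate_before.append(state.s_ampa.copy())
        netcore.network_step(net, state, i_ff, 1.0, 0.5, rng)
    # no postsynaptic gating before the delay elapsed
    for g in gate_before[1:delay_steps]:
        assert np.all(g == 0.0)
    assert np.any(state.s_ampa > 0.0)


def test_refractoriness_and_spike_determinism(default_net):
    p = default_net.params
    dt = 0.5
    rng = np.random.default_rng(21)
    state = netcore.NetworkState.initial(default_net, dt,
                                         np.random.default_rng(2))
    i_ff = np.zeros(p.n_total)
    i_ff[:p.n_exc] = netcore.place_input((0.0, 0.0), default_net.place_map)
    last_spike = np.full(p.n_total, -1e9)
    trains = []
    for i in range(8000):
        spikes = netcore.network_step(default_net, state, i_ff, 1.0, dt, rng)
        t = i * dt
        if spikes.size:
            assert np.all(t - last_spike[spikes] >= p.membrane.refractory_ms)
            last_spike[spikes] = t
            trains.append((i, tuple(spikes)))
    # identical (state seed, noise seed) => identical spikes
    state2 = netcore.NetworkState.initial(default_net, dt,
                                          np.random.default_rng(2))
    rng2 = np.random.default_rng(21)
    trains2 = []
    for i in range(8000):
        spikes = netcore.network_step(default_net, state2, i_ff, 1.0, dt, rng2)
        if spikes.size:
            trains2.append((i, tuple(spikes)))
    assert trains == trains2


def test_ei_currents_are_comparable_in_magnitude(default_net):
    """With plasticity and phasic DA off, the mean recurrent inhibitory
    current tracks the mean recurrent excitatory current (balanced regime,
    inhibition-dominated by construction)."""
    p = default_net.params
    state = netcore.NetworkState.initial(default_net, 0.5,
                                         np.random.default_rng(4))
    rng = np.random.default_rng(5)
    i_ff = np.zeros(p.n_total)
    i_ff[:p.n_exc] = netcore.place_input((10.0, 5.0), default_net.place_map)
    exc_sum = inh_sum = 0.0
    for i in range(4000):
        netcore.network_step(default_net, state, i_ff, 1.0, 0.5, rng)
        V = state.V
        exc = (p.ampa.gbar_ns * state.s_ampa * (p.ampa.reversal_mv - V)
               + p.nmda.gbar_ns * state.s_nmda * (p.nmda.reversal_mv - V))
        inh = (p.gaba_a.gbar_ns * state.s_gaba_a * (p.gaba_a.reversal_mv - V)
               + p.gaba_b.gbar_ns * state.s_gaba_b * (p.gaba_b.reversal_mv - V))
        exc_sum += exc[:p.n_exc].mean()
        inh_sum += inh[:p.n_exc].mean()
    ratio = abs(inh_sum) / abs(exc_sum)
    assert 0.3 < ratio < 8.0
    # and the build-time construction balances expected drives exactly at the
    # assumed rate ratio
    net = default_net
    v_ref = 0.5 * (p.membrane.leak_reversal_mv + p.membrane.threshold_mv)
    q_ampa = p.ampa.gbar_ns * p.ampa.tau_ms * (p.ampa.reversal_mv - v_ref)
    q_nmda = p.nmda.gbar_ns * p.nmda.tau_ms * (p.nmda.reversal_mv - v_ref)
    q_exc = np.full(p.n_total, q_ampa + (0.0 if not p.inh_nmda else 0.0))
    q_exc[:p.n_exc] += q_nmda
    q_inh = (p.gaba_a.gbar_ns * p.gaba_a.tau_ms *
             (p.gaba_a.reversal_mv - v_ref)
             + p.gaba_b.gbar_ns * p.gaba_b.tau_ms *
             (p.gaba_b.reversal_mv - v_ref))
    exc_drive = net.W_exc.sum(axis=1) * q_exc
    inh_drive = net.W_inh.sum(axis=1) * (-q_inh) * p.balance_rate_ratio
    ok = inh_drive > 0
    assert np.allclose(exc_drive[ok], inh_drive[ok], rtol=1e-9)


def test_firing_rates_window_counts():
    rec = netcore.SpikeRecord([0, 0, 0, 0, 1], [10.0, 30.0, 60.0, 95.0, 200.0])
    rates = netcore.firing_rates(rec, 100.0, 3, t_now_ms=100.0)
    assert rates[0] == pytest.approx(40.0)
    assert rates[1] == 0.0
    assert rates[2] == 0.0
    empty = netcore.firing_rates(netcore.SpikeRecord(), 50.0, 3)
    assert np.all(empty == 0.0)
    # brute-force recount over sliding windows
    rng = np.random.default_rng(0)
    ids = rng.integers(0, 5, 200)
    ts = np.sort(rng.uniform(0, 1000.0, 200))
    rec = netcore.SpikeRecord(ids, ts)
    for t_now in (150.0, 400.0, 990.0):
        got = netcore.firing_rates(rec, 120.0, 5, t_now_ms=t_now)
        want = np.zeros(5)
        for i, t in zip(ids, ts):
            if t_now - 120.0 < t <= t_now:
                want[i] += 1
        assert np.allclose(got, want / 0.12)
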