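"""Dopamine-gated spike-timing-dependent plasticity with eligibility traces.

Plastic E->E synapses carry a calcium variable fed by pre- and postsynaptic
spiking (the presynaptic contribution arrives after the conduction delay) and
cleared by buffering/extrusion.  Calcium activates a kinase and a phosphatase
with sigmoidal calcium dependence; because the kinase half-activation sits
above the phosphatase's, near-coincident pre-then-post spiking (high calcium)
drives kinase-dominated eLTP traces while the looser post-then-pre ordering
(intermediate calcium) drives phosphatase-dominated eLTD traces.  These
eligibility traces decay over seconds and produce no weight change on their
own: dopamine gates their consolidation into bounded long-term changes,

    dW = eta * DA * (eLTP - eLTD) * dt,  clipped to [0, w_max].

Implementation note: with linear summation of pre/post calcium contributions
sharing one clearance constant, synaptic calcium factorizes as
Ca_ij = ca_post_i + ca_pre_j, so only two per-neuron traces are stored and
per-synapse work is done on the sparse edge list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlasticityParams",
    "EligibilityState",
    "calcium_step",
    "eligibility_step",
    "consolidate_step",
    "synaptic_calcium",
]


@dataclass
class PlasticityParams:
    """Constants of the calcium / eligibility / consolidation cascade.

    The asymmetric calcium increments (postsynaptic spikes contribute more
    than presynaptic ones) shape the timing window: only a pre spike followed
    closely by a post spike lifts calcium above the kinase half-activation.
    """

    ca_pre: float = 0.6            # calcium increment per presynaptic spike
    ca_pre_max: float = 0.6        # presynaptic site saturates at one spike
    ca_post: float = 1.2           # calcium increment per postsynaptic spike
    ca_post_max: float = 2.0       # postsynaptic influx stacks across a burst
    tau_ca_ms: float = 20.0        # clearance (buffering + extrusion)
    kinase_half: float = 2.3       # kinase needs a presynaptic spike during a
                                   # postsynaptic burst (rate discrimination)
    kinase_steep: float = 25.0
    tau_kinase_ms: float = 15.0
    phosphatase_half: float = 0.7  # phosphatase activates at moderate calcium
    phosphatase_steep: float = 25.0
    tau_phosphatase_ms: float = 15.0
    gain_eltp: float = 1.0         # eLTP drive per unit kinase activation
    gain_eltd: float = 0.005        # eLTD drive per unit net phosphatase activation
    tau_eltp_ms: float = 600.0     # eligibility traces persist for ~a second
    tau_eltd_ms: float = 600.0
    trace_max: float = 60.0         # tag saturation: eligibility resources per
                                   # synapse are finite
    eta: float = 2.0e-3            # consolidation rate per (DA a.u. * ms)
    consolidation_threshold: float = 0.45  # DA level below which D1-gated
                                          # consolidation is inactive (tonic DA
                                          # does not read out the traces)
    w_max: float = 8.0

    def validate(self) -> None:
        for tau in (self.tau_ca_ms, self.tau_kinase_ms, self.tau_phosphatase_ms,
                    self.tau_eltp_ms, self.tau_eltd_ms):
            if tau <= 0:
                raise ValueError("plasticity time constants must be positive")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")
        if self.kinase_half <= self.phosphatase_half:
            raise ValueError(
                "kinase must activate at higher calcium than phosphatase")


class EligibilityState:
    """Per-edge eligibility machinery over a fixed sparse E->E edge list."""

    def __init__(self, ee_pre: np.ndarray, ee_post: np.ndarray, n_exc: int):
        self.ee_pre = ee_pre
        self.ee_post = ee_post
        self.n_exc = n_exc
        n_edges = len(ee_pre)
        self.ca_pre_trace = np.zeros(n_exc)    # presynaptic (delayed) calcium trace
        self.ca_post_trace = np.zeros(n_exc)   # postsynaptic back-signal trace
        self.kinase = np.zeros(n_edges)
        self.phosphatase = np.zeros(n_edges)
        self.eltp = np.zeros(n_edges)
        self.eltd = np.zeros(n_edges)

    @property
    def n_edges(self) -> int:
        return len(self.ee_pre)


def calcium_step(state: EligibilityState, params: PlasticityParams,
                 pre_spikes: np.ndarray, post_spikes: np.ndarray,
                 dt_ms: float) -> EligibilityState:
    """Decay calcium traces and add spike contributions (in place).

    ``pre_spikes`` are excitatory spikes as seen at the synapse, i.e. already
    shifted by the conduction delay; ``post_spikes`` are somatic spikes of
    excitatory neurons backpropagating to their incoming synapses.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    decay = math.exp(-dt_ms / params.tau_ca_ms)
    state.ca_pre_trace *= decay
    state.ca_post_trace *= decay
    # presynaptic calcium saturates at the single-spike level while the
    # postsynaptic influx can stack across a burst: potentiation thus requires
    # a presynaptic spike arriving during vigorous postsynaptic firing
    if len(pre_spikes):
        state.ca_pre_trace[pre_spikes] = np.minimum(
            state.ca_pre_trace[pre_spikes] + params.ca_pre, params.ca_pre_max)
    if len(post_spikes):
        state.ca_post_trace[post_spikes] = np.minimum(
            state.ca_post_trace[post_spikes] + params.ca_post,
            params.ca_post_max)
    return state


def synaptic_calcium(state: EligibilityState) -> np.ndarray:
    """Per-edge calcium: the sum of pre- and post-contributed traces."""
    return (state.ca_pre_trace[state.ee_pre]
            + state.ca_post_trace[state.ee_post])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def eligibility_step(state: EligibilityState, params: PlasticityParams,
                     dt_ms: float) -> EligibilityState:
    """Advance kinase/phosphatase activations and eLTP/eLTD traces (in place).

    Activations relax toward their sigmoidal calcium dependence with their own
    time constants.  eLTP integrates the kinase activation; eLTD integrates
    the phosphatase activation in excess of the kinase (the competition), so
    high-calcium episodes are net potentiating and intermediate-calcium
    episodes net depressing.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    ca = synaptic_calcium(state)
    # below ~5 steepness units under the phosphatase half-activation both
    # sigmoids are numerically 0, so activations just relax there
    cut = params.phosphatase_half - 5.0 / params.phosphatase_steep
    active = ca > cut
    state.kinase *= 1.0 - dt_ms / params.tau_kinase_ms
    state.phosphatase *= 1.0 - dt_ms / params.tau_phosphatase_ms
    if np.any(active):
        ca_a = ca[active]
        k_inf = _sigmoid(params.kinase_steep * (ca_a - params.kinase_half))
        p_inf = _sigmoid(params.phosphatase_steep *
                         (ca_a - params.phosphatase_half))
        state.kinase[active] += k_inf * (dt_ms / params.tau_kinase_ms)
        state.phosphatase[active] += p_inf * (dt_ms / params.tau_phosphatase_ms)
    np.clip(state.kinase, 0.0, 1.0, out=state.kinase)
    np.clip(state.phosphatase, 0.0, 1.0, out=state.phosphatase)

    state.eltp *= math.exp(-dt_ms / params.tau_eltp_ms)
    state.eltd *= math.exp(-dt_ms / params.tau_eltd_ms)
    state.eltp += params.gain_eltp * state.kinase * dt_ms
    state.eltd += params.gain_eltd * np.maximum(
        state.phosphatase - state.kinase, 0.0) * dt_ms
    np.clip(state.eltp, 0.0, params.trace_max, out=state.eltp)
    np.clip(state.eltd, 0.0, params.trace_max, out=state.eltd)
    return state


def consolidate_step(weights: np.ndarray, state: EligibilityState,
                     params: PlasticityParams, da_level: float, dt_ms: float,
                     plasticity_enabled: bool = True) -> np.ndarray:
    """Dopamine-gated conversion of eligibility traces into weight changes.

    Returns the updated per-edge weight vector (a new array).  With the gate
    closed (``plasticity_enabled`` False) or no dopamine, weights are returned
    unchanged.  The raw update is computed first and clipped to [0, w_max]
    afterwards.
    """
    if not plasticity_enabled or da_level == 0.0:
        return weights
    dw = params.eta * da_level * (state.eltp - state.eltd) * dt_ms
    return np.clip(weights + dw, 0.0, params.w_max)
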