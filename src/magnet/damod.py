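"""Global dopamine signal and its instantaneous effect on NMDA conductances.

Dopamine (DA) is modelled as a single global concentration shared by every
synapse.  Release events (reward entries, spontaneous transients, commanded
stimulation trains) inject impulses into a second-order linear system that
captures release followed by recapture: an impulse first charges a fast
"release" variable which then feeds a slower "concentration" variable, giving
the familiar double-exponential transient

    c(t) = A * (exp(-t/tau_decay) - exp(-t/tau_rise)),   tau_rise < tau_decay.

The concentration rides on a small tonic baseline and is clipped at zero.
Phasic DA transiently scales the maximal NMDA conductance of every recurrent
synapse ("DA-excitability"); the gain is linear in the concentration above
baseline and returns to 1 in well under a second after a stimulation train.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DAParams",
    "DAEvent",
    "DAState",
    "da_step",
    "spontaneous_release",
    "nmda_gain",
    "command_phasic",
    "kernel_peak_time",
    "single_pulse_response",
    "STIM_TRAIN_PULSES",
    "STIM_TRAIN_INTERVAL_MS",
]

# A commanded stimulation is a 500-ms train of ten pulses at 20 Hz.
STIM_TRAIN_PULSES = 10
STIM_TRAIN_INTERVAL_MS = 50.0


@dataclass
class DAParams:
    """Constants of the global dopamine signal.

    Attributes
    ----------
    pulse_amplitude : a.u.
        Impulse injected into the release variable per pulse.  Scaled so that
        a full 10-pulse train peaks near 1 a.u. above baseline.
    tau_rise_ms, tau_decay_ms : ms
        Time constants of the second-order release/recapture kernel.  The
        decay constant is short enough that the NMDA-gain transient of a
        single train lasts less than a second.
    baseline : a.u.
        Tonic DA level; must be >= 0.  A small positive tonic level lets
        photo-inhibition push the NMDA gain below 1.
    spontaneous_rate_hz : events/s
        Rate of the Poisson process generating spontaneous single-pulse
        transients.
    excitability_enabled : bool
        Master switch of the DA -> NMDA-conductance coupling.
    gain_slope : 1/a.u.
        NMDA gain increase per unit of DA above baseline.
    gain_max : dimensionless
        Saturation of the gain (receptor occupancy saturates under
        superposed release trains).
    inhibition_factor : fraction in [0, 1]
        Multiplicative suppression of the tonic baseline during a commanded
        inhibition.
    inhibition_duration_ms : ms
        Duration of the suppression transient.
    """

    pulse_amplitude: float = 2.3
    tau_rise_ms: float = 30.0
    tau_decay_ms: float = 200.0
    baseline: float = 0.1
    spontaneous_rate_hz: float = 0.05
    excitability_enabled: bool = True
    gain_slope: float = 1.0
    gain_max: float = 2.4
    concentration_max: float = 1.5   # releasable-pool saturation under
                                     # overlapping trains
    inhibition_factor: float = 0.9
    inhibition_duration_ms: float = 1000.0

    def validate(self) -> None:
        if self.tau_rise_ms <= 0 or self.tau_decay_ms <= 0:
            raise ValueError("DA kernel time constants must be positive")
        if self.tau_rise_ms >= self.tau_decay_ms:
            raise ValueError("tau_rise must be shorter than tau_decay")
        if self.baseline < 0:
            raise ValueError("tonic baseline must be >= 0")
        if not 0.0 <= self.inhibition_factor <= 1.0:
            raise ValueError("inhibition_factor must lie in [0, 1]")


@dataclass
class DAEvent:
    """One logged dopamine event (time in ms, kind, pulse amplitude)."""

    time_ms: float
    kind: str  # "reward" | "spontaneous" | "commanded" | "inhibition"
    amplitude: float = 0.0


@dataclass
class DAState:
    """Evolving dopamine concentration plus its event log.

    ``phasic`` is the double-exponential component above the (possibly
    suppressed) tonic baseline; ``release`` is the fast auxiliary variable of
    the second-order kernel.  ``pending`` holds scheduled future pulses as
    (time_ms, amplitude) pairs, e.g. the remaining pulses of a commanded
    train.
    """

    t_ms: float = 0.0
    phasic: float = 0.0
    release: float = 0.0
    suppressed_until_ms: float = -math.inf
    concentration: float = 0.0
    events: list = field(default_factory=list)
    pending: list = field(default_factory=list)

    @classmethod
    def at_baseline(cls, params: DAParams) -> "DAState":
        s = cls()
        s.concentration = params.baseline
        return s


def kernel_peak_time(params: DAParams) -> float:
    """Time-to-peak (ms) of the single-impulse concentration response."""
    tr, td = params.tau_rise_ms, params.tau_decay_ms
    return tr * td / (td - tr) * math.log(td / tr)


def single_pulse_response(t_ms: np.ndarray, params: DAParams) -> np.ndarray:
    """Closed-form concentration response (above baseline) to one pulse at t=0."""
    tr, td = params.tau_rise_ms, params.tau_decay_ms
    t = np.asarray(t_ms, dtype=float)
    out = params.pulse_amplitude * tr / (td - tr) * (
        np.exp(-t / td) - np.exp(-t / tr)
    )
    return np.where(t >= 0.0, out, 0.0)


def spontaneous_release(rate_hz: float, dt_ms: float, rng: np.random.Generator) -> bool:
    """Bernoulli draw for a spontaneous release in one time bin."""
    if rate_hz < 0:
        raise ValueError("spontaneous rate must be >= 0")
    p = rate_hz * dt_ms * 1e-3
    if p > 1.0:
        raise ValueError("rate * dt exceeds 1; shrink the time step")
    return bool(rng.random() < p) if p > 0.0 else False


def nmda_gain(da_level: float, params: DAParams) -> float:
    """Instantaneous NMDA maximal-conductance scaling at a given DA level.

    Linear above/below baseline, floored at 0, saturating at ``gain_max``,
    and identically 1 when the excitability coupling is disabled.
    """
    if not params.excitability_enabled:
        return 1.0
    g = 1.0 + params.gain_slope * (da_level - params.baseline)
    return min(max(0.0, g), params.gain_max)


def command_phasic(state: DAState, params: DAParams, kind: str, t_ms: float) -> None:
    """Schedule a commanded phasic manipulation starting at ``t_ms``.

    ``stimulation`` queues the standard 500-ms train of ten pulses at 20 Hz;
    ``inhibition`` multiplicatively suppresses both the tonic baseline and any
    release occurring during the configured window.  Overlapping stimulations
    superpose; overlapping inhibitions extend the suppression window.
    """
    if kind == "stimulation":
        for k in range(STIM_TRAIN_PULSES):
            state.pending.append((t_ms + k * STIM_TRAIN_INTERVAL_MS,
                                  params.pulse_amplitude))
        state.pending.sort(key=lambda p: p[0])
        state.events.append(DAEvent(t_ms, "commanded", params.pulse_amplitude))
    elif kind == "inhibition":
        until = t_ms + params.inhibition_duration_ms
        state.suppressed_until_ms = max(state.suppressed_until_ms, until)
        state.events.append(DAEvent(t_ms, "inhibition"))
    else:
        raise ValueError(f"unknown phasic command: {kind!r}")


def da_step(state: DAState, params: DAParams, dt_ms: float,
            events: tuple = ()) -> DAState:
    """Advance the dopamine concentration by one time step (in place).

    ``events`` are releases occurring within this step, given as
    ``(kind, amplitude)`` pairs (amplitude ``None`` uses the default pulse).
    Scheduled pending pulses whose time has come are also consumed.  The
    kernel is integrated with exponential updates, exact for the homogeneous
    part of each variable.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    t_next = state.t_ms + dt_ms

    suppressed = state.t_ms < state.suppressed_until_ms
    release_scale = 1.0 - params.inhibition_factor if suppressed else 1.0
    inject = 0.0
    for kind, amplitude in events:
        amp = params.pulse_amplitude if amplitude is None else amplitude
        inject += amp * release_scale
        state.events.append(DAEvent(state.t_ms, kind, amp * release_scale))
    while state.pending and state.pending[0][0] <= state.t_ms:
        inject += state.pending.pop(0)[1] * release_scale

    decay_r = math.exp(-dt_ms / params.tau_rise_ms)
    decay_c = math.exp(-dt_ms / params.tau_decay_ms)
    state.release += inject
    # release variable feeds the concentration, then decays
    state.phasic = state.phasic * decay_c + state.release * (1.0 - decay_c)
    state.release *= decay_r

    tonic = params.baseline
    if suppressed:
        tonic *= 1.0 - params.inhibition_factor
    state.concentration = min(max(0.0, tonic + state.phasic),
                              params.concentration_max)
    state.t_ms = t_next
    return state
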