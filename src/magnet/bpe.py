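"""Reduced behavioural-potential-energy (BPE) model.

Exploiting the radial symmetry of the single-reward arena, the full embodied
architecture reduces to a particle at distance p >= 0 from the rewarded
assembly location (p = 0) moving in the one-dimensional energy landscape

    E(p, DA) = alpha_w * w(p) * I_exc(DA) + 1/2 * alpha_g * rho * DA * p**2

where w(p) is the spatial profile of summed reward-reinforced incoming
synaptic weights (uniform before learning, a Gaussian bump centred on the
reward after learning), and I_exc(DA) is the DA-dependent average inward
recurrent excitatory current per weight unit (negative, and decreasing with
DA — mirroring the NMDA-gain law of the full model so the two share the
excitability parameter).  The first term is the local attractor carved by
learning and deepened by phasic DA; the second is the weaker global pull of
internal-goal focalization, proportional to DA.

Learning thus builds a *latent* attractor: at baseline DA only a narrow
neighbourhood of p = 0 converges, while phasic DA widens and deepens the
basin, yielding global convergence.  Behaviour is simulated as overdamped
Langevin dynamics in this landscape, reflected at p = 0 and at the arena
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WeightProfile",
    "BPEParams",
    "BPEScenario",
    "bpe",
    "bpe_grad",
    "particle_step",
    "basin_metrics",
    "simulate_scenario",
    "calibrate_mobility",
]


@dataclass
class WeightProfile:
    """Radial profile of summed incoming weights.

    ``amplitude == baseline`` gives the pre-learning uniform profile;
    learning only adds weight, so ``amplitude >= baseline``.
    """

    baseline: float = 1.0
    amplitude: float = 1.0
    width_cm: float = 7.0

    def __post_init__(self):
        if self.width_cm <= 0:
            raise ValueError("profile width must be positive")
        if self.amplitude < self.baseline:
            raise ValueError("learning only adds weight: amplitude >= baseline")

    @classmethod
    def uniform(cls, level: float = 1.0) -> "WeightProfile":
        return cls(baseline=level, amplitude=level)

    @classmethod
    def gaussian(cls, amplitude: float = 6.0, width_cm: float = 7.0,
                 baseline: float = 1.0) -> "WeightProfile":
        return cls(baseline=baseline, amplitude=amplitude, width_cm=width_cm)

    @property
    def is_uniform(self) -> bool:
        return self.amplitude == self.baseline

    def __call__(self, p):
        p = np.asarray(p, dtype=float)
        return self.baseline + (self.amplitude - self.baseline) * np.exp(
            -p ** 2 / (2.0 * self.width_cm ** 2))

    def grad(self, p):
        p = np.asarray(p, dtype=float)
        return -(self.amplitude - self.baseline) * p / self.width_cm ** 2 * \
            np.exp(-p ** 2 / (2.0 * self.width_cm ** 2))


@dataclass
class BPEParams:
    """Constants of the reduced energy model and its particle dynamics."""

    alpha_w: float = 1.0
    alpha_g: float = 1.0
    rho: float = 0.08             # scales the global DA * p^2 confinement
    profile: WeightProfile = field(default_factory=WeightProfile.gaussian)
    gain_slope: float = 1.5       # shared with the full model's NMDA-gain law
    mobility: float = 2.5         # cm^2 / (energy * s)
    noise_sd: float = 1.2         # Langevin noise amplitude, cm / sqrt(s)
    p_max_cm: float = 33.5        # reflecting outer boundary (arena radius)

    def i_exc(self, da):
        """Average inward (negative) recurrent excitatory current per weight
        unit; decreasing in DA, mirroring the NMDA-gain law."""
        return -(1.0 + self.gain_slope * np.asarray(da, dtype=float))


@dataclass
class BPEScenario:
    """One Monte-Carlo scenario: initial distance and a DA time course.

    The DA course is baseline plus a plateau of the given (possibly negative)
    magnitude between ``onset_s`` and ``onset_s + duration_s``, with
    exponential rise and decay edges; it is clipped at 0.
    """

    p0_cm: float
    da_baseline: float = 0.1
    da_magnitude: float = 0.0
    onset_s: float = 0.5
    duration_s: float = 2.0
    tau_rise_s: float = 0.05
    tau_decay_s: float = 0.2
    horizon_s: float = 10.0
    convergence_radius_cm: float = 5.0

    def __post_init__(self):
        if self.p0_cm < 0:
            raise ValueError("initial distance must be >= 0")
        if self.horizon_s <= 0:
            raise ValueError("horizon must be positive")

    def da_course(self, t_s):
        """DA level at times ``t_s`` (clipped at 0)."""
        t = np.asarray(t_s, dtype=float) - self.onset_s
        rising = 1.0 - np.exp(-np.clip(t, 0.0, None) / self.tau_rise_s)
        level_end = 1.0 - math.exp(-self.duration_s / self.tau_rise_s)
        falling = level_end * np.exp(-np.clip(t - self.duration_s, 0.0, None)
                                     / self.tau_decay_s)
        shape = np.where(t < 0.0, 0.0,
                         np.where(t < self.duration_s, rising, falling))
        return np.clip(self.da_baseline + self.da_magnitude * shape, 0.0, None)


def bpe(p, da, params: BPEParams):
    """Behavioural potential energy E(p, DA)."""
    p = np.asarray(p, dtype=float)
    return params.alpha_w * params.profile(p) * params.i_exc(da) \
        + 0.5 * params.alpha_g * params.rho * np.asarray(da, dtype=float) * p ** 2


def bpe_grad(p, da, params: BPEParams):
    """Analytic dE/dp."""
    p = np.asarray(p, dtype=float)
    return params.alpha_w * params.profile.grad(p) * params.i_exc(da) \
        + params.alpha_g * params.rho * np.asarray(da, dtype=float) * p


def particle_step(p: float, da: float, params: BPEParams, dt_s: float,
                  rng: np.random.Generator | None = None) -> float:
    """One overdamped Langevin step, reflected at 0 and at the arena scale."""
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    p_new = p - params.mobility * float(bpe_grad(p, da, params)) * dt_s
    if rng is not None and params.noise_sd > 0:
        p_new += params.noise_sd * math.sqrt(dt_s) * rng.standard_normal()
    if p_new < 0.0:
        p_new = -p_new
    if p_new > params.p_max_cm:
        p_new = 2.0 * params.p_max_cm - p_new
    return float(min(max(p_new, 0.0), params.p_max_cm))


def basin_metrics(params: BPEParams, da: float,
                  p_ref_cm: float = 30.0,
                  convergence_radius_cm: float = 5.0,
                  horizon_s: float = 10.0,
                  dt_s: float = 0.01,
                  p_grid_step_cm: float = 0.5) -> tuple:
    """(depth, width) of the attractor basin at a given DA level.

    Depth is E(p_ref) - E(0); width is the largest starting distance from
    which noiseless gradient descent reaches the convergence radius within
    the horizon.  For the pre-learning uniform profile the first term
    contributes no interior structure and the depth reduces to the global
    quadratic term.
    """
    e = bpe(np.array([p_ref_cm, 0.0]), da, params)
    depth = float(e[0] - e[1])
    n_steps = int(round(horizon_s / dt_s))
    width = 0.0
    for p0 in np.arange(p_grid_step_cm, p_ref_cm + 1e-9, p_grid_step_cm):
        p = float(p0)
        for _ in range(n_steps):
            p = particle_step(p, da, params, dt_s, rng=None)
            if p <= convergence_radius_cm:
                break
        if p <= convergence_radius_cm:
            width = float(p0)
        else:
            break
    return depth, width


def simulate_scenario(scenario: BPEScenario, params: BPEParams,
                      n_trials: int, seed: int, dt_s: float = 0.01) -> dict:
    """Monte-Carlo first-passage statistics of a scenario.

    An "action" is reaching the convergence radius within the horizon;
    latency is the first-passage time of acting trials; speed is the mean
    |dp|/dt en route (acting trials).  Returns a dict with ``p_action``,
    ``latency_s`` (array of acting-trial latencies), ``latency_mean_s`` and
    ``speed_mean_cms``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    n_steps = int(round(scenario.horizon_s / dt_s))
    da_t = scenario.da_course(np.arange(n_steps) * dt_s)
    latencies, speeds = [], []
    hits = 0
    for _ in range(n_trials):
        p = scenario.p0_cm
        path_len = 0.0
        for k in range(n_steps):
            p_next = particle_step(p, float(da_t[k]), params, dt_s, rng)
            path_len += abs(p_next - p)
            p = p_next
            if p <= scenario.convergence_radius_cm:
                hits += 1
                t_hit = (k + 1) * dt_s
                latencies.append(t_hit)
                speeds.append(path_len / t_hit)
                break
    return {
        "p_action": hits / n_trials,
        "latency_s": np.asarray(latencies),
        "latency_mean_s": float(np.mean(latencies)) if latencies else math.nan,
        "speed_mean_cms": float(np.mean(speeds)) if speeds else math.nan,
        "n_trials": n_trials,
    }


def calibrate_mobility(distances_cm: np.ndarray, speeds_cms: np.ndarray,
                       params: BPEParams, da: float) -> float:
    """Least-squares mobility matching observed radial descent speeds.

    Given inward speeds measured at several distances (e.g. from full-model
    goal runs), fits the single mobility constant of the overdamped dynamics,
    speed(p) = mobility * |dE/dp|, and returns it.
    """
    g = np.abs(bpe_grad(np.asarray(distances_cm, dtype=float), da, params))
    denom = float(g @ g)
    if denom == 0.0:
        raise ValueError("zero gradient at all calibration distances")
    return float(g @ np.asarray(speeds_cms, dtype=float) / denom)
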