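"""Behavioural trajectory metrics and synthetic trajectory fixtures.

Operates on tracked trajectories sampled at 50-ms frames (20 fps), in
arena-centred coordinates (cm, y up).  Provides the standard open-field
measures: triangular-filter smoothing before speed computation, instantaneous
speed as the inter-frame distance per frame interval, event-to-zone delays
with the 60-s exclusion rule, pooled cumulative delay distributions on 3-s
bins, the bout directionality statistic ("angle error": the resultant length
of unit vectors of bearings-to-target referenced to the event-frame bearing;
1 for a straight approach, ~0 for incoherent wandering), and inter-reward
distance / maximum-speed statistics.

Fixture generators return trajectories with constructed ground truth for
metric validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "FRAME_S",
    "DELAY_EXCLUSION_S",
    "smooth_trajectory",
    "speed_series",
    "delay_to_target",
    "cumulative_delay_distribution",
    "angle_error",
    "inter_reward_stats",
    "make_fixture",
    "trajectory_from_frame",
]

FRAME_S = 0.05
DELAY_EXCLUSION_S = 60.0


@dataclass
class Trajectory:
    """Frames at uniform 50-ms spacing plus sparse event markers."""

    times_s: np.ndarray
    xy_cm: np.ndarray                       # (n, 2)
    events: list = field(default_factory=list)   # (time_s, kind) pairs

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.xy_cm = np.asarray(self.xy_cm, dtype=float)
        if len(self.times_s) != len(self.xy_cm):
            raise ValueError("times and positions must have equal length")
        if len(self.times_s) > 1:
            dt = np.diff(self.times_s)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.any(np.abs(dt - dt[0]) > 1e-6):
                raise ValueError("frame spacing must be uniform")

    @property
    def frame_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0]) \
            if len(self.times_s) > 1 else FRAME_S

    def to_frame(self) -> pd.DataFrame:
        ev = np.full(len(self.times_s), "", dtype=object)
        for t, kind in self.events:
            i = int(round((t - self.times_s[0]) / self.frame_s))
            if 0 <= i < len(ev):
                ev[i] = kind
        return pd.DataFrame({"time_s": self.times_s,
                             "x_cm": self.xy_cm[:, 0],
                             "y_cm": self.xy_cm[:, 1],
                             "event": ev})


def trajectory_from_frame(df: pd.DataFrame) -> Trajectory:
    """Build a Trajectory from a tidy (time_s, x_cm, y_cm, event) table."""
    events = [(float(t), str(e)) for t, e in zip(df["time_s"], df["event"])
              if isinstance(e, str) and e != ""]
    return Trajectory(df["time_s"].to_numpy(),
                      df[["x_cm", "y_cm"]].to_numpy(), events)


def smooth_trajectory(traj: Trajectory, half_width: int = 2) -> Trajectory:
    """Triangular-filter smoothing of the coordinates.

    The kernel is the normalized triangle of half-width ``half_width``
    frames; at the edges the kernel is renormalized over the available
    samples, so constant and (interior) linear trajectories are unchanged.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    if half_width == 0 or len(traj.times_s) < 2:
        return Trajectory(traj.times_s.copy(), traj.xy_cm.copy(),
                          list(traj.events))
    kernel = np.concatenate([np.arange(1, half_width + 1),
                             [half_width + 1],
                             np.arange(half_width, 0, -1)]).astype(float)
    kernel /= kernel.sum()
    norm = np.convolve(np.ones(len(traj.times_s)), kernel, mode="same")
    xy = np.column_stack([
        np.convolve(traj.xy_cm[:, 0], kernel, mode="same") / norm,
        np.convolve(traj.xy_cm[:, 1], kernel, mode="same") / norm,
    ])
    return Trajectory(traj.times_s.copy(), xy, list(traj.events))


def speed_series(traj: Trajectory) -> np.ndarray:
    """Instantaneous speed (cm/s): inter-frame distance / frame interval.

    Returned per frame (same length as the trajectory); the first element
    repeats the second so the series aligns with the frames.
    """
    if len(traj.times_s) < 2:
        return np.zeros(len(traj.times_s))
    d = np.hypot(*np.diff(traj.xy_cm, axis=0).T)
    s = d / traj.frame_s
    return np.concatenate([[s[0]], s])


def _first_entry_after(traj: Trajectory, t_s: float, center, radius: float):
    d = np.hypot(*(traj.xy_cm - np.asarray(center, dtype=float)).T)
    after = (traj.times_s > t_s) & (d <= radius)
    idx = np.nonzero(after)[0]
    return float(traj.times_s[idx[0]]) if idx.size else None


def delay_to_target(traj: Trajectory, event_times_s, center, radius_cm: float,
                    exclusion_s: float = DELAY_EXCLUSION_S) -> pd.DataFrame:
    """Event-to-first-zone-entry delays with exclusion/censoring flags.

    Delays above ``exclusion_s`` (60 s) are flagged ``excluded``; events with
    no subsequent entry before the record ends are flagged ``censored`` (and
    excluded).  Returns a DataFrame (event_time_s, delay_s, included,
    censored).
    """
    rows = []
    for t in np.atleast_1d(np.asarray(event_times_s, dtype=float)):
        entry = _first_entry_after(traj, t, center, radius_cm)
        if entry is None:
            rows.append((t, math.nan, False, True))
        else:
            delay = entry - t
            rows.append((t, delay, delay <= exclusion_s, False))
    return pd.DataFrame(rows, columns=["event_time_s", "delay_s",
                                       "included", "censored"])


def cumulative_delay_distribution(delays_s, bin_s: float = 3.0,
                                  max_s: float = DELAY_EXCLUSION_S):
    """Pooled empirical cumulative distribution of delays on fixed bins.

    Returns (bin_edges_s, cumulative_fraction) where each fraction is the
    share of *all* events (the pooled pool, censored/excluded included in the
    denominator) with delay <= the bin's right edge.
    """
    d = np.asarray(delays_s, dtype=float)
    edges = np.arange(bin_s, max_s + bin_s / 2, bin_s)
    if d.size == 0:
        return edges, np.zeros(0)
    finite = d[np.isfinite(d)]
    cum = np.array([(finite <= e).sum() for e in edges], dtype=float) / d.size
    return edges, cum


def angle_error(traj: Trajectory, event_time_s: float, target_cm,
                until_s: float | None = None) -> float:
    """Bout directionality statistic in [0, 1].

    For frames after the event (until zone entry or ``until_s``), theta_t is
    the bearing-to-target at frame t minus the bearing-to-target at the event
    frame; the statistic is ||sum_t exp(i theta_t)|| / n.  A straight radial
    approach keeps theta_t = 0 and scores 1; incoherent headings cancel
    toward 0.  Frames where the position sits on the target are skipped.
    """
    target = np.asarray(target_cm, dtype=float)
    i0 = int(np.searchsorted(traj.times_s, event_time_s))
    if i0 >= len(traj.times_s):
        raise ValueError("event beyond the end of the trajectory")
    stop = traj.times_s[-1] if until_s is None else until_s
    sel = (traj.times_s >= traj.times_s[i0]) & (traj.times_s <= stop)
    pos = traj.xy_cm[sel]
    delta = target - pos
    dist = np.hypot(*delta.T)
    ok = dist > 1e-9
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-degenerate frames after event")
    bearings = np.arctan2(delta[ok, 1], delta[ok, 0])
    theta = bearings - bearings[0]   # the event frame contributes theta = 0
    resultant = np.abs(np.exp(1j * theta).sum())
    return float(resultant / len(theta))


def inter_reward_stats(traj: Trajectory, reward_times_s) -> pd.DataFrame:
    """Path length and maximum speed between consecutive rewards.

    Returns a DataFrame with one row per consecutive reward pair:
    (t_from_s, t_to_s, path_cm, displacement_cm, max_speed_cms).
    """
    t_r = np.sort(np.atleast_1d(np.asarray(reward_times_s, dtype=float)))
    if t_r.size < 2:
        raise ValueError("need at least two reward events")
    speeds = speed_series(traj)
    rows = []
    for a, b in zip(t_r[:-1], t_r[1:]):
        sel = (traj.times_s >= a) & (traj.times_s <= b)
        pos = traj.xy_cm[sel]
        steps = np.hypot(*np.diff(pos, axis=0).T)
        rows.append((a, b, float(steps.sum()),
                     float(np.hypot(*(pos[-1] - pos[0]))),
                     float(speeds[sel].max())))
    return pd.DataFrame(rows, columns=["t_from_s", "t_to_s", "path_cm",
                                       "displacement_cm", "max_speed_cms"])


def make_fixture(kind: str, seed: int = 0, n_frames: int = 400,
                 arena_radius_cm: float = 33.5, speed_cms: float = 20.0,
                 start_distance_cm: float = 30.0,
                 diffusion_step_cm: float = 1.0) -> Trajectory:
    """Synthetic trajectories with constructed ground truth.

    kinds: ``straight_approach`` (radial run at constant speed from
    ``start_distance_cm`` toward the origin, then parked), ``wall_follower``
    (constant angular sweep at the wall), ``random_walk`` (reflected isotropic
    Gaussian steps of rms ``diffusion_step_cm``), ``conditioned_like``
    (wall-following with periodic straight runs to the centre and back,
    reward markers on arrival).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * FRAME_S
    events: list = []
    if kind == "straight_approach":
        d = np.maximum(start_distance_cm - speed_cms * t, 0.0)
        xy = np.column_stack([d, np.zeros(n_frames)])
    elif kind == "wall_follower":
        r = arena_radius_cm - 1.0
        omega = speed_cms / r
        ang = omega * t
        xy = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    elif kind == "random_walk":
        steps = rng.normal(0.0, diffusion_step_cm / math.sqrt(2.0),
                           (n_frames, 2))
        xy = np.cumsum(steps, axis=0)
        rad = np.hypot(*xy.T)
        too_far = rad > arena_radius_cm
        xy[too_far] *= (arena_radius_cm / rad[too_far])[:, None]
    elif kind == "conditioned_like":
        xy = np.zeros((n_frames, 2))
        pos = np.array([arena_radius_cm - 1.0, 0.0])
        phase, run_len = "wall", 0
        for i in range(n_frames):
            if phase == "wall":
                ang = math.atan2(pos[1], pos[0]) + speed_cms * FRAME_S / \
                    (arena_radius_cm - 1.0)
                pos = (arena_radius_cm - 1.0) * np.array(
                    [math.cos(ang), math.sin(ang)])
                run_len += 1
                if run_len > 40 and rng.random() < 0.05:
                    phase, run_len = "in", 0
            elif phase == "in":
                r = np.hypot(*pos)
                step = min(speed_cms * FRAME_S, r)
                pos = pos * (1.0 - step / r) if r > 0 else pos
                if np.hypot(*pos) < 3.0:
                    events.append((t[i], "reward_entry"))
                    phase, run_len = "out", 0
            else:  # outbound after a reward
                r = max(np.hypot(*pos), 1e-9)
                pos = pos * ((r + speed_cms * FRAME_S) / r)
                if np.hypot(*pos) >= arena_radius_cm - 1.0:
                    pos *= (arena_radius_cm - 1.0) / np.hypot(*pos)
                    phase, run_len = "wall", 0
            xy[i] = pos
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return Trajectory(t, xy, events)
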