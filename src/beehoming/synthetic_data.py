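"""Synthetic flight trajectories with the statistics the analysis assumes.

The study's raw recordings are not deposited, so this module generates
stand-in flights whose *statistical* structure matches what the analysis
pipeline relies on: 74 Hz 3D tracks of up to 5 minutes, search time
concentrated near one or two attractor locations (the fictive nests of a
cue-conflict condition), and an altitude distribution whose 75th
percentile sits at 20.63 cm (median near the 6 cm flight height). The
horizontal path is a mean-reverting (AR(1)/Ornstein-Uhlenbeck) walk whose
set point switches between attractor-centred search bouts and diffuse
wandering through a two-state semi-Markov process with exponential dwell
times; altitude follows a log-space AR(1) with a log-normal stationary
law. No claim of biomechanical realism is made.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.stats import norm

from .behaviour import Trajectory
from .scene import ArenaGeometry, ConflictCondition, fictive_nests

__all__ = ["SearchProfile", "simulate_flights", "paper_like_dataset", "SCENARIOS"]

_Z75 = norm.ppf(0.75)  # standard-normal 75th percentile


@dataclass(frozen=True)
class SearchProfile:
    """Parameters of the synthetic search-flight generator.

    ``attractors`` maps locations to occupancy weights; weights must sum
    to at most 1, the remainder being spent in diffuse wandering. ``seed``
    fully determines the output.
    """

    attractors: tuple = field(default=((np.zeros(2), 1.0),))
    spread: float = 8.0  # cm, stationary per-axis s.d. during a search bout
    altitude_q75: float = 20.63  # cm, pooled 75th percentile target
    altitude_median: float = 6.0  # cm, typical search flight height
    frame_rate: float = 74.0  # Hz
    duration: float = 300.0  # s per flight
    n_flights: int = 8
    seed: int = 0
    arena_radius: float = 75.0
    bout_mean_s: float = 6.0  # mean dwell in an attractor-centred bout
    tau_xy_s: float = 1.5  # horizontal mean-reversion time constant
    tau_z_s: float = 0.5  # altitude (log-space) time constant
    wander_spread: float = 34.0  # cm, per-axis s.d. of diffuse wandering

    def __post_init__(self) -> None:
        w = sum(float(w) for _, w in self.attractors)
        if w > 1.0 + 1e-9:
            raise ValueError("attractor weights must sum to at most 1")
        if self.duration > 300.0:
            raise ValueError("flights last at most 300 s")
        for p, _ in self.attractors:
            if np.hypot(*np.asarray(p, dtype=float)) >= self.arena_radius:
                raise ValueError(f"attractor {p} outside the arena")


def _ar1(target: np.ndarray, noise_sd: np.ndarray, a: float, x0: float, rng) -> np.ndarray:
    """x[k] = a x[k-1] + (1-a) target[k] + eps[k], vectorized via lfilter."""
    eps = rng.standard_normal(target.size) * noise_sd
    drive = (1.0 - a) * target + eps
    drive[0] += a * x0
    return lfilter([1.0], [1.0, -a], drive)


def _switch_schedule(profile: SearchProfile, n: int, dt: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample target positions and in-bout flags from the semi-Markov
    switching process (attractor bouts alternating with wandering)."""
    weights = np.array([float(w) for _, w in profile.attractors])
    points = [np.asarray(p, dtype=float) for p, _ in profile.attractors]
    total = weights.sum()
    # mean wander dwell chosen so attractor occupancy matches sum of weights
    tau_a = profile.bout_mean_s
    tau_w = tau_a * (1.0 - total) / total if total > 1e-9 else np.inf
    targets = np.zeros((n, 2))
    in_bout = np.zeros(n, dtype=bool)
    k = 0
    state_wander = total < 1e-9 or (tau_w > 0 and rng.random() < (1.0 - total))
    while k < n:
        if state_wander:
            dwell = rng.exponential(tau_w) if np.isfinite(tau_w) else profile.duration
            m = max(1, int(round(dwell / dt)))
            m = min(m, n - k)
            # diffuse wandering drifts about the arena centre
            targets[k : k + m] = 0.0
            k += m
            state_wander = False
        else:
            if total <= 1e-9:
                state_wander = True
                continue
            i = rng.choice(len(points), p=weights / total)
            dwell = rng.exponential(tau_a)
            m = max(1, int(round(dwell / dt)))
            m = min(m, n - k)
            targets[k : k + m] = points[i]
            in_bout[k : k + m] = True
            k += m
            state_wander = np.isfinite(tau_w) and tau_w > 1e-9
    return targets, in_bout


def simulate_flights(profile: SearchProfile) -> list[Trajectory]:
    """Generate the flights described by a :class:`SearchProfile`.

    Deterministic for a given seed; every sample respects the arena bounds
    (positions beyond the wall are folded back radially) and time is
    strictly increasing at the nominal frame rate.
    """
    rng = np.random.default_rng(profile.seed)
    dt = 1.0 / profile.frame_rate
    n = int(round(profile.duration * profile.frame_rate))
    a_xy = math.exp(-dt / profile.tau_xy_s)
    a_z = math.exp(-dt / profile.tau_z_s)
    mu_z = math.log(profile.altitude_median)
    sigma_z = math.log(profile.altitude_q75 / profile.altitude_median) / _Z75
    r_max = profile.arena_radius - 1.0

    flights = []
    for i in range(profile.n_flights):
        targets, in_bout = _switch_schedule(profile, n, dt, rng)
        sd = np.where(in_bout, profile.spread, profile.wander_spread)
        noise_sd = sd * math.sqrt(1.0 - a_xy * a_xy)
        # enter near the wall, as bees do from the foraging chamber
        entry_angle = rng.uniform(0.0, 2.0 * math.pi)
        x0 = (r_max - 5.0) * math.cos(entry_angle)
        y0 = (r_max - 5.0) * math.sin(entry_angle)
        x = _ar1(targets[:, 0], noise_sd, a_xy, x0, rng)
        y = _ar1(targets[:, 1], noise_sd, a_xy, y0, rng)
        # radial fold keeps samples inside the wall without a sharp cut
        r = np.hypot(x, y)
        over = r > r_max
        if over.any():
            scale = (2.0 * r_max - r[over]) / r[over]
            x[over] *= scale
            y[over] *= scale
        g = _ar1(
            np.zeros(n), np.full(n, math.sqrt(1.0 - a_z * a_z)), a_z,
            rng.standard_normal(), rng,
        )
        z = np.exp(mu_z + sigma_z * g)
        np.clip(z, 0.1, 89.5, out=z)
        flights.append(
            Trajectory(
                flight_id=f"flight{i:03d}",
                t=np.arange(n) * dt,
                x=x,
                y=y,
                z=z,
            )
        )
    return flights


SCENARIOS = ("stripes_dominant", "both_nests", "compromise_control")


def paper_like_dataset(
    condition: ConflictCondition | str,
    scenario: str = "stripes_dominant",
    geometry: ArenaGeometry | None = None,
    n_flights: int = 8,
    duration: float = 300.0,
    seed: int = 0,
    spread: float = 8.0,
) -> list[Trajectory]:
    """Flights searching at a condition's fictive nests.

    Scenarios mirror the qualitative outcomes of the cue-conflict
    experiments: ``stripes_dominant`` (most search at the stripes' fictive
    nest, some at the cylinders'), ``both_nests`` (both visited equally) and
    ``compromise_control`` — a negative control searching at the midpoint
    between the fictive nests, which real bees did not show.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if isinstance(condition, str):
        condition = ConflictCondition.from_label(condition)
    geometry = geometry if geometry is not None else ArenaGeometry()
    p_cyl, p_str = fictive_nests(condition, geometry)
    if scenario == "stripes_dominant":
        attractors = ((p_cyl, 0.15), (p_str, 0.70))
    elif scenario == "both_nests":
        attractors = ((p_cyl, 0.40), (p_str, 0.40))
    else:  # compromise_control
        attractors = ((0.5 * (p_cyl + p_str), 0.80),)
    profile = SearchProfile(
        attractors=attractors,
        spread=spread,
        n_flights=n_flights,
        duration=duration,
        seed=seed,
        arena_radius=geometry.radius,
    )
    flights = simulate_flights(profile)
    for tr in flights:
        tr.condition = condition.label
    return flights
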