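"""Synthetic microtubule tip trajectories.

Two generators: a drift–diffusion model of steady growth (the stochastic
process whose ensemble MSD is v_g^2 tau^2 + 2 D_p tau + const), and a
two-state telegraph model of dynamic instability (exponential growth and
shrinkage phase durations) feeding the event-frequency estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Trajectory

__all__ = [
    "TrajectoryParams",
    "InstabilityParams",
    "simulate_length_trajectory",
    "simulate_dynamic_instability",
]


def _check_finite(**kwargs):
    for name, value in kwargs.items():
        if not np.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass
class TrajectoryParams:
    """Drift–diffusion growth parameters.

    v_g : mean growth speed, nm/s.
    D_p : polymerization diffusion coefficient, nm^2/s (variance of the
          length increments grows as 2*D_p*tau beyond the drift term).
    sigma_err : per-frame localization error SD, nm.
    dt : sampling interval, s (0.7 s in the imaging this emulates).
    duration : total recording time, s (300 s = 5 min).
    """

    v_g: float
    D_p: float = 0.0
    sigma_err: float = 0.0
    dt: float = 0.7
    duration: float = 300.0
    seed: int | None = None

    def __post_init__(self):
        _check_finite(v_g=self.v_g, D_p=self.D_p, sigma_err=self.sigma_err,
                      dt=self.dt, duration=self.duration)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least dt")
        if self.D_p < 0:
            raise ValueError("D_p must be non-negative")
        if self.sigma_err < 0:
            raise ValueError("sigma_err must be non-negative")


@dataclass
class InstabilityParams:
    """Telegraph (dynamic instability) parameters.

    Growth at v_g nm/s interrupted by catastrophes at rate f_cat (min^-1);
    shrinkage at v_s nm/s ended by rescue at rate f_res (min^-1) or by
    reaching the stable seed (reflecting floor at seed_length).
    """

    v_g: float
    v_s: float
    f_cat: float
    f_res: float
    seed_length: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        _check_finite(v_g=self.v_g, v_s=self.v_s, f_cat=self.f_cat,
                      f_res=self.f_res, seed_length=self.seed_length)
        if self.v_s <= 0:
            raise ValueError("v_s must be positive")
        if self.f_cat < 0 or self.f_res < 0:
            raise ValueError("rates must be non-negative")


def simulate_length_trajectory(params: TrajectoryParams, rng=None) -> Trajectory:
    """Simulate one drift–diffusion growth trajectory.

    True increments per frame are v_g*dt + sqrt(2*D_p*dt)*xi with xi ~ N(0,1);
    the observed length adds independent N(0, sigma_err^2) per frame, so
    observed increment variance carries a 2*sigma_err^2 contribution.
    """
    rng = np.random.default_rng(params.seed if rng is None else rng)
    n = int(np.floor(params.duration / params.dt)) + 1
    times = np.arange(n) * params.dt
    steps = params.v_g * params.dt + np.sqrt(2.0 * params.D_p * params.dt) * rng.standard_normal(n - 1)
    true = np.concatenate([[0.0], np.cumsum(steps)])
    observed = true + params.sigma_err * rng.standard_normal(n)
    return Trajectory(times, true, observed)


def simulate_dynamic_instability(
    params: InstabilityParams, duration: float, dt: float, rng=None
) -> Trajectory:
    """Simulate a telegraph growth/shrink trajectory sampled on a dt grid.

    Phase durations are exponential with the stated rates; a shrink phase
    ends at rescue, on reaching seed_length (reflecting, resumes growth
    without counting as a rescue), or at the end of the recording.  The
    returned Trajectory carries per-sample ground-truth phase labels.
    """
    if dt <= 0 or duration < dt:
        raise ValueError("need dt > 0 and duration >= dt")
    rng = np.random.default_rng(params.seed if rng is None else rng)
    rate_cat = params.f_cat / 60.0  # s^-1
    rate_res = params.f_res / 60.0

    # event-driven pass: piecewise-linear true length
    t, L = 0.0, params.seed_length
    knot_t, knot_L, knot_phase = [0.0], [L], []
    state = "growth"
    while t < duration:
        if state == "growth":
            tau = rng.exponential(1.0 / rate_cat) if rate_cat > 0 else np.inf
            t_end = min(t + tau, duration)
            L = L + params.v_g * (t_end - t)
            knot_t.append(t_end)
            knot_L.append(L)
            knot_phase.append("growth")
            state = "shrink"
        else:
            tau = rng.exponential(1.0 / rate_res) if rate_res > 0 else np.inf
            t_floor = (L - params.seed_length) / params.v_s
            t_end = min(t + min(tau, t_floor), duration)
            L = L - params.v_s * (t_end - t)
            knot_t.append(t_end)
            knot_L.append(L)
            knot_phase.append("shrink")
            state = "growth"
        t = t_end

    n = int(np.floor(duration / dt)) + 1
    times = np.arange(n) * dt
    knot_t = np.asarray(knot_t)
    knot_L = np.asarray(knot_L)
    true = np.interp(times, knot_t, knot_L)
    # phase at each sample = phase of the interval containing it
    idx = np.clip(np.searchsorted(knot_t, times, side="right") - 1, 0, len(knot_phase) - 1)
    phases = np.asarray(knot_phase, dtype=object)[idx]
    return Trajectory(times, true, true.copy(), phases=phases)
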