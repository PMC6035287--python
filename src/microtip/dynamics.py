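"""Trajectory segmentation, event statistics and molecule counting.

Piecewise-linear segmentation locates phases of constant average speed in a
tip trajectory with an exact dynamic program (SSD cost + per-segment
penalty), followed by a continuous hinge-basis refit.  Segments are
classified into growth / shrinkage / pause by speed thresholds, transitions
give catastrophe and rescue counts, and event frequencies carry the field's
standard errors: f/sqrt(N_events) for catastrophes and repair events, a
ratio-based SE for rescues, switching to the Poisson rule SE = f/sqrt(N_r)
when the rescue count is small (<= 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import Trajectory

__all__ = [
    "PhaseSegment",
    "EventTable",
    "FreqEstimate",
    "segment_piecewise_linear",
    "classify_events",
    "frequency_estimates",
    "count_molecules",
    "DEFAULT_SPEED_THRESHOLD",
]

DEFAULT_SPEED_THRESHOLD = 8.3
"""Default growth/shrink speed threshold, nm/s (0.5 um/min)."""


@dataclass
class PhaseSegment:
    """One constant-speed segment of a trajectory."""

    t_start: float
    t_end: float
    slope: float  # nm/s
    phase: str | None = None
    y_start: float = np.nan
    y_end: float = np.nan

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class EventTable:
    """Classified phase transitions and observation times.

    Times are in minutes for direct use in the frequency estimators;
    per-event records hold the transition times (s) and tip positions (nm).
    """

    n_catastrophes: int
    n_rescues: int
    n_repair_events: int
    total_growth_time: float  # min
    total_shrink_time: float  # min
    catastrophe_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    catastrophe_positions: np.ndarray = field(default_factory=lambda: np.empty(0))
    rescue_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    rescue_positions: np.ndarray = field(default_factory=lambda: np.empty(0))
    shrink_durations: np.ndarray = field(default_factory=lambda: np.empty(0))  # min

    def __post_init__(self):
        if self.n_catastrophes != len(self.catastrophe_times):
            raise ValueError("catastrophe count must match records")
        if self.n_rescues != len(self.rescue_times):
            raise ValueError("rescue count must match records")

    def __add__(self, other: "EventTable") -> "EventTable":
        return EventTable(
            self.n_catastrophes + other.n_catastrophes,
            self.n_rescues + other.n_rescues,
            self.n_repair_events + other.n_repair_events,
            self.total_growth_time + other.total_growth_time,
            self.total_shrink_time + other.total_shrink_time,
            np.concatenate([self.catastrophe_times, other.catastrophe_times]),
            np.concatenate([self.catastrophe_positions, other.catastrophe_positions]),
            np.concatenate([self.rescue_times, other.rescue_times]),
            np.concatenate([self.rescue_positions, other.rescue_positions]),
            np.concatenate([self.shrink_durations, other.shrink_durations]),
        )


@dataclass
class FreqEstimate:
    """Event frequency (min^-1) with its standard error and method tag."""

    value: float
    se: float
    n_events: int
    method: str
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("se must be non-negative")


# ---------------------------------------------------------------------------
# segmentation


def _segment_cost_tables(t, y):
    """Prefix sums enabling O(1) OLS residual cost for any segment [i, j)."""
    def prefix(v):
        return np.cumsum(np.concatenate([[0.0], v]))

    return {"t": prefix(t), "tt": prefix(t * t), "y": prefix(y),
            "yy": prefix(y * y), "ty": prefix(t * y)}


def _sse(cs, i, j):
    """OLS line-fit SSE on samples i..j-1 (vectorized over array i)."""
    n = j - i
    st = cs["t"][j] - cs["t"][i]
    stt = cs["tt"][j] - cs["tt"][i]
    sy = cs["y"][j] - cs["y"][i]
    syy = cs["yy"][j] - cs["yy"][i]
    sty = cs["ty"][j] - cs["ty"][i]
    with np.errstate(divide="ignore", invalid="ignore"):
        stt_c = stt - st * st / n
        sty_c = sty - st * sy / n
        syy_c = syy - sy * sy / n
        sse = syy_c - np.where(stt_c > 1e-12, sty_c**2 / np.maximum(stt_c, 1e-300), 0.0)
    return np.maximum(sse, 0.0)


def _auto_penalty(t, y):
    """BIC-style default: 3 * sigma^2 * log(n), noise SD from 2nd differences."""
    d2 = np.diff(y, 2)
    sigma = 1.4826 * np.median(np.abs(d2)) / np.sqrt(6.0) if len(d2) else 1.0
    sigma = max(sigma, 1e-6)
    return 3.0 * sigma**2 * np.log(len(y))


def _refine_knots(t, y, knots, halfwidth=4, subdiv=4, sweeps=2):
    """Refine breakpoint positions under the continuous piecewise-linear model.

    The dynamic program places boundaries for *independent* segment fits;
    for a continuous kink the optimal knot can sit a couple of samples
    away.  Each knot is swept over a sub-sample grid around its current
    position (holding the others fixed) and moved to the least-squares
    optimum of the hinge-basis fit.
    """
    knots = list(np.atleast_1d(np.asarray(knots, dtype=float)))
    dt = np.median(np.diff(t))

    def sse(cand):
        X = np.column_stack([np.ones_like(t), t] +
                            [np.maximum(t - kt, 0.0) for kt in cand])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    for _ in range(sweeps):
        for i in range(len(knots)):
            lo = knots[i - 1] + dt if i > 0 else t[0] + dt
            hi = knots[i + 1] - dt if i + 1 < len(knots) else t[-1] - dt
            grid = knots[i] + np.arange(-halfwidth * subdiv, halfwidth * subdiv + 1) \
                * (dt / subdiv)
            grid = grid[(grid > lo) & (grid < hi)]
            if grid.size == 0:
                continue
            scores = [sse(knots[:i] + [g] + knots[i + 1:]) for g in grid]
            knots[i] = float(grid[int(np.argmin(scores))])
    return np.asarray(knots)


def segment_piecewise_linear(traj: Trajectory, penalty=None, min_size=5,
                             continuous=True):
    """Penalized change-point decomposition into constant-speed segments.

    Breakpoints minimize sum-of-squared-deviations + penalty * (#segments)
    exactly (dynamic program over all breakpoint placements, O(n^2));
    with ``continuous=True`` (default) the final slopes come from a
    continuous piecewise-linear refit on the hinge basis at the selected
    breakpoints.  ``penalty=None`` selects a BIC-style default from the
    estimated noise level.
    """
    if len(traj) < 10:
        raise ValueError("need at least 10 samples to segment")
    t = traj.times
    y = traj.observed_lengths
    if penalty is None:
        penalty = _auto_penalty(t, y)
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    n = len(t)
    cs = _segment_cost_tables(t, y)

    best = np.full(n + 1, np.inf)
    best[0] = 0.0
    back = np.zeros(n + 1, dtype=int)
    for j in range(min_size, n + 1):
        i = np.arange(0, j - min_size + 1)
        cand = best[i] + _sse(cs, i, j) + penalty
        k = int(np.argmin(cand))
        best[j] = cand[k]
        back[j] = i[k]

    # recover breakpoints
    bounds = [n]
    j = n
    while j > 0:
        j = back[j]
        bounds.append(j)
    bounds = bounds[::-1]  # 0 = b0 < b1 < ... = n

    if continuous and len(bounds) > 2:
        knots = _refine_knots(t, y, t[np.asarray(bounds[1:-1])])
        X = np.column_stack([np.ones(n), t] +
                            [np.maximum(t - kt, 0.0) for kt in knots])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        yhat = X @ coef
        slopes = coef[1] + np.concatenate([[0.0], np.cumsum(coef[2:])])
        seg_bounds = [t[0]] + list(knots) + [t[-1]]
        fit_at = np.interp(seg_bounds, t, yhat)
        segments = [
            PhaseSegment(seg_bounds[k], seg_bounds[k + 1], float(slopes[k]),
                         y_start=float(fit_at[k]), y_end=float(fit_at[k + 1]))
            for k in range(len(slopes))
        ]
    else:
        segments = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            tt, yy = t[a:b], y[a:b]
            A = np.column_stack([np.ones(b - a), tt])
            coef, *_ = np.linalg.lstsq(A, yy, rcond=None)
            t0 = t[a]
            t1 = t[b] if b < n else t[-1]
            if t1 <= t0:
                t1 = t0 + (t[1] - t[0])
            segments.append(PhaseSegment(
                t0, t1, float(coef[1]),
                y_start=float(coef[0] + coef[1] * t0),
                y_end=float(coef[0] + coef[1] * t1),
            ))
    return segments


# ---------------------------------------------------------------------------
# event classification and frequencies


def classify_events(
    segments,
    v_growth_min: float = DEFAULT_SPEED_THRESHOLD,
    v_shrink_min: float = DEFAULT_SPEED_THRESHOLD,
    repair_intervals=None,
) -> EventTable:
    """Classify segments into phases and count catastrophes and rescues.

    A segment is growth when slope >= v_growth_min, shrinkage when
    slope <= -v_shrink_min, pause otherwise.  A catastrophe is any
    growth-or-pause -> shrinkage transition; a rescue is shrinkage ->
    growth-or-pause.  Tip-repair events cannot be inferred from a single tip
    trace — they need a paired lagging-comet track — so they are supplied as
    ``repair_intervals``: (t_split, t_merge) pairs in seconds.
    """
    if v_growth_min <= 0 or v_shrink_min <= 0:
        raise ValueError("speed thresholds must be positive")
    segments = sorted(segments, key=lambda s: s.t_start)
    for a, b in zip(segments[:-1], segments[1:]):
        if b.t_start < a.t_end - 1e-9:
            raise ValueError("segments overlap in time")
    for seg in segments:
        if seg.slope >= v_growth_min:
            seg.phase = "growth"
        elif seg.slope <= -v_shrink_min:
            seg.phase = "shrink"
        else:
            seg.phase = "pause"

    growth_time = sum(s.duration for s in segments if s.phase == "growth") / 60.0
    shrink_time = sum(s.duration for s in segments if s.phase == "shrink") / 60.0
    shrink_durations = np.asarray(
        [s.duration / 60.0 for s in segments if s.phase == "shrink"])

    cat_t, cat_x, res_t, res_x = [], [], [], []
    for prev, cur in zip(segments[:-1], segments[1:]):
        if prev.phase in ("growth", "pause") and cur.phase == "shrink":
            cat_t.append(cur.t_start)
            cat_x.append(cur.y_start)
        elif prev.phase == "shrink" and cur.phase in ("growth", "pause"):
            res_t.append(cur.t_start)
            res_x.append(cur.y_start)

    n_rep = 0 if repair_intervals is None else len(repair_intervals)
    return EventTable(
        n_catastrophes=len(cat_t),
        n_rescues=len(res_t),
        n_repair_events=n_rep,
        total_growth_time=growth_time,
        total_shrink_time=shrink_time,
        catastrophe_times=np.asarray(cat_t),
        catastrophe_positions=np.asarray(cat_x),
        rescue_times=np.asarray(res_t),
        rescue_positions=np.asarray(res_x),
        shrink_durations=shrink_durations,
    )


def frequency_estimates(events: EventTable, poisson_threshold: int = 10) -> dict:
    """Catastrophe, rescue and tip-repair frequencies with standard errors.

    f_cat = N_cat / total growth time with SE = f / sqrt(N_cat);
    f_res = N_res / total shrinkage time with the ratio-based SE
    f_res * SE(t_sh) / mean(t_sh), switching to the Poisson rule
    SE = f_res / sqrt(N_res) when N_res <= ``poisson_threshold``;
    f_repair = N_repair / total growth time with SE = f / sqrt(N_repair).
    Zero event counts give frequency 0, SE 0 and a 'low_information' flag;
    zero observation time gives NaN with an 'undefined' flag.
    """

    def _count_rate(n, time_min):
        if time_min <= 0:
            return FreqEstimate(np.nan, 0.0, n, "ratio_se", flags=["undefined"])
        f = n / time_min
        if n == 0:
            return FreqEstimate(0.0, 0.0, 0, "ratio_se", flags=["low_information"])
        return FreqEstimate(f, f / np.sqrt(n), n, "ratio_se")

    f_cat = _count_rate(events.n_catastrophes, events.total_growth_time)
    f_rep = _count_rate(events.n_repair_events, events.total_growth_time)

    n_r = events.n_rescues
    if events.total_shrink_time <= 0:
        f_res = FreqEstimate(np.nan, 0.0, n_r, "ratio_se", flags=["undefined"])
    else:
        f = n_r / events.total_shrink_time
        if n_r == 0:
            f_res = FreqEstimate(0.0, 0.0, 0, "poisson_se", flags=["low_information"])
        elif n_r <= poisson_threshold:
            f_res = FreqEstimate(f, f / np.sqrt(n_r), n_r, "poisson_se")
        else:
            d = events.shrink_durations
            t_mean = float(np.mean(d))
            se_t = float(np.std(d, ddof=1) / np.sqrt(len(d))) if len(d) > 1 else 0.0
            f_res = FreqEstimate(f, f * se_t / t_mean, n_r, "ratio_se")
    return {"f_cat": f_cat, "f_res": f_res, "f_repair": f_rep}


# ---------------------------------------------------------------------------
# single-molecule intensity counting


def count_molecules(spot_intensities, reference_intensities, bin_width=0.5):
    """Convert spot intensities to molecule counts via single-molecule calibration.

    Each spot intensity is divided by the mean single-molecule reference
    intensity (measured in an adjacent chamber under identical imaging).
    Returns (counts, (histogram, bin_edges)) with bins of ``bin_width``
    molecules starting at zero.
    """
    spots = np.asarray(spot_intensities, dtype=float)
    refs = np.asarray(reference_intensities, dtype=float)
    if refs.size == 0:
        raise ValueError("reference set must be non-empty")
    ref_mean = float(np.mean(refs))
    if ref_mean <= 0:
        raise ValueError("mean reference intensity must be positive")
    counts = spots / ref_mean
    top = max(np.ceil(counts.max() / bin_width) * bin_width, bin_width) if counts.size else bin_width
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    hist, edges = np.histogram(counts, bins=edges)
    return counts, (hist, edges)
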