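"""Core data containers shared across the package.

Units are fixed package-wide: axial positions and lengths in nm, times in s,
event frequencies in min^-1, tubulin concentrations in uM.  Intensity is in
arbitrary units (a.u.); rendered synthetic profiles use "labeled dimers per
pixel" as their natural unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntensityProfile",
    "Trajectory",
    "AveragedProfile",
    "OutgrowthTable",
]


def _as1d(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class IntensityProfile:
    """One fluorescence line profile (a single kymograph row).

    Parameters
    ----------
    x : array
        Pixel-center coordinates in nm, equally spaced at ``pixel_size``.
    intensity : array
        Intensity per pixel, a.u.
    pixel_size : float
        Pixel pitch in nm (65 nm for the EMCCD data this package emulates).
    """

    x: np.ndarray
    intensity: np.ndarray
    pixel_size: float

    def __post_init__(self):
        self.x = _as1d(self.x, "x")
        self.intensity = _as1d(self.intensity, "intensity")
        if len(self.x) != len(self.intensity):
            raise ValueError("x and intensity must have equal length")
        if len(self.x) >= 2:
            steps = np.diff(self.x)
            if not np.allclose(steps, self.pixel_size, rtol=1e-6, atol=1e-6):
                raise ValueError("x must be equally spaced at pixel_size")
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive and finite")

    def __len__(self) -> int:
        return len(self.x)

    def window(self, center: float, halfwidth: float) -> "IntensityProfile":
        """Return the sub-profile with pixel centers in [center-halfwidth, center+halfwidth]."""
        m = (self.x >= center - halfwidth) & (self.x <= center + halfwidth)
        if not np.any(m):
            raise ValueError("window contains no pixels")
        return IntensityProfile(self.x[m], self.intensity[m], self.pixel_size)


@dataclass
class Trajectory:
    """Time series of microtubule tip position (length).

    ``true_lengths`` is the noise-free ground truth (available for synthetic
    data only); ``observed_lengths`` includes per-frame localization error.
    ``phases`` optionally labels each sample 'growth' / 'shrink' / 'pause'.
    """

    times: np.ndarray
    true_lengths: np.ndarray
    observed_lengths: np.ndarray
    phases: np.ndarray | None = None

    def __post_init__(self):
        self.times = _as1d(self.times, "times")
        self.true_lengths = _as1d(self.true_lengths, "true_lengths")
        self.observed_lengths = _as1d(self.observed_lengths, "observed_lengths")
        n = len(self.times)
        if len(self.true_lengths) != n or len(self.observed_lengths) != n:
            raise ValueError("times and length arrays must have equal length")
        if n >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.phases is not None:
            self.phases = np.asarray(self.phases)
            if len(self.phases) != n:
                raise ValueError("phases must match times in length")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def delta_lengths(self) -> np.ndarray:
        """Length change relative to the first frame, dL(t) = L(t) - L(t0)."""
        return self.observed_lengths - self.observed_lengths[0]


@dataclass
class AveragedProfile:
    """Tip-aligned, normalized, averaged intensity profile on the half-pixel grid.

    ``grid`` holds coordinates relative to the fitted tip position, spaced at
    half a pixel (32.5 nm by default); negative coordinates are behind the tip
    (on the lattice) when profiles are oriented lattice-at-lower-x.
    """

    grid: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_profiles: int
    n_kymographs: int
    grid_step: float = 32.5

    def __post_init__(self):
        self.grid = _as1d(self.grid, "grid")
        self.mean = _as1d(self.mean, "mean")
        self.sem = _as1d(self.sem, "sem")
        if not (len(self.grid) == len(self.mean) == len(self.sem)):
            raise ValueError("grid, mean and sem must have equal length")
        if len(self.grid) >= 2:
            if not np.allclose(np.diff(self.grid), self.grid_step, atol=1e-9):
                raise ValueError("grid must be equally spaced at grid_step")
        if np.any(self.sem < -1e-12):
            raise ValueError("sem must be non-negative")

    def __len__(self) -> int:
        return len(self.grid)


@dataclass
class OutgrowthTable:
    """Seed-outgrowth counts versus tubulin concentration.

    One row per tubulin concentration: the number of GMPCPP seeds observed
    and the number that nucleated a microtubule within the imaging window.
    """

    concentrations: np.ndarray
    n_seeds: np.ndarray
    n_outgrown: np.ndarray

    def __post_init__(self):
        self.concentrations = _as1d(self.concentrations, "concentrations")
        self.n_seeds = np.asarray(self.n_seeds, dtype=int)
        self.n_outgrown = np.asarray(self.n_outgrown, dtype=int)
        n = len(self.concentrations)
        if len(self.n_seeds) != n or len(self.n_outgrown) != n:
            raise ValueError("all columns must have equal length")
        if np.any(self.n_seeds <= 0):
            raise ValueError("n_seeds must be positive")
        if np.any(self.n_outgrown < 0) or np.any(self.n_outgrown > self.n_seeds):
            raise ValueError("need 0 <= n_outgrown <= n_seeds elementwise")

    @property
    def fractions(self) -> np.ndarray:
        return self.n_outgrown / self.n_seeds

    def __len__(self) -> int:
        return len(self.concentrations)
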