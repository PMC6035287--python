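"""Protofilament lattice models of the microtubule tip and profile rendering.

The microtubule is a 13-protofilament regular array with 8 nm longitudinal
dimer spacing, projected onto a single axial coordinate (the lateral extent
is far below the diffraction limit).  A tip configuration is described by
the axial length missing from each protofilament relative to the longest one:

* Model A ("sharp"): N protofilaments are all shortened by the same length d.
* Model B ("gradual"): the N missing lengths are i.i.d. exponential, mean d.

Rendering: present dimers are fluorescently labeled with a Bernoulli
probability (0.09 by default, the labeled-tubulin fraction), each labeled
dimer contributes a unit-mass Gaussian (the PSF) and intensities are
integrated over camera pixels; Gaussian noise is scaled so that the lattice
plateau sits at the requested signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .containers import IntensityProfile
from .profiles import add_noise, plateau_mean

__all__ = [
    "TaperModelSpec",
    "LatticeConfig",
    "RenderParams",
    "sample_taper_config",
    "render_profile",
    "N_PROTOFILAMENTS",
    "DIMER_SPACING",
]

N_PROTOFILAMENTS = 13
DIMER_SPACING = 8.0  # nm


@dataclass
class TaperModelSpec:
    """Tip-erosion hypothesis: model 'A' (sharp) or 'B' (gradual), with
    N eroded protofilaments (0..13) and characteristic missing length d (nm)."""

    model: str
    N: int
    d: float

    def __post_init__(self):
        if self.model not in ("A", "B"):
            raise ValueError("model must be 'A' or 'B'")
        if not 0 <= self.N <= N_PROTOFILAMENTS:
            raise ValueError(f"N must be in 0..{N_PROTOFILAMENTS}")
        if self.d < 0:
            raise ValueError("d must be non-negative")


@dataclass
class RenderParams:
    """Optical and labeling parameters for profile rendering.

    Defaults reproduce the imaging conditions this package emulates:
    9% labeled tubulin, Gaussian PSF sigma 122 nm, 65 nm pixels, SNR 7.
    ``fov`` is the rendered field of view (nm); rendering pads the lattice
    with a >= 4*psf_sigma margin so both edges decay to background inside
    the field.
    """

    label_fraction: float = 0.09
    psf_sigma: float = 122.0
    pixel_size: float = 65.0
    snr: float = 7.0
    fov: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.label_fraction <= 1.0:
            raise ValueError("label_fraction must be in [0, 1]")
        if self.psf_sigma <= 0 or self.pixel_size <= 0:
            raise ValueError("psf_sigma and pixel_size must be positive")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.fov is not None and self.fov <= 0:
            raise ValueError("fov must be positive")


@dataclass
class LatticeConfig:
    """One simulated tip: per-protofilament missing lengths plus the axial
    coordinates of the labeled dimers (with multiplicity across
    protofilaments; all 13 project onto one axis).

    The lattice spans [0, lattice_length]; the plus end (tip) is at high x
    and erosion removes dimers from the plus end.
    """

    lattice_length: float
    missing_per_pf: np.ndarray
    labeled_positions: np.ndarray
    n_pf: int = N_PROTOFILAMENTS
    dimer_spacing: float = DIMER_SPACING

    def __post_init__(self):
        self.missing_per_pf = np.asarray(self.missing_per_pf, dtype=float)
        self.labeled_positions = np.asarray(self.labeled_positions, dtype=float)
        if len(self.missing_per_pf) != self.n_pf:
            raise ValueError("missing_per_pf must have one entry per protofilament")
        if np.any(self.missing_per_pf < 0) or np.any(self.missing_per_pf > self.lattice_length + 1e-9):
            raise ValueError("missing lengths must lie in [0, lattice_length]")
        res = np.abs(self.missing_per_pf / self.dimer_spacing
                     - np.round(self.missing_per_pf / self.dimer_spacing))
        if np.any(res > 1e-6):
            raise ValueError("missing lengths must be multiples of the dimer spacing")


def n_sites(lattice_length: float, spacing: float = DIMER_SPACING) -> int:
    return int(round(lattice_length / spacing))


def site_centers(lattice_length: float, spacing: float = DIMER_SPACING) -> np.ndarray:
    """Axial dimer-site centers: (j + 1/2) * spacing for j = 0 .. n_sites-1."""
    return (np.arange(n_sites(lattice_length, spacing)) + 0.5) * spacing


def sample_missing_lengths(spec: TaperModelSpec, lattice_length: float, rng) -> np.ndarray:
    """Draw the 13 per-protofilament missing lengths on the 8 nm grid."""
    if spec.model == "A" and lattice_length < spec.d:
        raise ValueError("lattice_length must be >= d for Model A")
    missing = np.zeros(N_PROTOFILAMENTS)
    if spec.N > 0:
        if spec.model == "A":
            eroded = np.full(spec.N, float(spec.d))
        else:
            eroded = rng.exponential(spec.d, size=spec.N) if spec.d > 0 else np.zeros(spec.N)
        eroded = np.minimum(eroded, lattice_length)
        missing[:spec.N] = eroded
    # discretize to whole dimers
    missing = np.round(missing / DIMER_SPACING) * DIMER_SPACING
    return np.minimum(missing, n_sites(lattice_length) * DIMER_SPACING)


def sample_taper_config(
    spec: TaperModelSpec, lattice_length: float, seed=None, label_fraction: float = 0.09
) -> LatticeConfig:
    """Sample one lattice configuration: erosion pattern plus Bernoulli labeling."""
    rng = np.random.default_rng(seed)
    missing = sample_missing_lengths(spec, lattice_length, rng)
    centers = site_centers(lattice_length)
    positions = []
    for miss in missing:
        present = centers[centers < lattice_length - miss + 1e-9]
        keep = rng.random(len(present)) < label_fraction
        positions.append(present[keep])
    labeled = np.sort(np.concatenate(positions)) if positions else np.empty(0)
    return LatticeConfig(lattice_length, missing, labeled)


def pixel_edges(x0: float, x1: float, pixel_size: float) -> np.ndarray:
    """Pixel-edge coordinates from x0 up to (at most) x1, step pixel_size."""
    n = int(np.floor((x1 - x0) / pixel_size + 1e-9))
    if n < 2:
        raise ValueError("field of view must span at least two pixels")
    return x0 + np.arange(n + 1) * pixel_size


def psf_pixel_masses(positions: np.ndarray, edges: np.ndarray, psf_sigma: float) -> np.ndarray:
    """Integrated Gaussian mass per pixel for each source position.

    Returns shape (len(positions), len(edges)-1); each row sums to <= 1
    (exactly 1 when the field fully covers the PSF).  Pixel integration uses
    the Gaussian CDF difference across pixel edges, not center sampling.
    """
    if len(positions) == 0:
        return np.zeros((0, len(edges) - 1))
    z = (edges[None, :] - np.asarray(positions, dtype=float)[:, None]) / psf_sigma
    cdf = ndtr(z)
    return np.diff(cdf, axis=1)


def render_profile(config: LatticeConfig, rp: RenderParams, rng=None) -> IntensityProfile:
    """Render one noisy intensity profile from a lattice configuration.

    The field of view is [x0, x0 + fov] with x0 = -4*psf_sigma (rounded down
    to whole pixels) so the minus-end edge at x=0 decays inside the field;
    ``rp.fov`` defaults to lattice_length + 8*psf_sigma.  Noise SD is the
    noiseless lattice-plateau mean divided by ``rp.snr``.
    """
    rng = np.random.default_rng(rp.seed if rng is None else rng)
    margin = 4.0 * rp.psf_sigma
    fov = rp.fov if rp.fov is not None else config.lattice_length + 2 * margin
    if fov < config.lattice_length + 2 * margin - 1e-9:
        raise ValueError("fov must cover the lattice plus a 4*psf_sigma margin per side")
    x0 = -np.ceil(margin / rp.pixel_size) * rp.pixel_size
    edges = pixel_edges(x0, x0 + fov, rp.pixel_size)
    masses = psf_pixel_masses(config.labeled_positions, edges, rp.psf_sigma)
    noiseless = masses.sum(axis=0)
    x = 0.5 * (edges[:-1] + edges[1:])
    tip_base = config.lattice_length - float(np.max(config.missing_per_pf, initial=0.0))
    plateau = plateau_mean(x, noiseless, tip_base, rp.psf_sigma)
    if plateau <= 0:  # empty label set: flat noise floor with unit-scale noise
        plateau = 1.0
    intensity = add_noise(noiseless, rp.snr, plateau, rng)
    return IntensityProfile(x, intensity, rp.pixel_size)


def expected_profile(config_mean_missing, lattice_length, rp: RenderParams, label_fraction=None):
    """Deterministic ensemble-mean profile for a fixed erosion pattern.

    Equals label_fraction times the PSF-convolved, pixel-integrated density
    of present dimer sites; the Monte-Carlo mean of ``render_profile`` over
    labeling realizations converges to this curve.
    """
    p = rp.label_fraction if label_fraction is None else label_fraction
    missing = np.asarray(config_mean_missing, dtype=float)
    margin = 4.0 * rp.psf_sigma
    fov = rp.fov if rp.fov is not None else lattice_length + 2 * margin
    x0 = -np.ceil(margin / rp.pixel_size) * rp.pixel_size
    edges = pixel_edges(x0, x0 + fov, rp.pixel_size)
    centers = site_centers(lattice_length)
    counts = (centers[None, :] < lattice_length - missing[:, None] + 1e-9).sum(axis=0)
    masses = psf_pixel_masses(centers, edges, rp.psf_sigma)
    noiseless = p * counts @ masses
    x = 0.5 * (edges[:-1] + edges[1:])
    return IntensityProfile(x, noiseless, rp.pixel_size)
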