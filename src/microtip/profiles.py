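"""Analytic PSF-convolved intensity models and synthetic profile generators.

All profiles are oriented with the microtubule lattice at lower x and the
growing plus end (tip) at higher x, so the tubulin signal is a *falling* edge:

    I(x) = I_BG + (I_AMP / 2) * erfc((x - x_c) / (sqrt(2) * sigma))

An EB comet is an exponential density decaying away from the tip into the
lattice; convolved with a Gaussian PSF it becomes an exponentially modified
Gaussian (EMG).  A point-like accumulation at the tip convolves to a Gaussian
peak with the PSF width.  These three building blocks are the models fitted
throughout the package.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf, erfc, erfcx

from .containers import IntensityProfile

__all__ = [
    "erf_edge",
    "erfc_edge",
    "emg_comet",
    "step_peak",
    "comet_model",
    "tog2_model",
    "synth_comet_profile",
    "synth_tog2_profile",
    "plateau_mean",
    "add_noise",
]

SIGMA_PSF_DEFAULT = 97.5
"""Fixed PSF standard deviation for point-peak fitting: 1.5 px * 65 nm (nm)."""


def erf_edge(x, i_bg, i_amp, x_c, sigma):
    """Rising error-function edge: background at low x, plateau at high x."""
    x = np.asarray(x, dtype=float)
    return i_bg + 0.5 * i_amp * (1.0 + erf((x - x_c) / (np.sqrt(2.0) * sigma)))


def erfc_edge(x, i_bg, i_amp, x_c, sigma):
    """Falling (complementary) error-function edge: lattice plateau at low x."""
    x = np.asarray(x, dtype=float)
    return i_bg + 0.5 * i_amp * erfc((x - x_c) / (np.sqrt(2.0) * sigma))


def emg_comet(x, i_eb, x_c, sigma, decay_length):
    """PSF-convolved exponential comet (EMG), peak-amplitude parameterization.

    The underlying fluorophore density is exp((x - x_c)/decay_length) for
    x <= x_c and 0 ahead of x_c: the comet maximum sits at ``x_c`` and the
    density decays with characteristic length ``decay_length`` (nm) behind it.
    Convolution with a Gaussian PSF of width ``sigma`` gives

        h(x) = (i_eb / 2) * exp(k^2 s^2/2 + k d) * erfc((d + k s^2)/(sqrt(2) s))

    with d = x - x_c and rate k = 1/decay_length.  Evaluated through the
    scaled complementary error function, h = (i_eb/2) exp(-d^2/2s^2) erfcx(t),
    which cannot overflow for any decay length.
    """
    if decay_length <= 0:
        raise ValueError("decay_length must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    d = x - x_c
    k = 1.0 / decay_length
    t = (d + k * sigma**2) / (np.sqrt(2.0) * sigma)
    # erfcx is stable for t >= 0; for t < 0 the plain product is safe because
    # the exponent is negative wherever that branch is selected (t < 0
    # implies k*d < -(k*sigma)^2/2), so it is zeroed elsewhere before exp.
    pos = 0.5 * np.exp(-0.5 * (d / sigma) ** 2) * erfcx(np.maximum(t, 0.0))
    expo = np.where(t < 0, 0.5 * (k * sigma) ** 2 + k * d, 0.0)
    neg = 0.5 * np.exp(expo) * erfc(np.minimum(t, 0.0))
    return i_eb * np.where(t >= 0, pos, neg)


def comet_model(x, i_bg, i_lattice, i_eb, x_c, sigma, decay_length):
    """Full EB-comet profile: erfc lattice edge plus the EMG comet."""
    return (
        erfc_edge(x, i_bg, i_lattice, x_c, sigma)
        + emg_comet(x, i_eb, x_c, sigma, decay_length)
    )


def step_peak(x, i_bg, i_lattice, i_peak, x_c, x_peak, sigma, sigma_psf=SIGMA_PSF_DEFAULT):
    """Lattice step plus point accumulation: erfc edge + Gaussian peak.

    ``x_peak`` is the peak position relative to the fitted lattice tip ``x_c``
    (negative = behind the tip, on the lattice side).  The peak width is the
    fixed PSF standard deviation because the accumulation is modeled as a
    delta function.
    """
    if sigma_psf <= 0:
        raise ValueError("sigma_psf must be positive")
    x = np.asarray(x, dtype=float)
    peak = i_peak * np.exp(-0.5 * ((x - x_c - x_peak) / sigma_psf) ** 2)
    return erfc_edge(x, i_bg, i_lattice, x_c, sigma) + peak


tog2_model = step_peak


def plateau_mean(x, intensity, x_c, sigma, n_sigma=4.0):
    """Mean intensity over the lattice plateau, >= n_sigma*sigma behind the tip.

    Used as the reference level for signal-to-noise scaling.  Falls back to
    the mean of the five brightest pixels when no pixel lies that far behind
    the tip (heavily eroded tips).
    """
    x = np.asarray(x, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    m = x <= x_c - n_sigma * sigma
    if np.any(m):
        return float(np.mean(intensity[m]))
    k = min(5, len(intensity))
    return float(np.mean(np.sort(intensity)[-k:]))


def add_noise(intensity, snr, plateau, rng):
    """Additive Gaussian noise with SD = plateau / snr (no-op for snr=inf)."""
    if not snr > 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return np.asarray(intensity, dtype=float).copy()
    sd = plateau / snr
    return intensity + rng.normal(0.0, sd, size=np.shape(intensity))


def _pixel_grid(fov, pixel_size):
    n = int(np.floor(fov / pixel_size))
    if n < 2:
        raise ValueError("fov must span at least two pixels")
    return (np.arange(n) + 0.5) * pixel_size


def synth_comet_profile(
    i_bg,
    i_lattice,
    i_eb,
    x_c,
    sigma,
    decay_length,
    *,
    fov,
    pixel_size=65.0,
    snr=np.inf,
    noise=False,
    rng=None,
):
    """Evaluate the EB-comet model at pixel centers, optionally adding noise.

    Noise follows the rendering convention: SD = (lattice plateau mean)/snr.
    """
    x = _pixel_grid(fov, pixel_size)
    y = comet_model(x, i_bg, i_lattice, i_eb, x_c, sigma, decay_length)
    if noise:
        rng = np.random.default_rng(rng)
        y = add_noise(y, snr, plateau_mean(x, y, x_c, sigma), rng)
    return IntensityProfile(x, y, pixel_size)


def synth_tog2_profile(
    i_bg,
    i_lattice,
    i_peak,
    x_c,
    x_peak,
    sigma,
    *,
    sigma_psf=SIGMA_PSF_DEFAULT,
    fov,
    pixel_size=65.0,
    snr=np.inf,
    noise=False,
    rng=None,
):
    """Evaluate the lattice-step + PSF-peak model at pixel centers."""
    x = _pixel_grid(fov, pixel_size)
    y = step_peak(x, i_bg, i_lattice, i_peak, x_c, x_peak, sigma, sigma_psf)
    if noise:
        rng = np.random.default_rng(rng)
        y = add_noise(y, snr, plateau_mean(x, y, x_c, sigma), rng)
    return IntensityProfile(x, y, pixel_size)
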