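"""Nonlinear least-squares fitting of convolved tip-intensity models.

The three models (erf/erfc tip edge, erfc + EMG comet, erfc + Gaussian peak)
share a structure: a few nonlinear shape parameters (positions, widths,
decay lengths) and amplitudes that enter linearly.  Fitting uses variable
projection — the nonlinear parameters are optimized with a bounded
trust-region least-squares solver while the amplitudes are solved exactly by
linear least squares at every step — with multi-start from data-driven
initializations (edge at the steepest gradient, background from the profile
tails), tie-broken by the lowest residual sum of squares.

Results objects carry the fitted parameters, their standard errors (from the
Gauss-Newton approximation of the Hessian at the optimum), the residual sum
of squares, and acceptance flags; downstream averaging consumes only
accepted fits.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .containers import AveragedProfile, IntensityProfile
from .profiles import (
    SIGMA_PSF_DEFAULT,
    comet_model,
    emg_comet,
    erf_edge,
    erfc_edge,
    step_peak,
)

__all__ = [
    "TipModel",
    "CometModel",
    "Tog2Model",
    "ProfileFitResults",
    "fit_tip_erf",
    "fit_comet_emg",
    "fit_tog2_step_peak",
    "peak_to_lattice_ratio",
    "align_and_average",
    "fit_comet_amplitude_series",
    "AmplitudeSeries",
]


class ProfileFitResults:
    """Fit results for one intensity profile.

    Attributes
    ----------
    params : dict
        Fitted parameter values, keyed by the model's parameter names.
    bse : dict
        Asymptotic standard errors (NaN when the covariance is singular).
    rss : float
        Residual sum of squares at the optimum.
    flags : list of str
        Quality flags; an empty list means the fit is accepted.
    """

    def __init__(self, model, params, rss, flags, nfev):
        self.model = model
        self.params = dict(params)
        self.rss = float(rss)
        self.flags = list(flags)
        self.nfev = int(nfev)
        self._bse = None
        for k, v in self.params.items():
            setattr(self, k.lower(), v)

    @property
    def accepted(self) -> bool:
        return not self.flags

    @property
    def dof(self) -> int:
        return len(self.model.x) - len(self.params)

    @property
    def bse(self) -> dict:
        if self._bse is None:
            self._bse = self.model._standard_errors(self.params, self.rss)
        return self._bse

    def predict(self, x=None) -> np.ndarray:
        x = self.model.x if x is None else np.asarray(x, dtype=float)
        return self.model.evaluate(x, self.params)

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} fit",
            f"  n pixels: {len(self.model.x)}   rss: {self.rss:.4g}   "
            f"flags: {', '.join(self.flags) if self.flags else 'none'}",
            f"  {'param':>10s} {'value':>12s} {'std err':>12s}",
        ]
        for name in self.params:
            se = self.bse.get(name, np.nan)
            lines.append(f"  {name:>10s} {self.params[name]:>12.4g} {se:>12.3g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.x, self.model.y, ".", label="data", ms=4)
        xs = np.linspace(self.model.x[0], self.model.x[-1], 400)
        ax.plot(xs, self.predict(xs), "-", label="fit")
        ax.set_xlabel("x (nm)")
        ax.set_ylabel("intensity (a.u.)")
        ax.legend()
        return ax

    def __repr__(self):
        pars = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"<{type(self).__name__} {pars}, rss={self.rss:.4g}>"


class _VarProModel:
    """Shared machinery: variable-projection fit with multi-start."""

    #: names of the nonlinear parameters, in optimizer order
    nonlinear_names: tuple = ()
    #: names of the linear amplitudes, in design-matrix column order
    linear_names: tuple = ()
    #: nonlinear parameters whose lower bound is a physical constraint
    #: (pinning there is acceptable, not a failed fit)
    physical_lower_bounds: tuple = ("sigma",)

    def __init__(self, profile: IntensityProfile, window=None):
        if window is not None:
            center, halfwidth = window
            profile = profile.window(center, halfwidth)
        if len(profile) < len(self.nonlinear_names) + len(self.linear_names) + 1:
            raise ValueError("profile too short for this model")
        self.profile = profile
        self.x = profile.x
        self.y = profile.intensity
        self.pixel_size = profile.pixel_size

    # -- per-model hooks ---------------------------------------------------
    def design(self, theta) -> np.ndarray:
        raise NotImplementedError

    def bounds(self):
        raise NotImplementedError

    def initializations(self, init):
        raise NotImplementedError

    def evaluate(self, x, params) -> np.ndarray:
        raise NotImplementedError

    def _quality_flags(self, params, theta_opt) -> list:
        return []

    # -- fitting -----------------------------------------------------------
    def _solve_linear(self, theta):
        A = self.design(theta)
        coef, *_ = np.linalg.lstsq(A, self.y, rcond=None)
        return A, coef

    def _residual(self, theta):
        A, coef = self._solve_linear(theta)
        return self.y - A @ coef

    def fit(self, init=None, n_starts=3) -> ProfileFitResults:
        lo, hi = self.bounds()
        best = None
        flags_conv = []
        starts = self.initializations(init)[: max(1, n_starts)]
        for theta0 in starts:
            theta0 = np.clip(theta0, lo, hi)
            try:
                sol = least_squares(self._residual, theta0, bounds=(lo, hi),
                                    method="trf", xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            rss = 2.0 * sol.cost
            if best is None or rss < best[0]:
                best = (rss, sol)
        if best is None:
            raise RuntimeError("all fit starts failed")
        rss, sol = best
        if not sol.success:
            flags_conv.append("no_convergence")
        theta = sol.x
        _, coef = self._solve_linear(theta)
        params = dict(zip(self.linear_names, coef))
        params.update(zip(self.nonlinear_names, theta))
        params = {k: float(params[k]) for k in self.param_order()}
        flags = flags_conv + self._quality_flags(params, theta)
        # nonlinear parameter pinned at a bound; landing on a *physical*
        # lower bound (sigma at the PSF floor) is a legitimate outcome and
        # is not flagged
        atol = 1e-6 * np.maximum(1.0, np.abs(hi - lo))
        pinned_lo = np.abs(theta - lo) < atol
        pinned_hi = np.abs(theta - hi) < atol
        for name, plo, phi in zip(self.nonlinear_names, pinned_lo, pinned_hi):
            if phi or (plo and name not in self.physical_lower_bounds):
                flags.append(f"{name}_at_bound")
        return ProfileFitResults(self, params, rss, flags, sol.nfev)

    def param_order(self):
        return tuple(self.linear_names) + tuple(self.nonlinear_names)

    def _standard_errors(self, params, rss):
        names = list(params)
        p0 = np.array([params[k] for k in names], dtype=float)
        n, p = len(self.x), len(p0)
        if n <= p:
            return {k: np.nan for k in names}
        J = np.empty((n, p))
        for j, name in enumerate(names):
            h = 1e-6 * max(1.0, abs(p0[j]))
            up, dn = dict(params), dict(params)
            up[name] = p0[j] + h
            dn[name] = p0[j] - h
            J[:, j] = (self.evaluate(self.x, up) - self.evaluate(self.x, dn)) / (2 * h)
        s2 = rss / (n - p)
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
        return dict(zip(names, se))

    # shared initialization helpers
    def _edge_guess(self, direction="falling"):
        """Pixel index of the steepest gradient in the expected direction."""
        grad = np.gradient(self.y, self.x)
        idx = int(np.argmin(grad)) if direction == "falling" else int(np.argmax(grad))
        return float(self.x[idx])

    def _bg_guess(self, side="auto"):
        k = max(3, len(self.y) // 10)
        tail_lo, tail_hi = np.mean(self.y[:k]), np.mean(self.y[-k:])
        return min(tail_lo, tail_hi)


class TipModel(_VarProModel):
    """Error-function tip model: I(x) = I_BG + (I_AMP/2)(1 +/- erf(.)).

    ``direction='falling'`` (lattice at lower x, the erfc form) or
    ``'rising'`` (lattice at higher x).  Nonlinear parameters: the tip
    position ``x_c`` and the apparent tip width ``sigma``, which mixes true
    tip tapering with the PSF — hence the default lower bound at the PSF
    standard deviation (the apparent width can never be narrower than the
    PSF itself).
    """

    nonlinear_names = ("x_c", "sigma")
    linear_names = ("I_BG", "I_AMP")

    def __init__(self, profile, direction="falling", window=None, sigma0=122.0,
                 sigma_bounds=(SIGMA_PSF_DEFAULT, 1500.0)):
        if direction not in ("falling", "rising"):
            raise ValueError("direction must be 'falling' or 'rising'")
        super().__init__(profile, window)
        self.direction = direction
        self.sigma0 = float(sigma0)
        self.sigma_bounds = tuple(sigma_bounds)

    def design(self, theta):
        x_c, sigma = theta
        fn = erfc_edge if self.direction == "falling" else erf_edge
        edge = fn(self.x, 0.0, 1.0, x_c, sigma)
        return np.column_stack([np.ones_like(self.x), edge])

    def evaluate(self, x, params):
        fn = erfc_edge if self.direction == "falling" else erf_edge
        return fn(x, params["I_BG"], params["I_AMP"], params["x_c"], params["sigma"])

    def bounds(self):
        span = self.x[-1] - self.x[0]
        lo = np.array([self.x[0] - span, self.sigma_bounds[0]])
        hi = np.array([self.x[-1] + span, self.sigma_bounds[1]])
        return lo, hi

    def initializations(self, init):
        if init is not None:
            return [np.array([init["x_c"], init.get("sigma", self.sigma0)])]
        xc0 = self._edge_guess(self.direction)
        px = self.pixel_size
        return [np.array([xc0 + d, self.sigma0]) for d in (0.0, -2 * px, 2 * px)]

    def _quality_flags(self, params, theta):
        flags = []
        if params["I_AMP"] <= 0:
            flags.append("negative_amplitude")
        return flags


class CometModel(_VarProModel):
    """EB-comet model: erfc lattice edge + exponentially modified Gaussian.

    ``x_c`` is the position of the maximum of the underlying molecule
    density (the start of the exponential decay); ``decay_length`` is the
    comet decay length in nm.  In this model sigma represents the PSF
    standard deviation; when the instrument's PSF width is known, pass
    ``fix_sigma`` to pin it — x_c and the decay length then become
    markedly better conditioned.
    """

    linear_names = ("I_BG", "I_lattice", "I_EB")

    def __init__(self, profile, window=None, sigma0=122.0, decay0=300.0,
                 sigma_bounds=(SIGMA_PSF_DEFAULT, 1500.0), fix_sigma=None):
        self.fix_sigma = None if fix_sigma is None else float(fix_sigma)
        self.nonlinear_names = ("x_c", "decay_length") if self.fix_sigma \
            else ("x_c", "sigma", "decay_length")
        super().__init__(profile, window)
        self.sigma0 = float(sigma0)
        self.decay0 = float(decay0)
        self.sigma_bounds = tuple(sigma_bounds)

    def _unpack(self, theta):
        if self.fix_sigma is not None:
            x_c, lam = theta
            return x_c, self.fix_sigma, lam
        return tuple(theta)

    def design(self, theta):
        x_c, sigma, lam = self._unpack(theta)
        edge = erfc_edge(self.x, 0.0, 1.0, x_c, sigma)
        comet = emg_comet(self.x, 1.0, x_c, sigma, lam)
        return np.column_stack([np.ones_like(self.x), edge, comet])

    def evaluate(self, x, params):
        return comet_model(x, params["I_BG"], params["I_lattice"], params["I_EB"],
                           params["x_c"], params["sigma"], params["decay_length"])

    def bounds(self):
        span = self.x[-1] - self.x[0]
        lam_hi = 10 * max(1000.0, span)
        if self.fix_sigma is not None:
            return (np.array([self.x[0] - span, 5.0]),
                    np.array([self.x[-1] + span, lam_hi]))
        lo = np.array([self.x[0] - span, self.sigma_bounds[0], 5.0])
        hi = np.array([self.x[-1] + span, self.sigma_bounds[1], lam_hi])
        return lo, hi

    def initializations(self, init):
        if init is not None:
            theta = [init["x_c"]]
            if self.fix_sigma is None:
                theta.append(init.get("sigma", self.sigma0))
            theta.append(init.get("decay_length", self.decay0))
            return [np.array(theta)]
        xc0 = float(self.x[int(np.argmax(self.y))])
        px = self.pixel_size
        if self.fix_sigma is not None:
            return [np.array([xc0, lam0]) for lam0 in
                    (self.decay0, self.decay0 / 2, 2 * self.decay0)]
        return [np.array([xc0 + d, self.sigma0, self.decay0])
                for d in (0.0, -2 * px, 2 * px)]

    def fit(self, init=None, n_starts=3):
        res = super().fit(init=init, n_starts=n_starts)
        if self.fix_sigma is not None:
            res.params["sigma"] = self.fix_sigma
            res.sigma = self.fix_sigma
        return res

    def _quality_flags(self, params, theta):
        flags = []
        if params["decay_length"] < self.pixel_size:
            flags.append("lambda_collapsed")
        if params["I_EB"] < 0:
            flags.append("negative_amplitude")
        return flags


class Tog2Model(_VarProModel):
    """Lattice step + point-accumulation peak: erfc edge + fixed-width Gaussian.

    The peak width is pinned to the PSF standard deviation ``sigma_psf``
    (1.5 px = 97.5 nm by default) because the accumulation is modeled as a
    delta function; ``x_peak`` is its offset from the fitted lattice tip
    (negative = behind the tip).  A negative fitted peak amplitude is
    reported clamped with a 'no_peak' flag.
    """

    nonlinear_names = ("x_c", "x_peak", "sigma")
    linear_names = ("I_BG", "I_lattice", "I_peak")

    def __init__(self, profile, sigma_psf=SIGMA_PSF_DEFAULT, window=None, sigma0=122.0,
                 sigma_bounds=(SIGMA_PSF_DEFAULT, 1500.0), peak_offset_bound=650.0):
        if sigma_psf <= 0:
            raise ValueError("sigma_psf must be positive")
        super().__init__(profile, window)
        self.sigma_psf = float(sigma_psf)
        self.sigma0 = float(sigma0)
        self.sigma_bounds = tuple(sigma_bounds)
        self.peak_offset_bound = float(peak_offset_bound)

    def design(self, theta):
        x_c, x_peak, sigma = theta
        edge = erfc_edge(self.x, 0.0, 1.0, x_c, sigma)
        peak = np.exp(-0.5 * ((self.x - x_c - x_peak) / self.sigma_psf) ** 2)
        return np.column_stack([np.ones_like(self.x), edge, peak])

    def evaluate(self, x, params):
        return step_peak(x, params["I_BG"], params["I_lattice"], params["I_peak"],
                         params["x_c"], params["x_peak"], params["sigma"],
                         self.sigma_psf)

    def bounds(self):
        span = self.x[-1] - self.x[0]
        b = self.peak_offset_bound
        lo = np.array([self.x[0] - span, -b, self.sigma_bounds[0]])
        hi = np.array([self.x[-1] + span, b, self.sigma_bounds[1]])
        return lo, hi

    def initializations(self, init):
        if init is not None:
            return [np.array([init["x_c"], init.get("x_peak", -100.0),
                              init.get("sigma", self.sigma0)])]
        xc0 = self._edge_guess("falling")
        return [np.array([xc0, pk, self.sigma0])
                for pk in (-100.0, 0.0, -250.0)]

    def _quality_flags(self, params, theta):
        flags = []
        if params["I_peak"] < 0:
            params["I_peak"] = 0.0
            flags.append("no_peak")
        return flags


# ---------------------------------------------------------------------------
# functional wrappers


def fit_tip_erf(profile, direction="falling", init=None, window=None, **kw):
    """Fit the error-function tip model; see :class:`TipModel`."""
    return TipModel(profile, direction=direction, window=window, **kw).fit(init=init)


def fit_comet_emg(profile, init=None, window=None, **kw):
    """Fit the erfc + EMG comet model; see :class:`CometModel`."""
    return CometModel(profile, window=window, **kw).fit(init=init)


def fit_tog2_step_peak(profile, sigma_psf=SIGMA_PSF_DEFAULT, init=None, window=None, **kw):
    """Fit the lattice-step + PSF-peak model; see :class:`Tog2Model`."""
    return Tog2Model(profile, sigma_psf=sigma_psf, window=window, **kw).fit(init=init)


def peak_to_lattice_ratio(fit: ProfileFitResults, convention="pixel"):
    """Tip (peak) to lattice intensity ratio for a step+peak fit.

    The point accumulation and the lattice step blur differently under the
    PSF, so raw amplitudes are not comparable; the ratio uses the *area* of
    the peak Gaussian relative to the lattice intensity per pixel:

        ratio = I_peak * sqrt(2*pi) * sigma_PSF / (I_lattice * pixel_size)

    With ``convention='pixel'`` (default) sigma_PSF enters in pixel units,
    which makes the ratio dimensionless and the >1 inclusion filter
    meaningful; ``convention='nm'`` omits the pixel normalization and
    returns a quantity in nm.
    """
    params = fit.params
    if "I_peak" not in params:
        raise ValueError("peak_to_lattice_ratio requires a step+peak fit")
    if params["I_lattice"] <= 0:
        fit.flags.append("undefined_ratio")
        return np.nan
    area = params["I_peak"] * np.sqrt(2.0 * np.pi) * fit.model.sigma_psf
    if convention == "pixel":
        return area / (params["I_lattice"] * fit.model.pixel_size)
    if convention == "nm":
        return area / params["I_lattice"]
    raise ValueError("convention must be 'pixel' or 'nm'")


# ---------------------------------------------------------------------------
# batched erf fitting (vectorized Levenberg-Marquardt)


def fit_erf_batch(X, Y, direction="falling", sigma0=122.0, sigma_bounds=(10.0, 1000.0),
                  max_iter=80, tol=1e-10):
    """Fit the erf tip model to many profiles at once.

    Minimizes the same per-profile sum of squared deviations as
    :class:`TipModel` but runs a damped Gauss-Newton (Levenberg-Marquardt)
    update for all profiles simultaneously, which is what makes the
    Monte-Carlo taper grid search tractable.  ``X`` and ``Y`` are (n, m)
    arrays (``X`` may be (m,) when shared).

    Returns a dict of arrays: I_BG, I_AMP, x_c, sigma, rss, converged.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be 2D (profiles x pixels)")
    n, m = Y.shape
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = np.broadcast_to(X, (n, m))
    sgn = 1.0 if direction == "falling" else -1.0
    s_lo, s_hi = sigma_bounds

    # data-driven initialization: tails for the amplitudes, smoothed
    # half-crossing of the edge for its position (robust at low SNR)
    k = max(3, m // 10)
    left = Y[:, :k].mean(axis=1)
    right = Y[:, -k:].mean(axis=1)
    bg = np.where(sgn > 0, right, left)
    amp = np.abs(left - right)
    kern = np.ones(min(5, m)) / min(5, m)
    S = np.apply_along_axis(np.convolve, 1, Y, kern, mode="same")
    thr = 0.5 * (left + right)
    # pre-edge side of the threshold (high side for falling, low side for
    # rising); the edge is the last pre-edge pixel scanning left to right
    pre_edge = (sgn * S) >= (sgn * thr)[:, None]
    idx = m - 1 - np.argmax(pre_edge[:, ::-1], axis=1)
    xc = X[np.arange(n), np.clip(idx, 0, m - 1)]
    sig = np.full(n, float(sigma0))

    lam = np.full(n, 1e-3)
    params = np.column_stack([bg, amp, xc, sig])

    def model_and_jac(P):
        b, a, c, s = P[:, 0:1], P[:, 1:2], P[:, 2:3], P[:, 3:4]
        u = sgn * (X - c) / (np.sqrt(2.0) * s)
        from scipy.special import erfc as _erfc
        half_erfc = 0.5 * _erfc(u)
        mvals = b + a * half_erfc
        g = np.exp(-u * u)
        d_c = sgn * a * g / (np.sqrt(2.0 * np.pi) * s)
        d_s = a * u * g / (np.sqrt(np.pi) * s)
        J = np.stack([np.ones_like(mvals), half_erfc, d_c, d_s], axis=2)
        return mvals, J

    mvals, J = model_and_jac(params)
    r = Y - mvals
    sse = np.einsum("nm,nm->n", r, r)
    active = np.ones(n, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        JtJ = np.einsum("nmp,nmq->npq", J, J)
        Jtr = np.einsum("nmp,nm->np", J, r)
        diag = np.maximum(np.einsum("npp->np", JtJ), 1e-12)
        A = JtJ.copy()
        ii = np.arange(4)
        A[:, ii, ii] += lam[:, None] * diag
        try:
            step = np.linalg.solve(A, Jtr[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(Ai, bi, rcond=None)[0]
                             for Ai, bi in zip(A, Jtr)])
        trial = params + np.where(active[:, None], step, 0.0)
        trial[:, 3] = np.clip(trial[:, 3], s_lo, s_hi)
        m_t, J_t = model_and_jac(trial)
        r_t = Y - m_t
        sse_t = np.einsum("nm,nm->n", r_t, r_t)
        better = (sse_t < sse) & active
        rel = np.max(np.abs(trial - params), axis=1) / np.maximum(1.0, np.max(np.abs(params), axis=1))
        params[better] = trial[better]
        mvals[better] = m_t[better]
        J[better] = J_t[better]
        sse[better] = sse_t[better]
        r = Y - mvals
        lam = np.clip(np.where(better, lam / 3.0, lam * 4.0), 1e-12, 1e8)
        active = active & ~(better & (rel < tol)) & (lam < 1e7)

    return {
        "I_BG": params[:, 0],
        "I_AMP": params[:, 1],
        "x_c": params[:, 2],
        "sigma": params[:, 3],
        "rss": sse,
        "converged": ~active,
    }


# ---------------------------------------------------------------------------
# alignment / normalization / two-level averaging


def _average_on_grid(shifted_x, values, step):
    """Average curves (each on its own x array) on the common k*step grid.

    Only the overlap region shared by *all* curves is used; no extrapolation
    is ever performed.  Returns (grid, stacked interpolated values).
    """
    lo = max(xs[0] for xs in shifted_x)
    hi = min(xs[-1] for xs in shifted_x)
    k_lo = int(np.ceil(lo / step - 1e-9))
    k_hi = int(np.floor(hi / step + 1e-9))
    if k_hi < k_lo + 1:
        raise ValueError("profiles share no overlap region on the grid")
    grid = np.arange(k_lo, k_hi + 1) * step
    stack = np.vstack([np.interp(grid, xs, ys) for xs, ys in zip(shifted_x, values)])
    return grid, stack


def align_and_average(
    profiles,
    fits,
    normalize_by="I_AMP",
    shift_by=None,
    kymo_ids=None,
    grid_step=32.5,
) -> AveragedProfile:
    """Tip-align, normalize and average profiles on the half-pixel grid.

    Each accepted profile is shifted by its own fitted tip position (or by a
    partner channel's position passed in ``shift_by``), background-subtracted
    with its fitted I_BG, normalized by ``normalize_by`` ('I_AMP',
    'I_lattice' or 'max' of the background-subtracted profile), linearly
    interpolated on the ``grid_step`` grid over the common overlap, and
    averaged in two levels: mean per kymograph, then mean +/- SEM across
    kymographs.  Without ``kymo_ids`` every profile counts as its own
    kymograph.
    """
    profiles = list(profiles)
    fits = list(fits)
    if len(profiles) != len(fits):
        raise ValueError("profiles and fits must pair up")
    if shift_by is not None and len(shift_by) != len(profiles):
        raise ValueError("shift_by must give one position per profile")
    if kymo_ids is None:
        kymo_ids = list(range(len(profiles)))

    shifted, values, groups = [], [], []
    for i, (prof, fit) in enumerate(zip(profiles, fits)):
        if not fit.accepted:
            continue
        shift = fit.params["x_c"] if shift_by is None else float(shift_by[i])
        y = prof.intensity - fit.params["I_BG"]
        if normalize_by == "max":
            norm = float(np.max(y))
        else:
            if normalize_by not in fit.params:
                raise ValueError(f"fit has no parameter {normalize_by!r}")
            norm = fit.params[normalize_by]
        if not norm > 0:
            fit.flags.append("bad_normalization")
            continue
        shifted.append(prof.x - shift)
        values.append(y / norm)
        groups.append(kymo_ids[i])
    if not shifted:
        raise ValueError("no accepted fits to average")

    grid, stack = _average_on_grid(shifted, values, grid_step)
    groups = np.asarray(groups)
    kymo_means = np.vstack([stack[groups == g].mean(axis=0) for g in np.unique(groups)])
    n_k = kymo_means.shape[0]
    mean = kymo_means.mean(axis=0)
    sem = kymo_means.std(axis=0, ddof=1) / np.sqrt(n_k) if n_k > 1 else np.zeros_like(mean)
    return AveragedProfile(grid, mean, sem, n_profiles=len(shifted),
                           n_kymographs=n_k, grid_step=grid_step)


# ---------------------------------------------------------------------------
# per-timepoint comet amplitude series


class AmplitudeSeries:
    """Per-timepoint Gaussian comet amplitudes along a kymograph.

    Attributes: t (s), I_A (a.u.), x_c (nm), sigma (nm), normalized
    (I_A divided by the reference amplitude), flags (list per timepoint).
    """

    def __init__(self, t, i_a, x_c, sigma, normalized, flags):
        self.t = np.asarray(t, dtype=float)
        self.I_A = np.asarray(i_a, dtype=float)
        self.x_c = np.asarray(x_c, dtype=float)
        self.sigma = np.asarray(sigma, dtype=float)
        self.normalized = np.asarray(normalized, dtype=float)
        self.flags = flags

    def __len__(self):
        return len(self.t)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t_s": self.t, "I_A": self.I_A, "x_c_nm": self.x_c,
            "sigma_nm": self.sigma, "normalized": self.normalized,
            "flag": ["|".join(f) for f in self.flags],
        })


def _fit_gaussian_row(x, y, x0, sigma0):
    def resid(theta):
        xc, s = theta
        A = np.column_stack([np.ones_like(x), np.exp(-0.5 * ((x - xc) / s) ** 2)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return y - A @ coef

    sol = least_squares(resid, [x0, sigma0],
                        bounds=([x[0], 1.0], [x[-1], x[-1] - x[0]]), method="trf")
    xc, s = sol.x
    A = np.column_stack([np.ones_like(x), np.exp(-0.5 * ((x - xc) / s) ** 2)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid_sd = float(np.std(y - A @ coef))
    return coef[0], coef[1], xc, s, resid_sd


def fit_comet_amplitude_series(
    kymograph,
    pixel_size,
    dt,
    roi_halfwidth_px=3,
    reference="first",
    split_frame=None,
    track=None,
    fit_halfwidth_px=10,
):
    """Fit a Gaussian + background to the comet in every kymograph row.

    ``kymograph`` is a 2D array with rows = time (increasing downward) and
    columns = position.  The comet is tracked from row to row (previous
    fitted center, or ``track`` positions in nm when given) and each row is
    fitted within ``fit_halfwidth_px`` pixels of the predicted position; the
    comet is required to stay within ``roi_halfwidth_px`` of the prediction,
    otherwise the timepoint is flagged.

    ``reference='first'`` normalizes amplitudes to the first timepoint;
    ``reference='pre_split'`` normalizes to the mean amplitude of the frames
    before ``split_frame``.
    """
    K = np.asarray(kymograph, dtype=float)
    if K.ndim != 2:
        raise ValueError("kymograph must be a 2D array (time, position)")
    if reference not in ("first", "pre_split"):
        raise ValueError("reference must be 'first' or 'pre_split'")
    if reference == "pre_split" and not split_frame:
        raise ValueError("reference='pre_split' requires split_frame")
    nt, nx = K.shape
    x = np.arange(nx) * pixel_size
    t = np.arange(nt) * dt

    i_a = np.empty(nt)
    x_c = np.empty(nt)
    sig = np.empty(nt)
    flags = []
    pred = None
    for i in range(nt):
        row = K[i]
        if track is not None:
            pred = float(track[i])
        elif pred is None:
            pred = float(x[int(np.argmax(row))])
        m = np.abs(x - pred) <= fit_halfwidth_px * pixel_size
        bg, amp, xc, s, resid_sd = _fit_gaussian_row(x[m], row[m], pred, 2 * pixel_size)
        row_flags = []
        if s < pixel_size:
            row_flags.append("sigma_below_pixel")
        if amp < 2.0 * resid_sd:
            row_flags.append("low_amplitude")
        if abs(xc - pred) > roi_halfwidth_px * pixel_size and track is None and i > 0:
            row_flags.append("left_roi")
        else:
            pred = xc
        i_a[i], x_c[i], sig[i] = amp, xc, s
        flags.append(row_flags)

    if reference == "first":
        ref_val = i_a[0]
    else:
        ref_val = float(np.mean(i_a[:split_frame]))
    if not ref_val > 0:
        raise ValueError("reference amplitude must be positive")
    return AmplitudeSeries(t, i_a, x_c, sig, i_a / ref_val, flags)
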