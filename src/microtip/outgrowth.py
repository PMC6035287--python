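"""Seed-templated microtubule outgrowth: simulation and Hill-sigmoid fitting.

The probability that a stabilized seed nucleates a microtubule within the
imaging window rises sigmoidally with tubulin concentration.  The package
adopts the Hill form with zero floor,

    p(c) = p_max * c^h / (c50^h + c^h),

whose parameters are the half-maximal concentration c50 (uM) and the Hill
slope h, matching the parameter pair quoted with such fits.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .containers import OutgrowthTable

__all__ = ["hill", "simulate_outgrowth", "OutgrowthModel", "OutgrowthResults",
           "fit_outgrowth_sigmoid"]


def hill(c, p_max, c50, h):
    """Hill sigmoid p(c) = p_max * c^h / (c50^h + c^h)."""
    c = np.asarray(c, dtype=float)
    r = np.zeros_like(c)
    pos = c > 0
    # evaluate via the ratio (c/c50)^h for numerical range safety
    q = (c[pos] / c50) ** h
    r[pos] = p_max * q / (1.0 + q)
    return r


def simulate_outgrowth(c50, h, p_max, concentrations, n_seeds, seed=None) -> OutgrowthTable:
    """Bernoulli outgrowth per seed: counts ~ Binomial(n_seeds, p(c))."""
    if c50 <= 0 or h <= 0:
        raise ValueError("c50 and h must be positive")
    if not 0 < p_max <= 1:
        raise ValueError("p_max must be in (0, 1]")
    rng = np.random.default_rng(seed)
    concentrations = np.asarray(concentrations, dtype=float)
    n_seeds = np.asarray(n_seeds, dtype=int)
    p = hill(concentrations, p_max, c50, h)
    return OutgrowthTable(concentrations, n_seeds, rng.binomial(n_seeds, p))


class OutgrowthResults:
    """Fitted Hill parameters with asymptotic standard errors."""

    param_names = ("p_max", "c50", "h")

    def __init__(self, model, p_max, c50, h, cov, rss, flags):
        self.model = model
        self.p_max = float(p_max)
        self.c50 = float(c50)
        self.h = float(h)
        self.cov = cov
        self.rss = float(rss)
        self.flags = list(flags)

    @property
    def params(self):
        return {"p_max": self.p_max, "c50": self.c50, "h": self.h}

    @property
    def bse(self):
        if self.cov is None:
            return {k: np.nan for k in self.param_names}
        se = np.sqrt(np.maximum(np.diag(self.cov), 0.0))
        return dict(zip(self.param_names, se))

    def predict(self, c=None):
        c = self.model.table.concentrations if c is None else c
        return hill(c, self.p_max, self.c50, self.h)

    def summary(self) -> str:
        bse = self.bse
        return "\n".join([
            "Hill sigmoid outgrowth fit",
            f"  concentrations: {len(self.model.table)}   "
            f"total seeds: {int(self.model.table.n_seeds.sum())}",
            f"  c50   = {self.c50:.3f} +/- {bse['c50']:.3f} uM",
            f"  h     = {self.h:.3f} +/- {bse['h']:.3f}",
            f"  p_max = {self.p_max:.3f} +/- {bse['p_max']:.3f}",
            f"  rss = {self.rss:.4g}   flags: {', '.join(self.flags) or 'none'}",
        ])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.table
        ax.plot(t.concentrations, t.fractions, "o", label="data")
        cs = np.linspace(0, t.concentrations.max() * 1.1, 200)
        ax.plot(cs, self.predict(cs), "-", label="Hill fit")
        ax.set_xlabel("tubulin (uM)")
        ax.set_ylabel("fraction of seeds with outgrowth")
        ax.legend()
        return ax


class OutgrowthModel:
    """Hill fit of outgrowth fractions versus tubulin concentration.

    Estimation methods:

    ``'ols'``
        Plain least squares on the per-concentration fractions.
    ``'wls'`` (default)
        Least squares weighted by the binomial variance of each fraction
        evaluated at the fitted curve — the natural weighting when each
        point averages a different number of seeds.
    ``'mle'``
        Binomial maximum likelihood on the raw counts (equivalently,
        iteratively reweighted least squares).  The most efficient choice
        when per-seed outcomes really are Bernoulli.

    ``fix_p_max`` pins the plateau (e.g. at 1.0 when the assay saturates —
    every seed nucleates at high tubulin); otherwise p_max is fitted,
    bounded at 1.  At least four concentrations are required, and all-zero
    or all-one data are rejected as non-identifiable.
    """

    def __init__(self, table: OutgrowthTable, method="wls", fix_p_max=None):
        if len(table) < 4:
            raise ValueError("need at least 4 concentrations")
        if method not in ("ols", "wls", "mle"):
            raise ValueError("method must be 'ols', 'wls' or 'mle'")
        f = table.fractions
        if np.all(f == 0.0) or np.all(f == 1.0):
            raise ValueError("outgrowth fractions are degenerate (all 0 or all 1); "
                             "the sigmoid is not identifiable")
        if fix_p_max is not None and not 0 < fix_p_max <= 1:
            raise ValueError("fix_p_max must be in (0, 1]")
        self.table = table
        self.method = method
        self.fix_p_max = fix_p_max

    def _initial(self):
        c, f = self.table.concentrations, self.table.fractions
        p0_max = 1.0 if self.fix_p_max is not None else min(max(f.max(), 0.05), 1.0)
        order = np.argsort(f)
        c50_0 = float(np.interp(0.5 * p0_max, f[order], c[order]))
        c50_0 = min(max(c50_0, c[c > 0].min()), c.max())
        return p0_max, c50_0, 4.0

    def fit(self, init=None) -> OutgrowthResults:
        c = self.table.concentrations
        f = self.table.fractions
        n = self.table.n_seeds.astype(float)
        k = self.table.n_outgrown.astype(float)
        fixed = self.fix_p_max

        def unpack(theta):
            return (fixed, *theta) if fixed is not None else tuple(theta)

        def resid(theta):
            p_max, c50, h = unpack(theta)
            p = hill(c, p_max, c50, h)
            r = p - f
            if self.method == "wls":
                var = np.maximum(p * (1.0 - p), 1e-4) / n
                r = r / np.sqrt(var)
            elif self.method == "mle":
                # signed deviance residuals: sum of squares = binomial deviance
                pc = np.clip(p, 1e-12, 1.0 - 1e-12)
                fc = np.clip(f, 1e-12, 1.0 - 1e-12)
                dev = 2.0 * n * (f * np.log(fc / pc) + (1 - f) * np.log((1 - fc) / (1 - pc)))
                r = np.sign(f - p) * np.sqrt(np.maximum(dev, 0.0))
            return r

        theta0 = self._initial() if init is None else tuple(init)
        if fixed is not None:
            theta0 = theta0[1:]
            lo, hi = [1e-6, 1e-3], [np.inf, np.inf]
        else:
            lo, hi = [1e-6, 1e-6, 1e-3], [1.0, np.inf, np.inf]
        sol = least_squares(resid, np.clip(theta0, lo, 1e6), bounds=(lo, hi),
                            method="trf", xtol=1e-14, ftol=1e-14)
        flags = [] if sol.success else ["no_convergence"]
        p_max, c50, h = unpack(sol.x)
        rss = float(np.sum((hill(c, p_max, c50, h) - f) ** 2))
        n_pts, p_fit = len(c), len(sol.x)
        cov = None
        if n_pts > p_fit:
            J = sol.jac
            s2 = 2.0 * sol.cost / (n_pts - p_fit)
            try:
                cov_fit = s2 * np.linalg.inv(J.T @ J)
                cov = np.full((3, 3), np.nan)
                if fixed is None:
                    cov = cov_fit
                else:
                    cov[1:, 1:] = cov_fit
                    cov[0, 0] = 0.0
            except np.linalg.LinAlgError:
                flags.append("singular_covariance")
        return OutgrowthResults(self, p_max, c50, h, cov=cov, rss=rss, flags=flags)


def fit_outgrowth_sigmoid(table: OutgrowthTable, init=None, method="wls",
                          fix_p_max=None) -> OutgrowthResults:
    """Functional wrapper around :class:`OutgrowthModel`."""
    return OutgrowthModel(table, method=method, fix_p_max=fix_p_max).fit(init=init)
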