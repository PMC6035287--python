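"""Drift–diffusion analysis of tip trajectories via the ensemble MSD.

The mean squared displacement of the length increments of a steadily
growing tip follows

    MSD(tau) = v_g^2 tau^2 + 2 D_p tau + const,

where v_g is the mean growth speed, D_p the polymerization diffusion
coefficient, and the constant absorbs the (frame-independent) localization
error contribution.  The model is linear in (v_g^2, 2 D_p, const), so the
fit is ordinary least squares on the quadratic basis with non-negativity
enforced by clamping (a clamped D_p is flagged).
"""

from __future__ import annotations

import numpy as np

from .containers import Trajectory

__all__ = ["MSDModel", "MSDResults", "ensemble_msd", "fit_msd"]


def ensemble_msd(trajectories, tau_max=None, use_observed=True):
    """Ensemble MSD of length increments over all trajectories and lag pairs.

    Returns (taus, msd, sem, n_pairs): the pooled MSD per lag, its standard
    error estimated from the between-trajectory spread of per-trajectory
    MSDs, and the total number of (overlapping) increment pairs.  All
    trajectories must share the sampling interval.
    """
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("need at least one trajectory")
    dt = trajs[0].dt
    for tr in trajs:
        if abs(tr.dt - dt) > 1e-9:
            raise ValueError("all trajectories must share the sampling interval")
    max_dur = max(tr.times[-1] - tr.times[0] for tr in trajs)
    tau_cap = max_dur if tau_max is None else min(tau_max, max_dur)
    k_max = int(np.floor(tau_cap / dt + 1e-9))
    if k_max < 2:
        raise ValueError("tau range too short for a quadratic fit")
    per = np.full((len(trajs), k_max), np.nan)
    counts = np.zeros(k_max, dtype=int)
    for i, tr in enumerate(trajs):
        L = tr.observed_lengths if use_observed else tr.true_lengths
        n = len(L)
        for k in range(1, min(k_max, n - 1) + 1):
            diff = L[k:] - L[:-k]
            per[i, k - 1] = np.mean(diff * diff)
            counts[k - 1] += len(diff)
    valid = counts > 0
    taus = np.arange(1, k_max + 1)[valid] * dt
    per = per[:, valid]
    with np.errstate(invalid="ignore"):
        msd = np.nanmean(per, axis=0)
        n_tr = np.sum(~np.isnan(per), axis=0)
        sd = np.nanstd(per, axis=0, ddof=1) if len(trajs) > 1 else np.zeros_like(msd)
    sem = np.where(n_tr > 1, sd / np.sqrt(np.maximum(n_tr, 1)), 0.0)
    return taus, msd, sem, counts[valid]


class MSDResults:
    """Fitted drift–diffusion parameters.

    Attributes: v_g (nm/s), D_p (nm^2/s), sigma_err_sq (the fitted constant,
    nm^2), tau (s), msd (nm^2), rss, flags, and optionally per-trajectory
    diffusion coefficients ``D_p_individual``.
    """

    def __init__(self, model, v_g, D_p, sigma_err_sq, tau, msd, rss, flags,
                 D_p_individual=None):
        self.model = model
        self.v_g = float(v_g)
        self.D_p = float(D_p)
        self.sigma_err_sq = float(sigma_err_sq)
        self.tau = tau
        self.msd = msd
        self.rss = float(rss)
        self.flags = list(flags)
        self.D_p_individual = D_p_individual

    def predict(self, tau=None):
        tau = self.tau if tau is None else np.asarray(tau, dtype=float)
        return self.v_g**2 * tau**2 + 2.0 * self.D_p * tau + self.sigma_err_sq

    def summary(self) -> str:
        lines = [
            "Ensemble MSD drift-diffusion fit",
            f"  trajectories: {len(self.model.trajectories)}   "
            f"tau range: {self.tau[0]:.2f}-{self.tau[-1]:.2f} s",
            f"  v_g          = {self.v_g:.3f} nm/s",
            f"  D_p          = {self.D_p:.1f} nm^2/s",
            f"  const offset = {self.sigma_err_sq:.1f} nm^2",
            f"  rss = {self.rss:.4g}   flags: {', '.join(self.flags) or 'none'}",
        ]
        if self.D_p_individual is not None:
            d = np.asarray(self.D_p_individual)
            lines.append(f"  per-trajectory D_p: mean {d.mean():.1f} "
                         f"+/- {d.std(ddof=1)/np.sqrt(len(d)):.1f} (SEM) nm^2/s")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.tau, self.msd, ".", ms=4, label="ensemble MSD")
        ax.plot(self.tau, self.predict(), "-", label="fit")
        ax.set_xlabel("tau (s)")
        ax.set_ylabel("MSD (nm$^2$)")
        ax.legend()
        return ax


class MSDModel:
    """Ensemble drift–diffusion model for a set of tip trajectories.

    ``tau_max_fraction`` caps the fitted lag range at a fraction of the
    longest trajectory duration (default 1/4) to avoid the high-variance
    long-lag tail.
    """

    def __init__(self, trajectories, tau_max_fraction=0.25, use_observed=True):
        self.trajectories = list(trajectories)
        if not self.trajectories:
            raise ValueError("need at least one trajectory")
        if not 0 < tau_max_fraction <= 1:
            raise ValueError("tau_max_fraction must be in (0, 1]")
        self.tau_max_fraction = float(tau_max_fraction)
        self.use_observed = bool(use_observed)
        self.tau_max = tau_max_fraction * max(
            tr.times[-1] - tr.times[0] for tr in self.trajectories
        )

    @staticmethod
    def _quad_fit(tau, msd, sem=None):
        X = np.column_stack([tau**2, tau, np.ones_like(tau)])
        y = msd
        if sem is not None:
            # inverse-variance weighting; the long-lag MSD has few effective
            # samples and would otherwise dominate the quadratic term
            eps = 1e-12 * max(float(np.max(msd)), 1.0)
            if np.all(sem > eps):
                w = 1.0 / sem
                X = X * w[:, None]
                y = msd * w
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        basis = np.column_stack([tau**2, tau, np.ones_like(tau)])
        rss = float(np.sum((msd - basis @ coef) ** 2))
        return coef, rss

    def fit(self, per_trajectory=False, weighted=True) -> MSDResults:
        tau, msd, sem, _ = ensemble_msd(self.trajectories, self.tau_max, self.use_observed)
        coef, rss = self._quad_fit(tau, msd, sem if weighted else None)
        flags = []
        a, b, c = coef
        if a < 0:
            a, flags = 0.0, flags + ["negative_v_sq_clamped"]
        if b < 0:
            b, flags = 0.0, flags + ["negative_D_clamped"]
        v_g = float(np.sqrt(a))
        D_p = float(b / 2.0)
        d_ind = None
        if per_trajectory:
            d_ind = self._per_trajectory_D(v_g)
        return MSDResults(self, v_g, D_p, c, tau, msd, rss, flags, d_ind)

    def _per_trajectory_D(self, v_g_shared):
        """Per-trajectory D_p with the drift speed shared from the ensemble fit."""
        out = []
        for tr in self.trajectories:
            tau, msd, _, _ = ensemble_msd([tr], self.tau_max, self.use_observed)
            y = msd - v_g_shared**2 * tau**2
            X = np.column_stack([2.0 * tau, np.ones_like(tau)])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            out.append(max(coef[0], 0.0))
        return np.asarray(out)


def fit_msd(trajectories, tau_max_fraction=0.25, per_trajectory=False, use_observed=True):
    """Functional wrapper around :class:`MSDModel`."""
    return MSDModel(trajectories, tau_max_fraction, use_observed).fit(per_trajectory)
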