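# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and the limits of what the validation suite shows.

## Coordinate and unit conventions

Axial position and length in nm, time in s, event frequencies in min⁻¹,
tubulin concentration in μM.  Profiles are oriented with the microtubule
lattice at lower *x* and the growing plus end at higher *x*; kymograph rows
are time, increasing downward.  All averaged profiles live on a half-pixel
grid (32.5 nm) of integer multiples, so grids from different runs intersect
exactly.

## Convolved intensity models

A diffraction-limited image of a labeled microtubule end is modeled in 1D
(the ~25 nm lattice width is unresolved; all 13 protofilaments project onto
the axial coordinate).  Three analytic forms cover the fitted signals:

* **Tip edge**: a half-infinite uniform density convolved with a Gaussian
  PSF gives `I_BG + (I_AMP/2)·erfc((x−x_c)/(√2σ))`; σ is the *apparent* tip
  width, mixing the PSF with any real tapering, so its lower fit bound is
  the PSF SD (97.5 nm = 1.5 px) — an apparent width below the PSF is
  unphysical and in practice signals a fit latched onto noise.
* **EB comet**: exponential density (decay length λ) behind the comet
  maximum at x_c, convolved with the PSF — an exponentially modified
  Gaussian.  Evaluated through the scaled complementary error function
  (`erfcx`) the expression is overflow-free for any λ/σ; agreement with
  direct quadrature is ≤1e−6 relative (tested).  In this model σ plays the
  role of the PSF width; when the instrument PSF is known, `fix_sigma`
  pins it, which markedly improves the conditioning of x_c and λ (with σ
  free, the comet-maximum estimate carries a ~−5 nm bias at SNR 7).
* **Lattice step + point peak**: the tip edge plus a Gaussian of fixed
  width σ_PSF at offset x_peak from the tip, for proteins that accumulate
  in a sub-diffraction zone.  The dimensionless peak-to-lattice ratio is
  `I_peak·√(2π)·σ_PSF/(I_lattice·pixel_size)` — the integrated weight of
  the point accumulation relative to the lattice intensity collected per
  pixel; fits with ratio ≤ 1 are treated as peak-free in distance
  statistics.  (The PSF width may also be kept in nm via
  `convention="nm"`; the dimensionless pixel convention is the default
  because it makes the ratio>1 filter meaningful.)

### Fitting

All three models have amplitudes entering linearly and a few nonlinear
shape parameters, so fitting uses variable projection: bounded trust-region
least squares over the nonlinear parameters with the amplitudes solved
exactly by linear least squares at every step.  Multi-start (three
data-driven initializations: steepest gradient / argmax, plus shifted or
alternative peak-offset starts) guards against local minima; ties break by
lowest residual sum of squares.  Standard errors come from the
Gauss–Newton covariance at the optimum.  Fits are never silently dropped:
quality flags (non-convergence, parameter at a bound, negative amplitude,
decay length below one pixel, no peak) mark a fit as rejected, and
averaging consumes only accepted fits.

A vectorized Levenberg–Marquardt version of the edge fit processes
thousands of profiles simultaneously on a shared objective; it agrees with
the single-profile path to machine precision (tested) and is what makes
the exhaustive taper search affordable.

## Synthetic data generators

The generators define the validation conditions; defaults reproduce the
imaging they emulate.

* **Drift–diffusion trajectories**: length increments per frame
  `v_g·dt + √(2·D_p·dt)·ξ`; observed lengths add independent N(0, σ_err²)
  per frame, so increments between two observed frames carry 2σ_err².
  Defaults: dt = 0.7 s, 300 s (429 samples).
* **Telegraph (dynamic instability) trajectories**: exponential growth and
  shrink phase durations with rates f_cat, f_res (min⁻¹); shrinkage
  reflects at the stable-seed length without counting as a rescue.
* **Protofilament lattices**: 13 protofilaments, 8 nm dimer spacing.
  Model A erodes N protofilaments by a fixed d; Model B draws the N
  missing lengths i.i.d. exponential with mean d, truncated at the lattice
  length (no renormalization — the truncated mass is negligible for
  d ≪ lattice length) and rounded to whole dimers.
* **Rendering**: present dimers are labeled with Bernoulli probability
  0.09; each labeled dimer deposits a unit-mass Gaussian (σ = 122 nm)
  integrated across 65 nm pixels via CDF differences (not center
  sampling).  Additive Gaussian noise is scaled so the *total* plateau
  fluctuation — Bernoulli labeling shot noise (computed analytically from
  the pixel weight matrix) plus the additive term — equals plateau/SNR
  with SNR = 7, matching the signal-to-noise ratio measured on real
  profiles, which includes labeling stochasticity.
* **Seed outgrowth**: per-seed Bernoulli with Hill probability
  `p_max·c^h/(c50^h + c^h)`.

`render_profile` renders an isolated lattice (both ends visible inside the
field).  The Monte-Carlo taper engine instead emulates line profiles cut
from a kymograph along a long microtubule: the lattice continues past the
left field edge, each profile is trimmed to a 2.5 μm span centered on a
marked approximate tip, and only one edge is present — the geometry of the
experimental profiles.  Tip marking emulates manual annotation: the
profile is smoothed over 5 pixels and the mark placed at the last crossing
of the plateau/background midpoint, which is robust at SNR 7 where a
gradient criterion is not.

## Taper inference

For each candidate (N, d) the engine renders 50 iterations × n_mt noisy
profiles (lengths resampled with replacement from the supplied list), fits
every profile with the erf edge model, background-subtracts, normalizes by
I_AMP, aligns at the fitted x_c, interpolates to the 32.5 nm grid over the
common support (never extrapolating), averages within iteration and then
across iterations.  The residual against the reference profile is summed
over the common support only, and the grid search is exhaustive.

Two deliberate numerical choices:

* **Common random numbers.**  Every (N, d) cell replays an identical RNG
  stream — labeling uniforms per (protofilament, site), one normal per
  pixel, fixed-count exponential draws — so all cells see the same noise
  fields wherever their lattices agree and the residual surface is smooth:
  cell-to-cell comparisons reflect the hypotheses, not Monte-Carlo
  jitter.  Different master seeds remain independent replicates, and the
  per-cell residual is independent of which other cells are evaluated
  (order invariance is tested).
* **SEM-weighted residual (optional).**  Aligning each profile at its own
  fitted x_c makes the family of averaged model curves nearly collapse in
  the mid-edge region (the alignment compensates shape changes), while
  the surviving differences sit in the shoulder and toe.  The reference's
  per-point SEM is largest exactly in the mid-edge (alignment jitter), so
  an inverse-variance-weighted residual — SEM floored at a fifth of its
  median — substantially sharpens the (N, d) optimum.  Both statistics are
  available; see `profile_residual(weight_by_ref_sem=...)`.

Identifiability caveat: N = 13 (all protofilaments eroded equally) is a
blunt tip shifted by d, which tip alignment removes entirely — its
residual row is flat in d by construction.  Nearby high-N cells are
near-degenerate for the same reason, and a single 17-profile reference
leaves the optimum scattered by about one grid step along a curved (N, d)
valley; the Monte-Carlo repeats in `select_taper_model` quantify exactly
this.  Model selection repeats the whole search (default 3×), compares
mean minimal residuals, and breaks ties toward Model A (the structurally
simpler hypothesis) with an explicit tie flag.

## Growth variability (MSD)

The ensemble MSD of length increments uses all overlapping pairs at each
lag; the quadratic model `v_g²τ² + 2·D_pτ + const` is linear in
(v_g², 2D_p, const) and fitted by weighted linear least squares with
inverse-variance weights from the between-trajectory spread at each lag
(the long-lag MSD has few effective samples and enormous variance; the
unweighted fit is unbiased but an order of magnitude less precise —
weighting is essential for a usable D_p).  Lags are capped at 25% of the
trajectory duration by default.  Negative fitted v_g² or D_p are clamped
to zero and flagged.  The constant term absorbs the localization-error
offset (2σ_err² for increments between two noisy frames) and is reported
as fitted.  Per-trajectory D_p values (for distributions across events)
share the ensemble drift speed.

## Event statistics

Piecewise-linear segmentation minimizes SSD + penalty·(#segments) exactly
by dynamic programming (O(1) per-segment OLS cost from prefix sums,
minimum segment length 5 samples), then refits a *continuous*
piecewise-linear function on the hinge basis at the selected breakpoints;
slopes come from the continuous refit.  The default penalty is BIC-style,
3·σ̂²·log n, with σ̂ from the median absolute second difference.
Classification: growth if slope ≥ 8.3 nm/s (0.5 μm/min), shrinkage if
≤ −8.3 nm/s, pause otherwise — explicit, configurable thresholds, not a
claim about any particular annotation tool.  Catastrophe = growth/pause →
shrinkage; rescue = shrinkage → growth/pause.  Tip-repair events need a
paired lagging-comet track and are supplied as (split, merge) intervals.

Frequencies: f = N_events/observation time with SE = f/√N for catastrophes
and repair events; rescues use the ratio SE f̄_r·SE(t_sh)/t̄_sh, switching
to the Poisson rule SE = f̄_r/√N_r when N_r ≤ 10.  Zero counts report 0
with a low-information flag; zero observation time reports NaN flagged.

## Outgrowth fit

Hill form with zero floor, parameterized by (p_max, c50, h).  Three
estimation methods: plain least squares on fractions, least squares
weighted by the binomial variance at the fitted curve (default), and
binomial maximum likelihood on the counts (via signed deviance residuals —
iteratively reweighted least squares).  The plateau may be pinned
(`fix_p_max=1` when the assay saturates); with the plateau free and data
near saturation the slope estimate is noticeably biased upward, which is
why the recovery experiments pin it.

## Recovery experiments

`microtip.recovery` packages seeded end-to-end experiments that use
published analysis results as simulation ground truth (drift–diffusion
D_p = 316 and 506 nm²/s; Hill c50/h = 7.28/5.99 and 1.28/3.16 with the
published per-concentration seed counts; TOG2 peak offsets 92.9 nm behind
the tubulin tip and 59.9 nm behind the EB comet maximum; taper Model A
with N = 10, d = 250 nm).  Free design choices made once: 8 tubulin
concentrations at 1, 2, 3.5, 5, 6.5, 8, 10, 12 μM; profile amplitudes for
the two-channel peak-offset experiments in the bright-accumulation regime
(background 5, lattice 40, peak 200 and a tapered edge σ = 180 nm for the
TOG2 channel; lattice 100 for tubulin; lattice 40, comet 120 for the EB
channel, fitted with σ pinned at the known PSF width); trajectory drift
25 nm/s with 20 nm frame noise; 17 reference profiles with lattice
lengths uniform in 2–3 μm, with the taper reference averaging 50
iterations of that condition to mirror the search side.  The peak-offset
distances are measured against the partner channel's fitted position
(tubulin tip or comet maximum) because that is how such distances are
defined in two-color imaging; the TOG2 profile's own edge position is far
noisier than its peak position and would dominate the error budget.
Nonlinear least squares carries small O(1–2 nm) second-order biases in
the peak-offset estimates (noise coupling between the peak and the edge
components); the bright-accumulation designs keep them near the
Monte-Carlo resolution of the recovery experiments.

## What passing tests do and do not show

The generators share the analytic PSF/noise model with the fitted
functions, so parameter-recovery tests validate the estimation machinery,
not the optical model itself.  Real data add camera EM-gain noise,
photobleaching, drift, chromatic offsets and background structure that are
deliberately out of scope here; flags and configurable thresholds are the
hooks for handling them.  The segmentation penalty and the phase-speed
thresholds are conventions, and event frequencies inherit them.  Problem
sizes in the test suite (hundreds of replicates, reduced grids) are chosen
to keep the default run fast while leaving Monte-Carlo standard errors
well below the asserted tolerances.
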