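# microtip

Quantitative analysis of growing **microtubule plus ends** from TIRF
microscopy, for researchers studying microtubule dynamics and +TIP proteins:
sub-pixel tip localization by fitting PSF-convolved intensity models to
kymograph line profiles, Monte-Carlo inference of protofilament tip-taper
structure, drift–diffusion analysis of growth variability, event-frequency
statistics with their standard errors, Hill-sigmoid fits of seed-templated
nucleation, and single-molecule intensity counting.  A synthetic-data layer
generates trajectories, protofilament lattices and noisy rendered profiles
with the statistical structure of the real data, so every estimator can be
validated against known ground truth.

## Models

With the lattice at lower *x* and the growing tip at *x<sub>c</sub>*, the
fitted intensity models are:

* **Tip edge** — `I(x) = I_BG + (I_AMP/2)·erfc((x−x_c)/(√2 σ))`, where σ
  mixes true tip tapering with the point-spread function (PSF).
* **EB comet** — the edge plus an exponential density (decay length λ)
  convolved with the PSF, an exponentially modified Gaussian:
  `(I_EB/2)·exp(σ²/2λ² + (x−x_c)/λ)·erfc(((x−x_c) + σ²/λ)/(√2 σ))`.
* **Point accumulation** (e.g. a tip-tracking protein) — the edge plus a
  Gaussian peak of fixed width σ_PSF (1.5 px = 97.5 nm) at offset x_peak
  from the tip; the dimensionless peak-to-lattice ratio
  `I_peak·√(2π)·σ_PSF/(I_lattice·pixel)` compares the peak's integrated
  weight to the lattice intensity per pixel.

Tip structure is inferred by simulating 13-protofilament lattices (8 nm
dimer spacing, Bernoulli labeling at 0.09, Gaussian PSF σ = 122 nm, 65 nm
pixels, signal-to-noise ratio 7) under two erosion hypotheses — N
protofilaments shortened by a uniform length *d* (Model A, sharp) or by
exponentially distributed lengths with mean *d* (Model B, gradual) —
pushing the renders through the same fit/normalize/align/average pipeline
as the data, and exhaustively searching (N, d) for the minimal sum of
squared differences.

Growth variability is summarized by the ensemble mean squared displacement
of tip-length increments, `MSD(τ) = v_g²τ² + 2·D_p·τ + const`, yielding the
growth speed v_g and the polymerization diffusion coefficient D_p.
Catastrophe/rescue/repair frequencies carry the field's standard errors,
including the Poisson rule `SE = f̄/√N` for small rescue counts (N ≤ 10).

## Worked example

```python
import numpy as np
from microtip import (RenderParams, TaperModelSpec, TrajectoryParams,
                      MSDModel, simulate_length_trajectory,
                      simulate_averaged_model_profile, TaperModel, TaperGrid)

# growth variability: 40 trajectories at 0.7 s sampling for 5 min
rng = np.random.default_rng(7)
params = TrajectoryParams(v_g=25.0, D_p=316.0, sigma_err=20.0)
trajs = [simulate_length_trajectory(params, rng=rng) for _ in range(40)]
print(MSDModel(trajs).fit().summary())

# taper inference on a simulated 17-profile condition (50-iteration average)
rp = RenderParams()
lengths = rng.uniform(2000.0, 3000.0, 17)
ref = simulate_averaged_model_profile(TaperModelSpec("A", 10, 250.0),
                                      lengths, rp, iterations=50, seed=1,
                                      resample_lengths=False)
grid = TaperGrid(N_values=range(14), d_values=np.arange(50., 751., 50.))
res = TaperModel(ref, model="A", grid=grid, mt_lengths=lengths,
                 render_params=rp).fit(seed=1)
print(res.summary())
```

This prints the ensemble MSD fit,

```
Ensemble MSD drift-diffusion fit
  trajectories: 40   tau range: 0.70-74.90 s
  v_g          = 24.589 nm/s
  D_p          = 340.4 nm^2/s
  const offset = 749.8 nm^2
  rss = 4.562e+09   flags: none
```

— the drift (truth 25 nm/s), the polymerization diffusion coefficient
(truth 316 nm²/s, recovered within its ~±35 sampling error at n = 40) and
the constant absorbing twice the 20 nm frame localization variance
(800 nm²) — followed by the taper grid search result,

```
Taper grid search, Model A
  best N = 10 eroded protofilaments
  best d = 250 nm
  minimal residual = 0.0011587
  grid: 14 N values x 15 d values, 17 MTs emulated per iteration
```

which recovers the generating truth (N = 10, d = 250 nm) exactly.  With a
single-iteration reference (one emulated experiment instead of the
50-iteration average) the optimum scatters along a near-degenerate (N, d)
valley — see the identifiability discussion in `docs/methods.md`.

A `microtip` command-line tool wraps the main workflows
(`simulate`, `fit-profiles`, `taper-fit`, `dynamics`, `outgrowth-fit`,
`count-molecules`, `recover`); see `microtip --help`.

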