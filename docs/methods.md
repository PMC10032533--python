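# Methods

This note records the modeling assumptions, numerical choices and known
limitations of the `magrheo` pipeline.

## Signal model

Tracks are displacements of magnetic spheres relative to the mean of the
reference-sphere positions, re-zeroed at the first frame. The reference
subtraction removes common-mode motion (stage drift, mounting vibration)
exactly for motion shared by all spheres; motion that differs between probe
and reference locations is not removable and ends up in the residual.

Amplitude and phase at the known drive frequency are estimated by linear
least squares in the basis {sin ωt, cos ωt, 1, t}, ω = 2πf. This is the
global optimum of the nonlinear sinusoid fit when the frequency is fixed —
no initialization, no local minima, exact on noiseless data. The drift term
is on by default; with it, estimates are invariant to any affine trend. The
phase convention φ = atan2(−b, a) for y = a·sin + b·cos makes displacement
*lag* positive, so viscoelastic media give φ ∈ [0°, 90°] and a Newtonian
fluid exactly 90°. Residual SD uses n − p degrees of freedom; SNR is
amplitude over residual SD, and QC thresholds (default SNR ≥ 3, R² ≥ 0.5)
partition fits with machine-readable reasons rather than dropping rows.

## Calibration

In a Newtonian fluid the force balance is Stokes drag, F = 3πµDv̂, giving
F_vol = 18µv̂/D². Spheres vary in size, so v̂ = βr² is fitted across
spheres with priors β ~ N(0, 5000) and σ ~ InvGamma(0.5, 1)·10⁻⁸ on the SI
scales of the data (v̂ in m/s, r² in m²); F_vol = (9/2)βµ draw-wise. The
written prior "InverseGamma(0.5, 1)·10⁻⁸" is read as a scaled random
variable: σ = 10⁻⁸·x with x ~ InvGamma(shape 0.5, scale 1). The scale
factor, and a shape/rate alternative for the second parameter, are config
knobs. Bayesian R² is the posterior mean of var(fit)/(var(fit) + σ²) per
draw. Because F_vol is exactly linear in µ, posteriors for different
viscosities are draw-matched scalings under a shared seed — a property the
tests exploit.

## Multilevel heterogeneity model

Observations are z-scored per matrix: y = (raw − mean_m)/SD_shared, where
SD_shared is the sample SD of the pooled per-matrix-centered data. Using
one shared SD keeps heterogeneity scales comparable across matrices; the
constants are stored with the results so the transform is invertible.

The primary model is the three-level non-centered chain given in the
README, with N(0,1) priors on matrix means and latent z's, HalfNormal(0,1)
on all α's and on the noise hyperparameters, and per-sphere noise
σ_t ~ InvGamma(σ^µ, σ^σ_m). σ^µ is shared across matrices (same
instrument, same mean noise level); σ^σ_m is matrix-specific. Repeats are
conditionally i.i.d. given the sphere mean; there is no repeat-level random
effect. The API names every scale by the level it *scatters*
(`sample_within_matrix`, `holder_within_sample`, `sphere_within_holder`) to
avoid superscript ambiguity; `sphere_within_holder` is the heterogeneity
estimate.

Eq-level choices that were genuinely open:

- The noise prior is implemented literally as InvGamma(shape = σ^µ,
  scale = σ^σ_m). Because σ^µ is described as a *mean* noise level, a
  mean-parametrized alternative (mean σ^µ, spread σ^σ_m, shape
  2 + (σ^µ/σ^σ)²) is available behind `noise_parametrization="mean"`.
  Default: the literal reading.
- "Sample-to-sample variation" for the parallel-plate comparison is taken
  as `sample_within_matrix` (the scale that scatters sample means); the
  alternative reading (`holder_within_sample`) is one accessor call away,
  and neither is asserted as canonical.
- Degenerate designs (one holder per sample, one sphere per holder) are
  permitted; the affected scale is then prior-dominated and the fit emits
  an identifiability warning.

### Variants

1. `primary` — the model above.
2. `location_level` — inserts a location tier: holders scatter locations,
   locations scatter spheres. Requires non-degenerate location labels.
3. `single_level` — spheres scatter directly around the matrix mean; its
   single scale absorbs sample and holder variance and therefore
   overestimates heterogeneity on clustered data (a property the tests
   verify).
4. `pooled_baseline` — one mean per matrix, per-sphere pooled noise kept;
   the posterior SD of the mean is its heterogeneity surrogate.
5. `pooled_no_shared_noise` — one mean and one noise SD per matrix.

## Posterior computation

Sampling uses an ensemble MCMC (differential-evolution moves with a 5%
snooker admixture) over the *hyperparameters only*: all Gaussian latent
effects are marginalized in closed form. The nested covariance collapses
level by level — spheres enter their holder as precision-weighted
pseudo-observations, holders their sample, samples the matrix — so one
likelihood evaluation is O(n) with no matrix factorizations. Per-sphere
noise SDs are sampled scale-free relative to σ^σ_m (a non-centered noise
tier), and all positive parameters on the log scale with Jacobians.

Latent level means and their non-centered z representation are recovered
after sampling by backward sampling from their exact Gaussian conditionals
(upward message pass, then top-down simulation). The joint draws are
therefore from the same posterior as sampling the full non-centered model
directly, with the funnel between scales and latents removed — which is
what makes a gradient-free ensemble sampler adequate here. Correctness is
pinned by two oracles in the test suite: the collapsed likelihood against a
dense multivariate-normal evaluation of the full nested covariance, and the
backward-sampled conditionals against a dense precision-matrix solve.

Diagnostics: split R-hat and bulk ESS treat each walker as a chain
(stricter than grouping); fits warn at R-hat ≥ 1.01 and are flagged
unconverged at ≥ 1.05. Divergence counts are a Hamiltonian concept and are
reported as zero; the acceptance fraction is the analogous health check.
Default chain settings (4000 warmup + 4000 kept steps, thin 4) converge for
small posteriors; the dimension grows with one noise parameter per sphere,
and full-design fits (~80 parameters) need roughly 5000+5000 steps with
~160 walkers, which is what the recovery studies use.

## ELPD model comparison

Leave-one-*sphere*-out cross-validation. `method="exact"` (default) refits
the model once per held-out sphere; the held-out log predictive density
integrates the sphere's latent effect analytically (compound-symmetric
Gaussian over its repeats) and its noise SD by Monte Carlo over the
InvGamma posterior-predictive. `method="psis"` reuses one full-data fit
with Pareto-smoothed importance weights per sphere (weights 1/p(y_t | θ)
with the sphere's conditional parent mean drawn jointly); Pareto-k
diagnostics are attached and folds with k > 0.7 flagged. The two paths
agree within their combined standard errors on small data (tested). The
model-comparison studies use the PSIS path for its ~20× speed advantage;
the preference margins involved (tens of ELPD units) dwarf the
approximation error.

## Synthetic data

The generator emulates: sinusoidal displacement at 0.05 Hz with phase lag,
additive i.i.d. Gaussian tracking noise and optional linear drift;
truncated-normal sphere-size dispersion (±3 SD, positive); the nested
design of 3 samples × 2 holders × 3–5 locations × 1–3 spheres × ≥2 repeats;
and the exact generative chain of the heterogeneity model, de-normalized
with per-matrix raw means and one shared raw SD. Defaults: 25 Hz sampling
for 20 s (one full drive period — the minimum identifiable window), 5 nm
tracking noise for calibration tracks, normalized-scale truth
(α: 0.3/0.2/0.8; noise InvGamma(3.0, 0.4), mean per-sphere SD 0.2), raw
means of order 100–250 Pa with a 50 Pa shared SD — values a soft-hydrogel
practitioner would call typical. The calibration fluid defaults to
µ = 30 Pa·s; the nominal silicone-oil grade is specified kinematically
(30 000 cSt), so the dynamic value assumes ~1 g/mL density and is a config
field, not a constant.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: spatial inhomogeneity of the magnetic-field
gradient across the field of view, non-spherical probe geometry, matrix
nonlinearity, correlated tracking errors, or local flows dragging reference
spheres (observed for large probes). Recovery results certify the
statistical machinery under the model's own assumptions, not the
instrument's physics.

## Problem sizes in the recovery studies

Chosen as the package's standard verification workload: calibration
recovery uses 100 replicates of 50 spheres at 5% velocity noise;
multilevel coverage uses 20 replicates of one matrix at the full design
size (3 × 2 × 12 spheres × 2 repeats); ordering and ELPD studies use
reduced designs (18 and 12 spheres) where the effects under test are
already decisive.

## Known limitations

- The ensemble sampler's walker-split R-hat is conservative; values up to
  ~1.1 on the weakly identified per-sphere noise parameters mainly signal
  slow tail exploration, but are still reported and flagged honestly.
- Exact-refit ELPD scales linearly in sphere count × chain length; beyond
  a few dozen spheres the PSIS path is the practical choice.
- The InvGamma noise prior with a HalfNormal-distributed *shape* admits
  very heavy tails when the shape is small; this is faithful to the model
  definition but is the main driver of sampling cost.
- Phase angles outside [0°, 90°] are flagged, not dropped; downstream
  summaries include them unless QC-filtered.
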