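# Methods

This note documents the models, estimators and numerical choices behind
`scaledcm`, in the order the pipeline uses them, together with what the
synthetic ground truths do and do not establish about real data.

## The generative model and its inversion

All first-level fitting concerns the linear stochastic state-space model

    dx/dt = A x + C v + ω(t),

with states `x` (N regions), intrinsic coupling `A` (N×N, units 1/time),
inputs `v` (m channels) entering through the extrinsic coupling `C` (N×m),
and random fluctuations `ω`.  The model is deliberately linear: its
trajectories under time rescaling map onto rescaled coupling matrices
exactly (`A → b^α A`, `C → b^(α+1) C`), which is the hypothesis the second
level tests.  Bilinear and higher-order extensions are out of scope.

**Priors.**  Gaussian, elementwise: diagonal of `A` at −1, off-diagonal at 0,
all variances 1, so that every region is self-inhibiting a priori and the
system decays after perturbation.  Entries of `C` default to fixed at zero
(variance 0), the appropriate convention for spontaneous recordings where
inputs have been regressed out; set `c_free=True` in `PriorSpec.default` to
estimate them.  A parameter with zero prior variance is excluded from the
free set and keeps its prior mean exactly.

**Variational Laplace.**  `scaledcm.laplace.variational_laplace` maximises the
free energy

    F = E_q[log p(y | θ, λ)] − KL(q(θ) ‖ p(θ)),   q = N(m, Σ),

by Gauss–Newton with step halving (accepted steps never decrease F), with the
observation noise treated as i.i.d. Gaussian with log precision λ updated by
its ML-II fixed point (flat hyperprior), or held fixed when the caller knows
the precision.  Convergence: relative change in F below 1e-6, cap 128
iterations; non-convergence is reported in the results object, not raised.
For a linear forward mapping and fixed λ the scheme is exact — the posterior
equals the conjugate closed form and F equals the log evidence — and the test
suite pins this to 1e-6 / 1e-3.  λ is capped at 32 so that noiseless data
(infinite precision) remain finite.

**Two likelihoods.**  The discrete-time data can be scored in two ways:

* `onestep` (default): predict `x[t+1] = expm(A Δ) x[t] + drive` and treat
  the residuals as white.  For decaying stochastic dynamics (real spectrum,
  e.g. OU-like imaging signals) this is the exact discretisation and is
  statistically efficient.
* `autocov`: fit the empirical lagged autocovariance to the model form
  `R(kΔ) = expm(A kΔ) R(0)` over k = 1..K lags.  Narrowband deterministic
  oscillations (orbital radii) defeat the one-step map: the state carries no
  quadrature component, so a one-lag regression of `cos(ωt)` yields
  `ln cos(ωΔ)/Δ ≈ −ω²Δ/2`, which scales as the *square* of the time
  rescaling.  Matching the autocovariance sequence instead ties `A` to the
  oscillation frequency itself (`A` acquires complex eigenvalues `−γ ± iω`),
  and the estimator is covariant: rescaling the data in time rescales the
  fitted `A` by the same factor.  The lag window K is chosen from the data —
  1.2 measured orbital periods for orbits, 3 measured 1/e times for lattice
  levels — so the window tracks each scale's own clock.  This is a
  pseudo-likelihood (autocovariance residuals are not independent); its
  posterior spreads are used as relative weights by the second level, not as
  calibrated frequentist errors.

**Bayesian model averaging.**  `bayesian_model_average` combines posteriors
by moment matching under softmax(F) weights (fixed-effects BMA) — identical
posteriors average to themselves, and a 20-nat evidence gap hands all weight
to the winner.  When pooling fits of *different data segments* (the blocks of
one lattice level), softmax weighting degenerates to winner-take-all because
evidence differences of hundreds of nats reflect segment noise rather than
model preference; the pipeline therefore pools blocks with `weights="equal"`.
The averaged covariance keeps the between-fit spread (mixture moments), so a
level's representative posterior is honest about block-to-block variability.

## Scaling transformations

`scale_trajectory` returns `b^β · b · r(b^α t)` on the original grid by cubic
interpolation; samples whose rescaled time falls outside the recorded span
are truncated with a warning, never extrapolated.  `β` is carried for
completeness but the analyses all z-score first, which pins β = 0.
`scale_connectivity` implements both the uniform law `(b^α A, b^(α+1) C)` and
the per-node elementwise law `a_ij → b_i^(α+1)/b_j · a_ij`,
`c_ij → b_i^(α+2)/b_j · c_ij`; the uniform case is the elementwise case with
all factors equal, and the tests verify closure: integrating the rescaled
model from the rescaled initial state reproduces the rescaled solution to
interpolation tolerance.

`kepler_alpha` solves `2α + 3 = 0`: rescaling a gravitational trajectory
leaves a factor `b^(2α+3)` on the central mass, and the unique exponent that
removes it is −3/2 — Kepler's third law in scaling form.

## Orbit simulation

Three bodies (sun + two planets) in 2D under pairwise inverse-square gravity,
integrated with a fourth-order Yoshida composition of velocity-Verlet steps.
Defaults: `G·M_sun = 1`, mass ratio 1e5 (sun wobble negligible), planets
started at periapsis on opposite sides with eccentricity 0.2 at radii 1.0 and
1.1.  The inner step is ~1/2000 of the shortest initial orbital period, giving
relative energy drift ~1e-11 (tested bound 1e-6) and momentum conservation to
1e-9.  Families grow the initial conditions by 10% per scale (velocities by
the square root, preserving shape) for ten scales, each run for six periods
of its outer planet at a common sampling interval of 0.05 time units.  A
close encounter below the separation floor raises rather than integrating
through an unresolved force.

`measure_orbit` takes the semi-major axis as the mean of the apsidal extremes
and the period from the first peak of the *per-lag Pearson* autocorrelation
of the radial distance, refined by parabolic interpolation.  The Pearson
normalisation (each lag window standardised separately) matters: the raw
autocovariance estimator's partial-period edge bias shifts the peak by a few
percent, an order of magnitude above the 1e-3 tolerance the period check
uses.  Eccentricity and run length are package choices; the simulation's
periods and axes are measured from the output, never assumed.

## Coarse graining and the correlation route to z

A lattice movie is an L×L×T array, L a power of two.  One coarse-graining
step replaces 2×2 regions by their mean; z-scoring is applied per region
before every analysis step (block averaging shrinks variance, and the
scale-free relation is stated for unit-variance signals).  The time
correlation function averages `x_i(t₀+t) x_i(t₀)` over regions *and* time
origins — stationarity is assumed; a single-origin product is far too noisy
to threshold.  The decay time is the first crossing of `C(0)/e`, located by
linear interpolation between bracketing lags; absence of a crossing raises.

`estimate_z_correlation` regresses `log2(decay time)` on level (block factor
2 per step), weighted by the square root of each level's region count: the
coarser the level, the fewer series enter its average and the noisier its
decay time.  Two equally weighted levels reduce to `z = log2(t_b / t_r)`.

A finite-record caveat shapes several defaults: the sample autocorrelation of
a z-scored series is biased low at lags that are an appreciable fraction of
the record (subtracting the sample mean removes the slowest fluctuations).
Measured: an OU timescale of 16 time units in a 100-unit record reads as ~7.4.
Decay-time estimates are therefore only trusted when many correlation lengths
fit in the record, which drives the synthetic defaults below, and the
coarsest levels of short recordings should be read with this bias in mind.

## The second level: evidence scan by Bayesian model reduction

Given per-scale posteriors over `A` and scale factors `b_s` (orbit size
ratios, or `2^level` under coarse graining), the hypothesis
`A_s = b_s^α A_base` is scored by Bayesian model reduction: the log-evidence
change from replacing each non-base scale's prior with a tight prior
(sd 0.05) centred on the rescaled base posterior mean, summed over scales.
The reduction formula is exact for linear-Gaussian models and is tested
against a directly computed evidence difference.  Scanning α over a grid
(default [−3, 0] step 0.05; z over [0, 3] via α = −z) yields the evidence
curve; its peak is the reported exponent, with exact ties broken toward the
smallest magnitude.  Noise trials perturb the non-base `b_s` by multiplicative
Gaussian noise (default sd 0.01, 100 trials, seeded) to give a distribution
of peaks, mirroring how sensitivity to the assumed scale factors is probed.
Per-element curves (1-D reductions on the marginal posteriors) are emitted
alongside the summed curve.

The degenerate case of identical scales gives an exactly flat curve, which is
detected and flagged rather than yielding an arbitrary peak.

## Synthetic ground truths

**Scalable families** draw a stable base `A` (diagonal −1/τ₀, off-diagonals
uniform in ±0.3/τ₀, redrawn until stable), then integrate `A_s = b_s^α A`
per scale with seeded state noise — scalable by construction, with the
generating model returned alongside each series.

**Scale-free lattices** are built coarsest-first: the top-level signal is an
OU process with the slowest timescale, and each finer level adds faster OU
innovations (timescale `τ₀·2^(z·level)`) that are centred within each 2×2
block, so block averaging reproduces the parent signal exactly up to
amplitude.  The parent contributes a fixed variance fraction
(`parent_weight`, default 0.2).  OU paths use the exact AR(1) discretisation
`φ = exp(−Δ/τ)`, keeping discretisation bias out of the ground truth.  White
observation noise (sd 0.1) is added per region before z-scoring.  Defaults:
L = 16, T = 2000 samples at Δ = 0.05 (a 20 Hz-like rate), τ₀ = 0.15 time
units — chosen once so that even the coarsest analysed level (2×2) retains
at least ~25 correlation lengths in the record across the exponent range
studied, keeping the finite-record bias described above out of the
ground-truth decay times.  The generator returns levels down to 2×2; the 1×1
top level only seeds the hierarchy.

What these lattices do *not* emulate: calcium-indicator kinetics (GCaMP rise
and decay), hemodynamic contamination, spatially correlated optics (light
diffusion couples neighbouring pixels), atlas geometry, or non-stationary
behavioural state.  Passing the recovery tests shows the estimators are
correct for self-similar OU hierarchies observed in white noise — it does not
certify the exponents obtained from any particular real recording, where the
listed factors add bias of their own.

## Coarse-graining workflow specifics

Per level: z-score; partition into 2×2-region blocks; fit a DCM per block; at
the three finest levels only a random quarter of the blocks is fitted
(seeded), for expediency, and all blocks at coarser levels; pool the block
posteriors with equal weights into one representative coupling matrix per
level; then coarse-grain and repeat through the 2×2 level (a 64×64 input
yields six levels).  Zero-variance blocks are skipped and logged with their
coordinates.  The block state vector defaults to the two diagonal-pair
averages of the four regions ("2×2 connectivity matrices" over 2×2-region
blocks); a 4-state variant is available (`block_states=4`).  Block fits use
the `autocov` likelihood with the level-tracking lag window; the `onestep`
option remains available but its rates carry an additive
`ln(1+σ²_noise)/Δ` offset under observation noise that flattens the
cross-level power law.  The z scan compares every level to the finest level
(base scale 1).

All workflow randomness (block sampling, scan noise trials) derives from the
single config seed; reports carry the sampled block indices per level so any
individual fit can be replayed.

## Known limitations

* The inversion estimates a single isotropic noise precision; cross-region
  noise covariance is not modelled.
* The `autocov` pseudo-likelihood's free energy is a fit score, not a
  calibrated evidence; comparisons across *different likelihoods* are not
  meaningful (the pipeline never mixes them within one scan).
* The evidence-scan exponent for a single L=16, T=2000 lattice has a
  seed-to-seed spread of roughly ±0.1; headline recoveries are therefore
  quoted as small seed averages (the acceptance script uses three).
* Orbit families assume near-circular-to-moderately-eccentric orbits; very
  high eccentricities would need a smaller integrator step near periapsis.
* Per-node (`b_i ≠ b_j`) connectivity scaling is implemented and internally
  consistent, but no worked ground truth exercises unequal factors.
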