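# scaledcm

Dynamic causal modelling of **scalable** and **scale-free** dynamical systems.

A system is *scalable* (mechanically similar) if, whenever `r(t)` solves its
equation of motion, so does the rescaled trajectory `b · r(b^α t)` — possibly
after a lawful rescaling of its parameters.  For the linear state-space model

    dx/dt = A x + C v + ω(t)

this holds for any temporal exponent α provided the coupling matrices
co-rescale as `A → b^α A` and `C → b^(α+1) C`.  A system is *scale free* if
coarse graining leaves its statistics unchanged; then the characteristic
relaxation times of blocks and their constituent regions obey `t_b = b^z t_r`,
where `z` is the dynamical critical exponent of renormalization-group theory,
and for z-scored signals the two pictures connect through `α = −z`.

`scaledcm` turns both statements into an inference pipeline:

1. **First level** — fit the linear model to each scale's timeseries by
   variational Laplace (`LinearDCM(...).fit()` → a Gaussian posterior over the
   intrinsic coupling matrix `A` plus the free energy `F`, a lower bound on
   log model evidence).
2. **Second level** — score the scaling hypothesis `A_s = b_s^α · A_base`
   across scales by Bayesian model reduction for each candidate exponent
   (`ExponentScan(...).fit()` → an evidence curve `F(α)` or `F(z)` whose peak
   is the exponent the data support).

Two ground-truth systems exercise the pipeline end to end:

* a symplectic three-body simulator (sun + two planets, mass ratio 1e5).
  Growing the orbits by 10% per scale, ten times, and scanning α over the
  per-scale DCM posteriors recovers **α = −3/2, Kepler's third law,** from
  the radial timeseries alone;
* a seeded generator of square lattice movies whose block-averaged signals
  relax slower by `2^z` per 2×2 coarse-graining step.  Both the
  correlation-function route (1/e decay times per level) and the
  evidence-scan route recover the generating `z`.

The same machinery consumes real region × time imaging matrices (CSV/HDF5) or
movie stacks (TIFF/HDF5), e.g. wide-field calcium recordings, via
`scaledcm coarse-grain`.

## Worked example

Generate a scalable family with a known exponent, fit each scale, scan:

```python
import numpy as np
from scaledcm import LinearDCM, ExponentScan, ScaleSeries
from scaledcm.synthdata import SynthSpec, generate_scalable_series

spec = SynthSpec(kind="scalable_series", seed=42, alpha_true=-1.5, T=1000,
                 dt=0.25, base_timescale=1.0, noise_sd=0.05,
                 scales=(1.0, 1.5, 2.0, 3.0))
family = generate_scalable_series(spec)                 # (b, data, model) per scale
posteriors = [LinearDCM(ts.zscore()).fit() for _, ts, _ in family]
print(posteriors[0].summary())

series = ScaleSeries(tuple((b, p) for (b, _, _), p in zip(family, posteriors)))
print(ExponentScan(series, n_trials=100, noise_sd=0.01).fit(seed=0).summary())
```

which prints (first-level posterior for the base scale, then the scan):

```
Linear DCM results
======================================================
method: onestep   converged: True   iterations: 3
free energy F: -81.4348 nats   log noise precision: 2.766
------------------------------------------------------
parameter     prior mean   post mean     post sd
a[0,0]           -1.0000     -1.0044      0.0745
a[0,1]           -0.0000     -0.0758      0.0716
a[1,0]           -0.0000      0.2081      0.0738
a[1,1]           -1.0000     -0.9258      0.0709
======================================================

Exponent scan results
======================================================
grid: [-3, 0] step 0.05   trials: 100
mode alpha* = -1.450   peak range [-1.500, -1.450]
...
```

The scan's mode (−1.45) recovers the generating exponent (−1.5) to within one
grid step: the data were built so that `A` shrinks as `b^−1.5` across scales,
and the evidence peaks where that hypothesis explains the four coupling
posteriors best.  The per-scale posterior shows the fitted coupling matrix
with its prior (diagonal −1, off-diagonal 0, variance 1) and posterior
uncertainty.

The same analysis from the shell, with the orbit simulator as the data source:

```bash
scaledcm kepler --seed 1 --out out/          # full 10-scale run, ~40 s
# alpha mode = -1.500 (Kepler slope 1.4997); report in out/
scaledcm synth --kind scalefree_lattice --L 16 --T 2000 --z 0.5 --seed 7 --out fx/
scaledcm coarse-grain --movie fx/fixture000_level0.h5 --seed 9 --out out-z/
# z mode = 0.300 (correlation-based z = 0.429); report in out-z/
```

(single-lattice evidence modes carry a spread of roughly ±0.1 about the
generating exponent; the acceptance script averages a few seeds)

## Layout

| module | contents |
| --- | --- |
| `scaledcm.dcm` | `LinearDCM` / `DCMResults`, forward integration, variational-Laplace inversion, Bayesian model averaging |
| `scaledcm.laplace` | the Gauss–Newton variational-Laplace engine |
| `scaledcm.scaling` | trajectory/input/connectivity rescaling, `kepler_alpha`, α ↔ z |
| `scaledcm.orbits` | symplectic N-body simulator, orbit families, orbit measurement |
| `scaledcm.renorm` | lattice movies, 2×2 coarse graining, correlation functions, decay times, correlation-based z |
| `scaledcm.evidence` | `ScaleSeries`, Bayesian model reduction, `ExponentScan` evidence curves |
| `scaledcm.synthdata` | seeded scalable-family and scale-free-lattice generators, fixture manifests |
| `scaledcm.pipeline` | the Kepler and coarse-graining workflows, movie I/O, reports |
| `scaledcm.cli` | `scaledcm` command: `simulate-orbits`, `synth`, `transform`, `fit-scales`, `kepler`, `coarse-grain`, `estimate-z` |
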