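# ivdratchet

Analysis of **ratcheting** in intervertebral discs under stress-controlled
cyclic compression. When a disc is loaded with an asymmetric stress cycle
(valley 0 MPa, peak Δσ), its mean strain creeps forward cycle by cycle —
the hysteresis loop drifts and densifies without closing. This package is
for tissue biomechanists who want to extract, model and predict that
behaviour from cyclic-test records, and to simulate realistic records when
no raw data are available.

## What it computes

From a stress–strain time series segmented into cycles, the per-cycle
**ratcheting strain** and its rate are

```
ε_r(N) = (ε_min + ε_max) / 2,        ε̇_r = dε_r/dN,
```

with ε_min, ε_max the valley and peak strain of cycle N. The evolution of
ε_r is described by a saturating one-parameter constitutive law controlled
by the ratcheting stress e_r (the peak stress, MPa):

```
X_r(N) = K · X_SR · (1 − α^(−N^β)),      X_SR = k_r · (e_r − e_rth)+
```

where X_SR is the saturated ratcheting strain (linear in stress above the
threshold e_rth, with ratcheting coefficient k_r), K is a dimensionless
material coefficient (≈ 0.01 for ovine lumbar discs), and the evolution
parameters depend linearly on stress: α = 53.565 + 10.571·e_r and
β = 0.13 − 0.035·e_r. Fitting curves at three or four stress levels is
enough to determine K and these relations, after which the law predicts
the ratcheting evolution at unseen stress levels.

Modules:

* `ivdratchet.synthetic` — triangular-wave loading protocols, specimen
  geometry (elliptic area with coefficient k = 1.01), and a synthetic
  generator producing records with the qualitative structure of real disc
  tests (densifying unclosed loops, two-stage ratcheting, rate and segment
  effects). Compression is positive throughout.
* `ivdratchet.cycles` — cycle segmentation, ε_r, ε̇_r, strain range, and
  loading-branch secant stiffness in N/mm (force = σ·S, displacement = ε·h).
* `ivdratchet.model` — the constitutive law (with a registry of evolution
  forms), per-curve nonlinear least squares, K regression, parameter–stress
  relations, prediction.
* `ivdratchet.stats` — endpoint tables at a chosen cycle (default 400),
  Pearson correlations, one-way ANOVA, directional-effect report.
* `ivdratchet.cli` — `ivdratchet simulate | metrics | fit | predict | report`.

## Worked example

Fit model-generated ratcheting curves at the three training stresses,
recover the material coefficient and the parameter relations, and predict
a held-out stress level:

```python
import numpy as np
from ivdratchet import model as mdl

N = np.arange(1, 401)
params = mdl.URMKParams()          # K = 0.01, k_r = 1, e_rth = 0
fits = {e: mdl.fit_single_curve((N, mdl.evaluate(N, e, params)))
        for e in (0.59, 1.18, 1.76)}
K = mdl.fit_K([f.amplitude for f in fits.values()], list(fits))
rel = mdl.fit_parameter_relations([(e, f.alpha, f.beta) for e, f in fits.items()])
print(f"K = {K:.4f}")
print(f"alpha(e_r) = {rel.alpha_intercept:.3f} + {rel.alpha_slope:.3f}*e_r  (R^2 = {rel.alpha_r_squared:.4f})")
print(f"beta(e_r)  = {rel.beta_intercept:.3f} {rel.beta_slope:+.3f}*e_r  (R^2 = {rel.beta_r_squared:.4f})")
pred = mdl.predict(0.88, N, rel, K=K)
print(f"predicted ratcheting strain at 0.88 MPa: "
      f"cycle 1 = {pred.at_cycle(1):.6f}, cycle 400 = {pred.at_cycle(400):.6f}")
```

prints

```
K = 0.0100
alpha(e_r) = 53.565 + 10.571*e_r  (R^2 = 1.0000)
beta(e_r)  = 0.130 -0.035*e_r  (R^2 = 1.0000)
predicted ratcheting strain at 0.88 MPa: cycle 1 = 0.008660, cycle 400 = 0.008795
```

The fitted K equals the generating value 0.01; the recovered α and β lines
match the generating relations; and the 0.88 MPa prediction lies between
the 0.59 and 1.18 MPa curves, already at 98% of its plateau after the
first cycle — ratcheting in this regime is front-loaded.

The same workflow from a shell, on simulated cohorts:

```sh
ivdratchet simulate --out sim                      # default 10-condition cohort
ivdratchet metrics sim/series_*.csv --out met      # per-cycle summaries
ivdratchet fit met/*.cycles.csv --out fitted       # K, alpha/beta relations
ivdratchet predict --params fitted/params.json --stress 0.88 --out pred.csv
ivdratchet report met/*.cycles.csv --out rep       # endpoint table + effect signs
```

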