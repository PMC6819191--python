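# Methods

## The ratcheting evolution model

Under asymmetric cyclic compression (valley 0 MPa, peak Δσ), disc strain
accumulates cycle by cycle. The per-cycle state variable is the ratcheting
strain ε_r(N) = (ε_min + ε_max)/2, with ε_min and ε_max the valley and peak
strain of cycle N (1-based), and its rate ε̇_r = dε_r/dN. The constitutive
law implemented here is a saturating one-parameter model controlled by the
ratcheting stress e_r (the peak stress, in MPa):

    X_r(N) = K · X_SR · (1 − α^(−N^β)),      X_SR = k_r · (e_r − e_rth)+

with

| symbol | meaning | units | default |
|---|---|---|---|
| K | material coefficient | — | 0.01 |
| k_r | ratcheting coefficient | strain/MPa | 1.0 |
| e_rth | ratcheting threshold | MPa | 0.0 |
| α(e_r) = 53.565 + 10.571·e_r | evolution parameter (> 1) | — | linear in stress |
| β(e_r) = 0.13 − 0.035·e_r | evolution parameter (0 < β < 1) | — | linear in stress |

Assumptions: the evolution is controlled by peak stress alone — no
temperature, creep-hold or load-history effects — and is rate-independent
even though disc data are rate-dependent, so fits are kept stratified by
stress rate. X_SR (the saturated ratcheting strain) is clamped at zero
below the threshold; sub-threshold behaviour is otherwise unspecified.
k_r and e_rth are not identifiable from a single stress sweep together
with K (only the product K·X_SR is); they are explicit configuration knobs
fixed during fitting, defaulting to 1 strain/MPa and 0 MPa.

### Functional form

The evolution factor is implemented as a registry of forms. The default,
`saturating_power`, reads the law as 1 − α^(−N^β): among the candidate
readings of the flattened expression it is the only one that is bounded in
(0, 1), increasing and saturating for the fitted α ≈ 54–72 and β ≈ 0.07–0.11.
An alternative reading, `exponential_rate` (1 − α^(−β·N)), stays selectable
through `form_id`. An empirical discriminator is the early-accumulation
fraction: with the default form at e_r = 1.76 MPa, about 46% of the
post-first-cycle accumulation over 200 cycles occurs within the first five
cycles, consistent with the observed sharp-rise/quasi-steady two-stage
evolution.

Under the default form X_r is strictly increasing in N and in e_r (above
threshold), its per-cycle increments are positive and decreasing, and
X_r ≤ K·X_SR with X_r/(K·X_SR) → 1. Note that the model front-loads the
accumulation heavily: X_r(1) = K·X_SR·(1 − 1/α) is already ≈ 98.5% of the
plateau, so a single model curve spans only ~1.2–1.7% of its own level.
This matters for fit-quality statistics (below).

## Fitting

Per curve, `fit_single_curve` minimizes unweighted least squares of
A·f(N; α, β) against ε_r(N) with A (= K·X_SR), α and β free, using
`scipy.optimize.least_squares` (trust-region reflective, ftol = xtol =
gtol = 1e-15) multi-started over a β grid {0.02, 0.05, 0.1, 0.2, 0.5} with
bounds α ∈ (1, 10⁴], β ∈ (0, 1); α is started from the first-cycle ratio
y₁/A₀ via α₀ = 1/(1 − y₁/A₀). The best-RSS start wins. A curve whose total
variation is below 10⁻⁹ of its level is flagged degenerate (amplitude =
mean, evolution parameters undefined). On noise-free model-generated
curves the recovery is exact to ≈ 10⁻¹⁴ relative.

The material coefficient is the origin-constrained least-squares slope of
per-condition amplitudes on X_SR(e_r): K = Σ A·X / Σ X², requiring at least
two distinct stresses. The parameter–stress relations are ordinary
least-squares lines of the per-condition mean fitted α and β on e_r.
Prediction at a new stress evaluates the law with α(e_r), β(e_r) and
X_SR(e_r); it refuses stresses where β(e_r) ≤ 0 (the linear β relation
turns negative near e_r ≈ 3.7 MPa with the default coefficients) and warns
outside the training-stress range widened by a configurable band (default
50% of the span).

### Fit-quality statistic

`FitResult` reports the per-curve Pearson R between fit and data. Because
a single curve spans so little of its plateau, per-curve R is *bounded*
near s/√(s² + σ²) ≈ 0.3–0.5 when the noise sd is 0.5% of the plateau — no
fitting procedure can do better. The headline fit-quality number computed
by the acceptance script is therefore the Pearson R between the fitted
model and the data pooled across the stress conditions (per replicate
seed, median across seeds), which measures how well the model family
tracks the data across its full dynamic range — the model-versus-all-data
sense in which a correlation of 0.99 is meaningful here.

## Synthetic test records

No raw disc-test data are deposited anywhere, so the generator is a
first-class part of the package. One record is

    strain(t) = stress(t)/E + drift(N(t)) + hysteresis(t) + noise

* **Command**: piecewise-linear triangular stress, valley 0 MPa, period
  2Δσ/rate, sampled with an integer number of samples per ramp (≥ 20,
  default 25) so every valley and peak lies exactly on the grid. This makes
  per-cycle metrics invariant to uniform resampling by construction.
* **Elasticity**: a per-condition secant modulus
  E = E_ref·(rate/0.59)^0.1·(Δσ/1.18)^0.15 with E_ref = 5 MPa. E_ref gives
  a disc stiffness E·S/h ≈ 495 N/mm for the typical geometry
  (S = 394 mm², h = 3.98 mm), within the range reported for ovine lumbar
  discs; the two small positive exponents encode rate- and
  amplitude-stiffening so that measured stiffness rises with both factors.
* **Drift**: the constitutive law scaled by (rate/0.59)^(−0.3) (faster
  loading ratchets less — trapped fluid resists load) and by a segment
  factor (L6–7 default 0.8: the caudal segment is more
  ratcheting-resistant). The drift channel is piecewise-linear with knots
  at each commanded valley and peak, chosen as valley_N = X_N − ΔX_N/2 and
  peak_N = X_N + ΔX_N/2 (ΔX_N = X_{N+1} − X_N), so the mean of the cycle-N
  valley and peak strain equals exactly X_r(N) + Δσ/(2E). Because the
  increments decrease, the knot sequence is monotone: loops stay unclosed
  and the per-cycle strain range strictly decreases (densification).
* **Hysteresis**: a half-sine per branch, w·sin(2π·phase) with w = 0.004
  strain, positive on loading. It opens the loop but vanishes at valley
  and peak, so it does not perturb ε_r.
* **Noise**: i.i.d. Gaussian on strain only (the stress channel is
  commanded and exact), default sd 0 — the deterministic mechanical
  response; measurement noise is opt-in.
* **Cohorts**: replicate variability is log-normal (keeping parameters
  positive) on the modulus (log-sd 0.03) and the drift amplitude (log-sd
  0.08) — matched-specimen levels appropriate for same-spine protocols;
  both are free calibration knobs. Per-series seeds derive from
  (seed, condition index, replicate index), so cohorts are byte-reproducible.

### What the generator does and does not emulate

It reproduces the directional structure of disc ratcheting experiments —
ε_r rises with Δσ and falls with rate, stiffness rises with both, L6–7 <
L5–6, two-stage evolution, densifying unclosed loops — with magnitudes set
by the default calibration, not measured from tissue. It does not model
poroelastic fluid flow, nonlinear (strain-level-dependent) elasticity
within a cycle, tertiary ratcheting or specimen failure, temperature or
hydration history. Passing tests therefore demonstrate correctness of the
pipeline and self-consistency of the model, not agreement with any
particular physical specimen; published correlation magnitudes (e.g.
R = 0.962 for ε_r vs Δσ) are data-dependent and only their signs are
meaningful on synthetic cohorts.

A further deliberate mismatch: measured ε_r curves contain the elastic
offset Δσ/(2E) that the pure evolution law does not, so amplitudes fitted
to full pipeline output absorb that offset. Exact coefficient-recovery
checks are run on model-generated curves; pipeline-level fits are checked
for fit quality and effect directions instead.

## Statistics

Endpoints (ε_r and stiffness) are taken at a configurable cycle, default
the 400th. Pearson correlations are two-sided via the t transform; ANOVA
is the standard one-way F. No multiple-testing correction is applied.
Factor effects are assessed one-factor-at-a-time: each correlation is
computed at the level of the other factor with the widest coverage. The
segment comparison is restricted to loading conditions present in every
segment group, since pooling unbalanced cells would confound the means;
segments and conditions are treated as separate one-way analyses.

## Numerical and design choices

* Compression positive for stress and strain everywhere, stated in every
  writer; cycle indexing 1-based.
* Valley strain is read at the commanded-valley sample (not the in-cycle
  minimum) and peak strain at the maximum-stress sample: robust to
  hysteresis shape.
* Stiffness is the loading-branch secant (F_peak − F_valley)/(d_peak −
  d_valley) with F = σ·S, d = ε·h — the machine-log convention; it is not
  a tissue modulus.
* ε̇_r uses central differences, one-sided at the ends.
* The elliptic area is (π/4)·length·width·k with k = 1.01; k corrects the
  ideal ellipse to the measured cross-section.
* `URMKParams` allows K = 0 (drift switched off for pure-elastic
  baselines); fits yield K > 0.
* Degenerate inputs: constant curves → degenerate fit flag; zero
  displacement span → explicit stiffness error; sub-period records →
  segmentation error; trailing partial cycles are dropped.

## Problem sizes

Tests and the acceptance script use 400-cycle curves at three stresses
(plus 200-cycle records for loop-shape checks), cohorts of up to 27 series
at 3 replicates, and 20 noise replicates for the fit-quality statistic —
sizes matched to the study designs they emulate; the full suite runs in
well under a minute.
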