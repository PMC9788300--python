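# Methods

## Model and estimators

The observation model is binary proximity detection: detector `k` records
animal `i` on occasion `s` at most once, independently across detectors and
occasions, with probability `g(d_ik) = g0 · exp(−d_ik²/(2σ²))` where `d_ik`
is the distance from the animal's latent activity centre to the detector.
Activity centres are the points of a spatial point process whose intensity
is the density `D` being estimated.

Fitting uses the likelihood conditional on the number of detected animals
`n`.  Each detected animal contributes

    Pr(ω_i) = ∫ Pr(ω_i | x) dx / a(θ),   a(θ) = ∫ p·(x) dx,

with both integrals approximated as sums over a discretised habitat mask.
Because detection probabilities are occasion-constant, `Pr(ω_i | x)` depends
on the history only through per-detector detection counts; the
implementation exploits this to evaluate all animals × all mask cells as two
matrix products per likelihood call.  Under homogeneous density the
conditional and full likelihoods give identical detection-parameter
estimates, so constant-density pooled fits are reported as
full-likelihood-equivalent without a separate implementation.

Density and its uncertainty: `D̂ = 100·n/â` (per 100 km²; areas are carried
in km², coordinates in metres, with the single conversion in
`density_per_100km2`), `var(D̂) = D̂²[var(n)/n² + var(â)/â²]` with
`var(n) = n` under the Poisson assumption and `var(â)` by the delta method
on the link scale (logit g0, log σ).  Regional estimates across `J` arrays
use the mean of array densities; the Poisson variance substitutes
`var(n) = n` and `var(Â) = Σ var(â_j)` (independence across arrays), the
empirical variance substitutes the across-array sample variance of the
`n_j`.  Intervals are the standard back-transformed lognormal form
`(D/C, D·C)`, `C = exp(z·√log(1 + var/D²))`; the formula is the SECR
literature's convention, chosen here as the interval named (but not printed)
alongside these estimators.

Model-sharing modes for multi-array data: `pooled_constant` (one θ),
`pooled_additive` (common θ plus per-array additive link-scale offsets on
both g0 and σ, first array as reference), `pooled_interactive` (separate θ
per array, jointly maximised).  The interactive model factorises by array,
so it reproduces independent per-array fits — a property the test suite
verifies to 1e-4 relative rather than assumes.

## Numerical choices

* **Links and bounds.** logit(g0) ∈ (±13.8) (g0 within [1e-6, 1−1e-6]) and
  log σ ∈ [0, log 1e7] (σ between 1 m and 10,000 km), enforced as box
  constraints.  A solution on a bound is reported as non-convergence.
* **Starts.** g0 starts at 0.2.  σ starts at the root pooled spatial
  variance of detection locations (per-animal centroids, pooled squared
  deviations over both axes, divided by twice the pooled degrees of
  freedom), clamped to [spacing/4, 20·spacing], falling back to half the
  detector spacing when no animal moved.
* **Optimiser.** Bounded quasi-Newton (L-BFGS-B, ftol 1e-12, gtol 1e-7)
  with numerical gradients and one restart from a perturbed start on
  failure.  Covariance is the inverse of a central-difference Hessian
  (step 1e-4 link units); a non-positive-definite Hessian is a failure.
* **Mask.** Union-of-discs buffer around the detectors rasterised on a
  square grid (a cell belongs to the mask when its centre is within the
  buffer of some detector).  Default buffer 4σ and cell side
  min(σ/2, spacing/2), both data-driven via the σ start value.  After
  fitting, if σ̂ exceeded its start the mask is rebuilt at 4σ̂ and the fit
  repeated once (two-pass), guarding against truncated integration when the
  start underestimates σ.  Half-normal detection at 4σ is
  `g0·e⁻⁸ ≈ 3·10⁻⁴·g0`, so truncation error in â is far below the Monte
  Carlo noise of the studies here; mask-area convergence under cell
  refinement is property-tested.  A fixed buffer (e.g. the 15-km buffer
  used in large-mammal field studies) can be supplied instead.
* **Minimum-data rule.** An array is estimable only with n ≥ 5 individuals
  and ≥ 1 spatial recapture (configurable).  Degenerate inputs — zero
  recaptures, all detections at one detector — therefore return an explicit
  failure result rather than a boundary estimate.
* **AICc** uses the number of detected individuals as the sample size, the
  SECR convention.

## Simulator and study design

The generator emulates the replicated-array design: a 200 × 300 km
rectangle, six 5 × 8 arrays of 40 detectors at exactly 2-km spacing, six
occasions.  Array centres sit on a 2 × 3 systematic grid at
(50, 50), (150, 50), (50, 150), (150, 150), (50, 250), (150, 250) km —
two arrays per 100-km band — so detectors of different arrays are ≥ 86 km
apart and no simulated animal is detectable on two arrays (verified both
analytically, p· < 1e-6 at the largest σ, and empirically in tests).  The
exact array coordinates and band widths are package choices (the design is
specified only as a systematic grid over equal subregions); the simulator's
manifest flags them as such.  They are immaterial in the sense that the
realised sample sizes reproduce the design's expected yields (≈182
individuals, ≈552 recaptures, ≈478 spatial recaptures per iteration of the
base scenario; ≈10.3 individuals per southern array in the hardest
scenario).

Populations are homogeneous Poisson point processes per band; detection
parameters attach to the band containing the animal's activity centre.
Four scenarios: (1) D = 12 per 100 km², g0 = 0.30, σ = 1500 m everywhere;
(2) D = 6/18/12 by band, detectability constant; (3) D constant,
g0 = 0.25/0.30/0.35 and σ = 1000/2000/3000 m by band; (4) both varying.
Animals farther than 8σ from an array's bounding box are skipped when
simulating that array (detection probability < 1e-14).  "Spatial
recaptures" are counted as movements: successive detection events (ordered
by occasion, detector index within occasion) at different detectors.

Seeds: each iteration derives its own `SeedSequence` from the master seed
and the iteration index, with separate child streams for the population and
the detection draws, so any iteration can be regenerated in isolation and
results are independent of execution order.

What the simulator does **not** emulate: curvilinear or irregular arrays,
gaps and unequal detector counts, habitat exclusion (waterbodies),
individual heterogeneity, behavioural responses to capture, sex effects, or
temporal variation in σ — all present in real field data.  Passing tests
therefore demonstrate the statistical properties of the estimators under
the idealised design, not robustness to those complications.

## Study summaries and replication

The study runner fits every array independently and one pooled
constant-parameter model per iteration, then summarises per array position
(median, MPRB, MRSE, CI coverage against the local truth) and per analysis
mode regionally (MPRB, mean percent RSE, and coverage for the Poisson
variance, plus the empirical variance for the independent-fit estimator,
matching how the two variances are meaningfully applicable).  Iterations
with any failed independent fit are dropped from the independent regional
summary and counted; local summaries use whatever fits converged.  Because
"median" across a study can mean the per-grid median over iterations or the
median over all arrays and iterations, the per-grid form is in the tables
and the overall form in the summary extras.

Default replication is 100 iterations per scenario for fitted summaries and
500 for simulation-only calibration — the package's desk-scale choice; the
reference operating characteristics for this design were established at
1000 iterations, so Monte-Carlo error at reduced replication is accounted
for explicitly: coverage comparisons use binomial standard errors, and
per-grid bias checks allow the Monte-Carlo standard error of the mean PRB
(per-grid PRB has a standard deviation up to ~35% in the sparsest scenario,
i.e. an MC standard error of ~3.5 percentage points at 100 iterations) on
top of the nominal ±3-point band.

## Known limitations

* Only the half-normal detection function and binary proximity detectors
  are implemented (no hazard/exponential forms, count detectors, or
  single/multi-catch traps).
* No covariates on detection (sex, behavioural response, time), no density
  surfaces, no finite-mixture heterogeneity; unmodelled individual
  heterogeneity will bias estimates downward here as in any SECR model.
* Masks are flat unions of discs; no habitat polygons or non-Euclidean
  distances.
* The empirical regional variance treats arrays as equal random samples; it
  underestimates when arrays are homogeneous (coverage ~0.90 in the base
  scenario) and overestimates badly when density or detectability varies —
  it is reported for completeness, with the Poisson variance as the usable
  default.
* The mean-of-densities regional estimator weights arrays equally; unequal
  inclusion probabilities or effort would require design weights that are
  out of scope.
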