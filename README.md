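# repsecr

Spatially explicit capture–recapture (SECR) density estimation for
**independent, spatially replicated detector arrays** — the survey design in
which a large region is sampled by several small clusters ("arrays") of
proximity detectors (hair snares, camera traps), each array yielding enough
data to estimate detectability locally.

It is written for quantitative ecologists who need animal density at two
scales at once: **locally** (per array) and **regionally** (averaged across
arrays), without assuming that detectability or density is constant across
the landscape — an assumption that, when violated, biases pooled-data SECR
estimates downward by 20–30%.

## The model

An animal with activity centre `x` is detected at a detector at distance `d`
on any one occasion with half-normal probability

```
g(d) = g0 · exp(−d² / (2σ²))
```

with `g0` the detection probability at distance zero and `σ` (metres) the
spatial scale of decline.  Over `S` occasions and `K` detectors the
probability of being detected at least once is
`p·(x) = 1 − Π_k (1 − g(d_k(x)))^S`, and its spatial integral over a habitat
mask is the **effective sampling area** `a(θ)`.  Conditioning the likelihood
on the number `n` of animals detected removes density from the likelihood,
so `θ = (g0, σ)` is estimated alone (on logit/log link scales) and density
follows from the Horvitz–Thompson-like estimator

```
D̂ = n / â ,    var(D̂) = D̂² [ var(n)/n² + var(â)/â² ] ,   var(n) = n .
```

Across `J` independent arrays the regional density is the unweighted mean of
array-specific densities, `D̂_region = (1/J) Σ_j n_j/â_j` (the area-weighted
alternative `Σn_j / Σâ_j` is also provided but is biased when detectability
differs among arrays).  Its variance uses either `var(n) = n` (Poisson,
assumes homogeneous density) or the empirical across-array variance
`var(n) = J/(J−1) Σ (n_j − n̄)²`.  Confidence intervals are lognormal.

The package also contains the full simulation machinery to evaluate these
estimators: a Poisson point-process population simulator on a 200 × 300 km
region with six 5 × 8 detector arrays, four scenarios varying density
(6/18/12 per 100 km²) and detectability (g0 0.25–0.35, σ 1000–3000 m) among
southern/central/northern subregions, and a study runner that reports median
estimates, mean percent relative bias (MPRB), mean relative standard error
(MRSE), and CI coverage.

## A worked example

```python
from repsecr import fit_array, make_scenario
from repsecr.study import simulate_iteration

spec = make_scenario(1)                       # D = 12/100 km², g0 = 0.30, σ = 1500 m
caps = simulate_iteration(spec, master_seed=1, iteration=0)
fit = fit_array(caps[0], spec.design[0])
```

Running `python examples/03_fit_single_array.py` (which is exactly this)
prints:

```
animals detected (n):       27
recaptures:                 68
g0 estimate:                0.291   (true 0.30)
sigma estimate:             1472 m  (true 1500 m)
effective sampling area:    246.6 km2
local density:              10.95 per 100 km2  (true 12)
RSE:                        0.198
lognormal 95% CI:           (7.45, 16.09)
```

The 27 detected animals divided by the 246.6 km² the array effectively
sampled give 10.95 animals per 100 km², within one standard error of the
simulated truth of 12.  The other scripts in `examples/` walk through the
detection geometry, the simulator, the regional estimators, and a miniature
bias study of pooled versus independent analyses.

A thin CLI wraps the same functions:

```sh
repsecr simulate --scenario 1 --iterations 5 --seed 1 --out runs/
repsecr fit --traps runs/traps.csv --captures runs/captures_0000.csv --out fits.csv
repsecr combine --fits fits.csv --out regional.csv
repsecr study --scenario all --iterations 100 --seed 1 --out study_out/
```

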