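"""A miniature simulation study: the cost of pooling heterogeneous data.

Scenario 3 keeps density constant (12 per 100 km2) but varies detectability
among subregions (g0 0.25/0.30/0.35, sigma 1000/2000/3000 m).  Fitting one
constant-detectability model to data pooled across the six arrays is precise
but negatively biased by roughly a quarter; fitting each array with its own
parameters and averaging densities removes the bias.  Run with more
iterations for tighter Monte-Carlo error (the full study uses hundreds).
"""

from repsecr import run_study

records, summary = run_study(scenario_id=3, iterations=10, seed=1)

ind = summary.regional_table.query("analysis == 'independent'").iloc[0]
pool = summary.regional_table.query("analysis == 'pooled'").iloc[0]
print("regional density, true value 12 per 100 km2, 10 iterations:")
print(f"  independent fits: median {ind['median']:.2f}  MPRB {ind['MPRB']:+.1f}%  "
      f"Poisson CI coverage {ind['coverage_poisson']:.2f}")
print(f"  pooled fit:       median {pool['median']:.2f}  MPRB {pool['MPRB']:+.1f}%  "
      f"Poisson CI coverage {pool['coverage_poisson']:.2f}")
print("\nunmodelled spatial heterogeneity in detectability biases the pooled")
print("estimate downward by ~25-30% while its narrow CI almost never covers")
print("the truth; independent per-array fits stay unbiased.")
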