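"""Simulate one iteration of the replicated-array sampling design.

Scenario 1 places a homogeneous Poisson population (12 animals per 100 km2)
in a 200 x 300 km region sampled by six 40-detector arrays, and simulates
binary proximity-detector histories over six occasions.  The printed sample
sizes are what a field crew would see: unique individuals, repeat
detections, and movements between detectors (spatial recaptures) that carry
the information about the detection scale sigma.
"""

from repsecr import make_scenario
from repsecr.study import simulate_iteration

spec = make_scenario(1)
captures = simulate_iteration(spec, master_seed=1, iteration=0)

print("array  individuals  recaptures  spatial recaptures")
for c in captures:
    print(f"{c.array_id:>5}  {c.n:11d}  {c.n_recaptures:10d}  {c.n_spatial_recaptures:18d}")
print("-" * 52)
print(f"total  {sum(c.n for c in captures):11d}  "
      f"{sum(c.n_recaptures for c in captures):10d}  "
      f"{sum(c.n_spatial_recaptures for c in captures):18d}")
print("\n(long-run means for this design are ~182 individuals, ~552"
      "\n recaptures and ~478 spatial recaptures per iteration)")
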