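"""Half-normal detection geometry and the effective sampling area.

Builds the standard 5 x 8 detector array (2-km spacing, 6 occasions),
evaluates the half-normal detection function and the overall detection
probability p.(x), and integrates p.(x) over a habitat mask to get the
effective sampling area a(theta) — the quantity that converts a count of
detected animals into a density.
"""

from repsecr import DetectionParams, build_mask, effective_area, half_normal_g, make_design, p_dot

params = DetectionParams(g0=0.30, sigma=1500.0)
array = make_design()[0]

print("detection probability at the activity centre:", half_normal_g(0.0, params))
print("  ... at one sigma (1500 m):", round(half_normal_g(1500.0, params), 4))
print("  ... at three sigma:", round(half_normal_g(4500.0, params), 6))

centre = array.coords.mean(axis=0)
print("\np.(x) at the array centre over 6 occasions:",
      round(p_dot(tuple(centre), array, params), 4))

mask = build_mask(array, buffer_m=4 * params.sigma, cell_side_m=params.sigma / 2)
a_hat, grad = effective_area(params, array, mask)
print(f"\nmask: {mask.n_cells} cells of {mask.cell_area:.4f} km2 "
      f"({mask.total_area:.0f} km2 total)")
print(f"effective sampling area a(theta) = {a_hat:.1f} km2")
print("  -> with density D animals per 100 km2, one array is expected to")
print(f"     detect D x {a_hat / 100:.2f} animals (e.g. {0.12 * a_hat:.1f} at D = 12).")
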