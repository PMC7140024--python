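"""Estimate tissue permeability from a synthetic falling-head trace.

Builds one noisy filtration trace for a scaffold with known permeability,
fits the exponential column-decay model over the 210-100 mm analysis
window, and prints the recovered K alongside the truth.
"""

from crcscaffold import DeviceGeometry, FluidProperties, fit_permeability, pressure_gradient
from crcscaffold.simulate import gen_filtration_trace

geom, fluid = DeviceGeometry(), FluidProperties()
k_true = 1500.0  # mm^4/(N s), synthetic decellularized-scaffold scale

trace = gen_filtration_trace(k_true, geom, fluid, noise_sd_rel=0.01, seed=42)
est = fit_permeability(trace, geom, fluid)

print(f"true K      : {k_true:10.1f} mm^4/(N s)")
print(f"fitted K    : {est.k_mm4_per_Ns:10.1f} mm^4/(N s)  "
      f"(objective I = {est.objective:.2e}, {est.n_points_used} points)")
print(f"window      : {est.window_mm} mm -> pressure gradient "
      f"{pressure_gradient(est.window_mm[1], geom, fluid):.2f} to "
      f"{pressure_gradient(est.window_mm[0], geom, fluid):.2f} kPa/mm")
print("The fitted K should sit within ~1% of truth at 1% height-reading noise;")
print("the gradient endpoints are the device's documented operating range.")
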