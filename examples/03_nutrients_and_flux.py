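"""Reconstruct nutrient profiles from temperature and form turbulent fluxes.

Applies the published theta->nitrate regression (valid for theta above
15 degC) to a temperature profile, differentiates the reconstructed
profile, and multiplies by an eddy-diffusivity profile to get the upward
turbulent nitrate flux in mmol N m^-2 d^-1.
"""

import numpy as np

from turbflux.biogeochem import (nutrient_from_theta, published_nutrient_registry,
                                 select_nutrient_model)
from turbflux.budget import flux_at_depth, turbulent_flux, vertical_gradient

depth = np.arange(0.0, 400.0, 5.0)
theta = np.where(depth < 40.0, 27.0, 27.0 - 0.03 * (depth - 40.0))

registry = published_nutrient_registry()
model = select_nutrient_model("L8", "nitrate", registry)  # pooled model
nitrate = nutrient_from_theta(theta, model)
print(f"nitrate at 100 m: {nitrate.values[depth == 100.0][0]:.2f} mmol m^-3 "
      f"(theta {theta[depth == 100.0][0]:.1f} degC)")
print(f"surface predictions clipped at zero: {int(nitrate.clipped.sum())} "
      "levels (depleted warm layer)")

gradient = vertical_gradient(nitrate.values, depth, smoothing_scale=10.0)
k_rho = np.where(depth > 60.0, 1.9e-3, np.nan)  # masked mixed layer
flux = turbulent_flux(k_rho, gradient, depth, species="nitrate")
f100 = flux_at_depth(flux, 100.0)
print(f"upward nitrate flux at 100 m: {f100:.1f} mmol N m^-2 d^-1 "
      "(hotspot-level K gives a flux of a few mmol per day)")
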