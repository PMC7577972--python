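"""Bloom budget from the 100-m nutrient fluxes.

Converts nitrate and phosphate fluxes at the euphotic-zone base into
Redfield new production, the steady-state chlorophyll depletion rate
gamma over its carbon-to-chlorophyll range, and the tidal-excursion
diagnostic L_e / W. Uncertainties propagate linearly from the 95%
confidence limits of the ridge-station (L4) nutrient regressions.
"""

from turbflux.biogeochem import published_nutrient_registry
from turbflux.budget import BudgetConstants, compute_budget

registry = published_nutrient_registry()
result = compute_budget(
    flux_n=4.7,    # mmol N m^-2 d^-1 at 100 m over the ridge
    flux_p=0.33,   # mmol P m^-2 d^-1
    nitrate_model=registry[("nitrate", "L4")],
    phosphate_model=registry[("phosphate", "L4")],
    constants=BudgetConstants(),
)

b = result
print(f"new production (N-limited): {b.new_production_n:.2f} "
      f"+/- {b.new_production_n_unc:.2f} g C m^-2 d^-1")
print(f"new production (P-limited): {b.new_production_p:.2f} "
      f"+/- {b.new_production_p_unc:.2f} g C m^-2 d^-1")
print(f"chlorophyll depletion rate gamma: {b.gamma_range[0]:.2f}-"
      f"{b.gamma_range[1]:.2f} d^-1 "
      "(fraction of standing chlorophyll lost per day)")
print(f"gamma corrected for regenerated production (f-ratio 0.5): "
      f"{b.gamma_modified_range[0]:.2f}-{b.gamma_modified_range[1]:.2f} d^-1")
print(f"tidal excursion L_e = {b.tidal_excursion_km:.1f} km; "
      f"L_e/W = {b.le_over_w[0]:.2f}-{b.le_over_w[1]:.2f} "
      "(below 1: advection does not dominate the local balance)")
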