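"""Estimate turbulent dissipation from a free-fall shear record.

Generates a synthetic 512-Hz shear record whose spectra follow the
Nasmyth form at a known dissipation rate, then runs the spectral
integration estimator and compares the depth-binned result with the
truth. Close agreement (within a few tens of percent per 5-m bin)
shows the iterative band selection and unresolved-variance correction
are working.
"""

import numpy as np

from turbflux.microstructure import dissipation_profile
from turbflux.synthetic import SyntheticConfig, generate_shear_record

EPS_TRUE = 1e-8  # W kg^-1, mid-range open-ocean thermocline value

config = SyntheticConfig(
    seed=12,
    epsilon_truth=lambda z, station=0: np.full_like(np.asarray(z, float), EPS_TRUE),
    nu_constant=1.2e-6,
    record_seconds=60.0,
)
record = generate_shear_record(config, station=0, n_probes=2)
profile = dissipation_profile(record, segment_seconds=4.0, bin_size=5.0)

print(f"true epsilon: {EPS_TRUE:.2e} W kg^-1")
print("depth bin    estimated eps   ratio to truth")
for d, e in zip(profile.depth, profile.epsilon):
    if np.isfinite(e):
        print(f"  {d:6.1f} m   {e:.3e}     {e / EPS_TRUE:.2f}")
print(f"median recovered: {np.nanmedian(profile.epsilon):.3e} W kg^-1 "
      "(a ratio near 1 means unbiased recovery)")
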