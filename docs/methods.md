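# Methods

## Dissipation from shear spectra

Free-fall shear records (512 Hz, nominal fall speed 0.6 m s⁻¹, up to two
probes) are cut into half-overlapping 4-s segments (~2.4 m of water),
linearly detrended, Hann-windowed with power correction, and transformed
to one-sided wavenumber spectra via the frozen-field conversion
k = f/W_fall, Φ(k) = Φ(f)·W_fall. Segment length, overlap, window and the
5-m depth bins are processing choices of this package (field practice
varies and no single standard exists); all are exposed in the
configuration. 4 s at 512 Hz resolves ~0.25–427 cpm, which brackets the
Nasmyth roll-off over the ε range of interest (10⁻¹⁰–10⁻⁶ W kg⁻¹).

Each spectrum is integrated iteratively: integrate Φ_obs from k_min
(1 cpm, excluding fine-structure contamination at larger scales) to a
provisional cutoff, form ε = 7.5 ν × variance, divide by the fraction of
Nasmyth variance resolved in that band (adding back both the low- and
high-wavenumber unresolved tails), then move the cutoff to the wavenumber
resolving 90 % of the model variance (capped by the observed band) and
repeat until the estimate changes by <1 %. The resolved fraction is
floored at 5 % to keep the correction bounded on pathological spectra.

The Nasmyth reference uses the standard closed-form fit
Φ̂(x) = 8.05 x^{1/3} / (1 + (20.6 x)^{3.715}), x = k/k_s,
k_s = (ε/ν³)^{1/4} cpm, dimensionalized by (ε³/ν)^{1/4}. Its defining
property — 7.5 ν ∫Φ dk = ε — holds to 0.1 % by quadrature, which is what
the tests assert; the constants themselves are not load-bearing.

Quality control replaces the traditional visual spectral inspection with a
deterministic surrogate: a segment is accepted when the mean
|log₁₀(Φ_obs/Φ_N)| over the fit band is below log₁₀ 3. The band for this
check extends beyond the integration cutoff into the roll-off (up to
0.5 k_s when resolved): broadband noise can mimic the near-flat inertial
subrange over a narrow low-wavenumber band, and the roll-off is the
feature that discriminates. Accepted segment estimates are averaged in
5-m bins per probe; probe values are averaged unless they disagree by
more than a factor of 10, in which case the smaller is kept (probe
contamination inflates, never deflates, apparent shear variance). Casts
are averaged bin-wise; a bin with every member rejected stays missing —
never zero.

Kinematic viscosity comes from a temperature-only fit,
ν = 1.792×10⁻⁶/(1 + 0.0337 T + 0.000221 T²) m² s⁻¹ (≈1.0×10⁻⁶ at 20 °C,
1.35×10⁻⁶ at 10 °C); salinity dependence is a ~1 % effect and is ignored.
A constant-ν override exists for controlled tests.

## Stratification and mixing

Potential-density profiles are Thorpe-resorted with a stable sort (ties
keep their order, so an already-stable profile maps to itself); the
Thorpe displacement of a sample is its original depth minus its resorted
depth, and NaNs are excluded and reinserted as gaps. N² is a centred
difference of the resorted density over a 10-m scale (one-sided at the
edges) with g = 9.81 m s⁻², ρ₀ = 1027.0 kg m⁻³, floored at 10⁻⁷ s⁻²
(flagged) to keep K_ρ bounded in near-homogeneous water. The mixed-layer
depth is the shallowest depth where σ_θ exceeds the uppermost observation
by 0.03 kg m⁻³, linearly interpolated between the bracketing samples; if
the criterion is never met, the deepest depth is returned with a flag.
K_ρ = 0.2 ε/N² is masked inside the mixed layer (where the production–
dissipation balance behind the Osborn relation fails), where ε was
rejected, and where N² sits at the floor, each with a recorded reason.

All profiles use depth in metres, positive downward, ordered surface to
bottom. The flux law F = −K ∂C/∂z is stated for z positive upward; the
implementation converts once, so an upward (euphotic-zone-feeding) flux
is F = +K ∂C/∂(depth) > 0 when concentration increases downward.

## Nutrient reconstruction and calibration

Bottle nutrient sampling is far too sparse to map a section, so nitrate
and phosphate are reconstructed from potential temperature through linear
regressions fitted where θ > 15 °C (the warm upper layer, roughly the top
400 m). Ordinary least squares with Student-*t* 95 % confidence
half-widths is used throughout; the shipped registry carries the pooled
coefficients (nitrate −0.540 θ + 14.077, phosphate −0.032 θ + 0.819) and
separate ridge-station (L4) overrides, each with a 15–27 °C validity
range. Prediction outside the validity range yields a masked value, never
an extrapolation; negative predictions (possible in warm, depleted
surface water) are clipped to zero and flagged. When the pipeline fits
its own pooled model from bottles, zero concentrations are excluded from
the fit: they are censored values at the detection/clipping floor, and
leaving them in demonstrably flattens the slope.

Chlorophyll comes from profiler fluorescence through two affine stages —
profiler→reference (CTD) fluorescence, then reference
fluorescence→bottle chlorophyll — each an OLS fit on co-located samples
at or below 100 m, where daytime non-photochemical quenching no longer
suppresses fluorescence yield. The composition is itself affine and the
implementation guarantees chained application equals the composed map to
machine precision. Bottles are matched to profile depths within 2 m.

Because both fluorescence channels carry noise, OLS slope estimates are
attenuated by the classical errors-in-variables factor
1/(1 + σ_x²/var(x)); at the default noise this is a ~1 % effect, smaller
than the confidence intervals at survey sample sizes, and no correction
is applied (matching standard practice for these calibrations).

## Budget

With the flux F (mmol m⁻² d⁻¹) at the 100-m euphotic-zone base —
evaluated at the horizon, not a maximum search; a ±10-m window maximum is
available as an option — the budget module forms:

* new production M_c·r·F/1000 g C m⁻² d⁻¹, r = 106/16 (N) or 106/1 (P),
  M_c = 12 g mol⁻¹;
* the steady-state chlorophyll depletion rate
  γ = M_c r_C-N F/(r_C-Chl h_e C̄), reported at both ends of the
  pico-phytoplankton carbon-to-chlorophyll range r_C-Chl = 25–52 g C
  (g Chl)⁻¹, with h_e = 100 m and C̄ = 0.4 mg m⁻³ by default (the
  pipeline can substitute the measured 0–100 m mean of calibrated
  chlorophyll);
* the f-ratio-modified rate γ/0.5, accounting for regenerated production;
* the tidal excursion L_e = U_K1/ω_K1 (0.5 m s⁻¹, 7.3×10⁻⁵ rad s⁻¹ →
  ≈6.85 km) and L_e/W over the topographic half-width range 10–20 km.

Flux uncertainty is propagated from the 95 % half-width of the nutrient
regression slope only: the reconstructed gradient, hence the flux, is
linear in the slope, so the relative uncertainties are equal. Sampling
variability of ε is deliberately not folded in. Production and γ
uncertainties inherit the same relative half-width. The 86400 s→day
factor is applied exactly once, at flux assembly; mmol→mg C conversion
via M_c and mg→g at output.

Evaluating γ from the rounded headline inputs (F = 4.7, C̄ = 0.4,
h_e = 100, r_C-Chl = 25/52) gives 0.374 and 0.180 d⁻¹; published
presentations of this budget quote 0.33 and 0.16 d⁻¹ from unrounded
intermediates. The two agree within the quoted ±0.13/±0.06, and the
implementation reports the formula's value rather than tuning constants
to reproduce rounded digits.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure each stage consumes:
shear records synthesized block-wise (4-s blocks) from independent
zero-mean Gaussian spectral amplitudes whose variance follows the Nasmyth
spectrum at the local prescribed ε and ν, so expected spectra track the
truth profile; density built by integrating the prescribed N²(z) below a
uniform mixed layer, with overturns injected as local permutations of the
stable profile (resorting recovers the stable profile exactly);
temperature with a uniform mixed layer and a constant lapse of
0.03 °C m⁻¹ below it (27 °C at the surface puts the 15 °C validity limit
near 440 m, as observed); bottles on the stated linear θ–nutrient
relations plus independent Gaussian noise, clipped at zero; fluorescence
from a chlorophyll profile (subsurface maximum at 50 m over a 100-m
e-folding background; 0–100-m mean ≈ 0.4 mg m⁻³) through the inverted
calibration chain, with an optional near-surface quenching suppression.
The default section places a Gaussian-in-depth dissipation enhancement
(peak 10⁻⁷ W kg⁻¹ at 120 m, 80-m scale, over a 10⁻⁹ background) at one
"ridge" station.

Everything is a deterministic function of (seed, config, station): the
same seed reproduces bit-identical serialized outputs.

Not emulated: internal-wave dynamics or tidal-cycle time dependence,
instrument spike/vibration noise (spectra are clean, so the QC exercises
shape consistency rather than despiking), salinity effects on viscosity,
and any nonlinear nutrient–temperature structure. Passing recovery tests
therefore demonstrate the correctness of the estimators under their own
statistical assumptions, not robustness to real-instrument artifacts.

## Problem sizes and numerical choices

The test suite and acceptance script run desk-scale problems: 20–60-s
single-probe records (the estimator is bin-wise, so record length only
sets the number of bins), 50 seeds per dissipation decade, 3-station
sections at 300-m depth with one cast per station for end-to-end checks,
500-fit Monte-Carlo for confidence-interval coverage. Recovery on these
sizes: median dissipation within ~15 % of truth at every decade
(well inside the factor-2 acceptance band; the largest deviation is at
10⁻¹⁰ W kg⁻¹ where the 1-cpm integration floor excludes the most
variance), and the end-to-end 100-m nitrate flux within ~20 % of the
analytic truth Γ ε N⁻² × slope × dθ/dz (dominated by per-bin ε sampling
scatter at one cast × one probe; the survey-scale configuration of two
casts × two probes halves it).

Ties in resorting are broken by stable order; flux-at-depth takes the
nearest finite bin to the horizon; gradients are centred differences with
optional 10-m boxcar pre-smoothing, NaN-aware; degenerate inputs (short
records, <3 regression points, zero predictor variance, empty registries,
overturns outside the depth range) raise with diagnostics rather than
propagating silently.

## Known limitations

* The Osborn Γ = 0.2 and the N² floor are constants of convenience;
  both are configurable but no attempt is made to model variable mixing
  efficiency.
* The regression registry treats station scope as an exact label match;
  pooling is unweighted across stations.
* Thorpe-scale-based dissipation (an alternative to shear spectra) and
  thermistor microstructure are out of scope.
* The CSV interchange stores full double precision and is therefore
  bulky for raw shear records; it is chosen for inspectability, not
  efficiency.
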