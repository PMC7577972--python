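"""Synthetic cruise-data generator with known ground truth.

Emulates the three observation streams of a ridge-section microstructure
survey at desk scale: free-fall shear records whose wavenumber spectra
follow the Nasmyth form for a prescribed dissipation profile eps(z);
CTD-style hydrographic profiles with a density-uniform mixed layer,
prescribed stratification N^2(z) and injected overturns; and discrete
bottle samples obeying linear potential-temperature--nutrient relations
plus Gaussian noise, with fluorescence tied to a known chlorophyll
profile through the two-stage affine calibration chain.

Every observable is a deterministic function of (seed, config, station),
so each downstream processing stage has a parameter-recovery test against
the stored truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

from .microstructure import (GRAVITY, RHO_0, ShearRecord, kinematic_viscosity,
                             _nasmyth_shape)

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "HydroProfile",
    "BottleSet",
    "ridge_section_epsilon",
    "station_truth",
    "generate_shear_record",
    "generate_hydro_profile",
    "generate_bottles",
]

# Paper-grade pooled theta->nutrient regressions used as generator truth
DEFAULT_NUTRIENT_COEFFS = {
    "nitrate": (-0.540, 14.077),    # mmol m^-3 per degC, mmol m^-3
    "phosphate": (-0.032, 0.819),
}

# Two-stage fluorescence calibration: Flu_ref = a1*Flu_probe + b1,
# Chl = a2*Flu_ref + b2
DEFAULT_CALIBRATION = ((1.42, 0.10), (1.11, -0.08))


def ridge_section_epsilon(peak_station: int = 2,
                          background: float = 1e-9,
                          peak: float = 1e-7,
                          peak_depth: float = 120.0,
                          depth_scale: float = 80.0) -> Callable:
    """Section-shaped dissipation truth: one station sits over the ridge.

    Returns eps(depth, station): ``background`` everywhere, plus a
    Gaussian-in-depth enhancement up to ``peak`` at the ridge station.
    """
    def eps(z, station=0):
        z = np.asarray(z, dtype=float)
        base = np.full_like(z, background)
        if station == peak_station:
            base = base + peak * np.exp(-((z - peak_depth) / depth_scale) ** 2)
        return base
    return eps


def _eval_truth(fn: Callable, z, station: int):
    """Call a truth function that takes (z) or (z, station)."""
    try:
        return np.asarray(fn(z, station), dtype=float)
    except TypeError:
        return np.asarray(fn(z), dtype=float)


@dataclass
class SyntheticConfig:
    """Ground-truth parameters for a synthetic ridge section.

    Defaults mirror the surveyed conditions: 512 Hz shear sampling at a
    0.6 m s^-1 fall speed, a ~40 m wintertime mixed layer, pooled nutrient
    regressions, bottle depths to 400 m, and a dissipation section peaking
    over a mid-section ridge within the 1e-10..1e-6 W kg^-1 range.
    """

    seed: int = 0
    n_stations: int = 5
    depth_max: float = 500.0                     # m
    dz: float = 1.0                              # CTD grid spacing, m
    epsilon_truth: Callable = field(default_factory=ridge_section_epsilon)
    N2_truth: Callable = field(default_factory=lambda: (lambda z: np.full_like(np.asarray(z, float), 1e-5)))
    mld_truth: float = 40.0                      # m
    sigma_surface: float = 23.0                  # kg m^-3
    theta_surface: float = 27.0                  # degC
    theta_lapse: float = 0.03                    # degC per m below the mixed layer
    nutrient_coeffs: dict = field(default_factory=lambda: dict(DEFAULT_NUTRIENT_COEFFS))
    calibration: tuple = DEFAULT_CALIBRATION
    noise_sd: dict = field(default_factory=lambda: {
        "sigma": 0.002,          # kg m^-3
        "theta": 0.005,          # degC
        "nitrate": 0.1,          # mmol m^-3
        "phosphate": 0.01,       # mmol m^-3
        "chl": 0.02,             # mg m^-3
        "fluorescence": 0.002,   # fluorescence units
    })
    fall_speed: float = 0.6                      # m s^-1
    sample_rate: float = 512.0                   # Hz
    overturn_spec: Sequence[tuple[float, float]] = ((150.0, 20.0),)
    bottle_depths: Sequence[float] = (0.0, 50.0, 100.0, 200.0, 300.0, 400.0)
    chl_background: float = 0.02                 # mg m^-3 abyssal floor
    chl_max: float = 0.4                         # mg m^-3 subsurface maximum
    chl_peak_depth: float = 50.0                 # m
    chl_width: float = 35.0                      # m
    chl_upper: float = 0.2                       # mg m^-3 decaying upper-ocean part
    chl_decay: float = 100.0                     # m e-folding of the upper part
    nu_constant: float | None = None             # fixed viscosity for tests
    quench: bool = False                         # suppress near-surface fluorescence
    record_seconds: float | None = None          # shear record length; None = full depth

    def validate(self):
        if self.mld_truth >= self.depth_max:
            raise ValueError("mld_truth must be shallower than depth_max")
        z = np.linspace(0.0, self.depth_max, 64)
        for s in range(self.n_stations):
            eps = _eval_truth(self.epsilon_truth, z, s)
            if np.any(eps <= 0):
                raise ValueError("epsilon_truth must be strictly positive everywhere")
        if np.any(_eval_truth(self.N2_truth, z, 0) < 0):
            raise ValueError("N2_truth must be non-negative")
        for c, ext in self.overturn_spec:
            if c - ext / 2 < 0 or c + ext / 2 > self.depth_max:
                raise ValueError("overturn extent exceeds the depth range")
        return self


@dataclass
class TruthRecord:
    """Per-station ground truth behind the generated observables."""

    station: int
    depth: np.ndarray
    epsilon: np.ndarray          # W kg^-1
    n2: np.ndarray               # s^-2
    mld: float                   # m
    theta: np.ndarray            # degC, noise-free
    sigma_stable: np.ndarray     # kg m^-3, stable (pre-overturn, pre-noise)
    chlorophyll: np.ndarray      # mg m^-3
    nutrient_coeffs: dict
    calibration: tuple

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "depth_m": self.depth, "epsilon_W_kg": self.epsilon,
            "N2_s2": self.n2, "theta_C": self.theta,
            "sigma_stable_kg_m3": self.sigma_stable,
            "chl_mg_m3": self.chlorophyll,
        })


@dataclass
class HydroProfile:
    """Depth-gridded CTD-style profile (depth positive down)."""

    station: int
    depth: np.ndarray
    theta: np.ndarray            # degC
    salinity: np.ndarray         # psu
    sigma_theta: np.ndarray      # kg m^-3
    fluorescence: np.ndarray     # profiler channel, relative units
    fluorescence_ref: np.ndarray | None = None  # reference (CTD) channel


@dataclass
class BottleSet:
    """Discrete bottle samples with matched potential temperature."""

    station: int
    depth: np.ndarray            # m
    theta: np.ndarray            # degC
    nitrate: np.ndarray          # mmol m^-3
    phosphate: np.ndarray        # mmol m^-3
    chlorophyll: np.ndarray      # mg m^-3


def _rng(config: SyntheticConfig, station: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, station, stream])


def _theta_profile(config: SyntheticConfig, z: np.ndarray) -> np.ndarray:
    theta = np.full_like(z, config.theta_surface)
    below = z > config.mld_truth
    theta[below] = config.theta_surface - config.theta_lapse * (z[below] - config.mld_truth)
    return np.maximum(theta, 2.0)


def _chl_profile(config: SyntheticConfig, z: np.ndarray) -> np.ndarray:
    """Subsurface maximum over a gradually decaying upper-ocean profile.

    The slow decay keeps deep (>=100 m) samples informative for the
    fluorescence calibration; the euphotic-zone (0-100 m) mean of the
    default profile is ~0.4 mg m^-3.
    """
    return (config.chl_background
            + config.chl_max * np.exp(-((z - config.chl_peak_depth)
                                        / config.chl_width) ** 2)
            + config.chl_upper * np.exp(-z / config.chl_decay))


def station_truth(config: SyntheticConfig, station: int) -> TruthRecord:
    """Ground truth on the CTD depth grid for one station."""
    config.validate()
    z = np.arange(0.0, config.depth_max + config.dz / 2, config.dz)
    eps = _eval_truth(config.epsilon_truth, z, station)
    n2 = _eval_truth(config.N2_truth, z, station)

    # stable sigma_theta: uniform above the mixed layer, then integrate
    # d(sigma)/dz = N^2 rho_0 / g downward from the mixed-layer base
    dsdz = np.where(z > config.mld_truth, n2 * RHO_0 / GRAVITY, 0.0)
    sigma = config.sigma_surface + np.concatenate(
        ([0.0], np.cumsum(0.5 * (dsdz[1:] + dsdz[:-1]) * np.diff(z))))
    return TruthRecord(station=station, depth=z, epsilon=eps, n2=n2,
                       mld=config.mld_truth, theta=_theta_profile(config, z),
                       sigma_stable=sigma, chlorophyll=_chl_profile(config, z),
                       nutrient_coeffs=dict(config.nutrient_coeffs),
                       calibration=config.calibration)


# ---------------------------------------------------------------------------
# shear records


def _synthesize_block(rng, n, fs, fall_speed, epsilon, nu):
    """One shear block whose expected one-sided spectrum is Nasmyth.

    Independent zero-mean Gaussian spectral amplitudes with variance
    proportional to the model spectrum, inverse-transformed to the time
    domain.
    """
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    k = f / fall_speed
    psd_f = np.zeros_like(f)
    ks = (epsilon / nu ** 3) ** 0.25
    pos = k > 0
    # Phi(f) = Phi(k)/W_fall
    psd_f[pos] = (epsilon ** 3 / nu) ** 0.25 * _nasmyth_shape(k[pos] / ks) / fall_speed
    scale = np.sqrt(psd_f * fs * n / 4.0)
    amp = scale * (rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size))
    amp[0] = 0.0
    if n % 2 == 0:
        amp[-1] = np.sqrt(2.0) * scale[-1] * rng.standard_normal()
    return np.fft.irfft(amp, n=n)


def generate_shear_record(config: SyntheticConfig, station: int,
                          cast: int = 0, n_probes: int = 2,
                          block_seconds: float = 4.0) -> ShearRecord:
    """Free-fall shear record for one cast at one station.

    The profiler descends at ``config.fall_speed`` from the surface; the
    record is synthesized in ``block_seconds`` blocks, each drawn from the
    Nasmyth spectrum at the local eps_truth and temperature-derived
    viscosity, so the expected spectrum tracks the prescribed dissipation
    profile. Probes are independent realizations.
    """
    config.validate()
    fs, w = config.sample_rate, config.fall_speed
    total_seconds = (config.record_seconds if config.record_seconds is not None
                     else config.depth_max / w)
    n_block = int(round(block_seconds * fs))
    n_blocks = max(1, int(np.ceil(total_seconds * fs / n_block)))
    n = n_blocks * n_block
    t = np.arange(n) / fs
    depth = t * w
    theta = _theta_profile(config, depth)
    rng = _rng(config, station, 1000 + cast)

    shear = np.empty((n, n_probes))
    for p in range(n_probes):
        for b in range(n_blocks):
            sl = slice(b * n_block, (b + 1) * n_block)
            z_mid = float(np.mean(depth[sl]))
            eps = float(_eval_truth(config.epsilon_truth, np.array([z_mid]), station)[0])
            if eps <= 0:
                raise ValueError(f"epsilon_truth non-positive at depth {z_mid:.1f} m")
            nu = (config.nu_constant if config.nu_constant is not None
                  else float(kinematic_viscosity(theta[sl].mean())))
            shear[sl, p] = _synthesize_block(rng, n_block, fs, w, eps, nu)

    return ShearRecord(time=t, shear=shear, depth=depth, temperature=theta,
                       fall_speed=w, sample_rate=fs, station=f"L{station + 1}",
                       cast=cast, nu_constant=config.nu_constant)


# ---------------------------------------------------------------------------
# hydrography and bottles


def generate_hydro_profile(config: SyntheticConfig, station: int) -> HydroProfile:
    """CTD-style profile with noise and injected overturns.

    Overturn segments are local permutations of the stable profile, so
    Thorpe resorting recovers the stable profile exactly (same multiset).
    """
    truth = station_truth(config, station)
    z = truth.depth
    rng = _rng(config, station, 2000)
    sigma = truth.sigma_stable + rng.normal(0.0, config.noise_sd["sigma"], z.size)
    theta = truth.theta + rng.normal(0.0, config.noise_sd["theta"], z.size)

    for center, extent in config.overturn_spec:
        inwin = np.nonzero(np.abs(z - center) <= extent / 2)[0]
        if inwin.size > 1:
            sigma[inwin] = sigma[inwin][rng.permutation(inwin.size)]

    (a1, b1), (a2, b2) = config.calibration
    flu_ref_truth = (truth.chlorophyll - b2) / a2
    flu_tm_truth = (flu_ref_truth - b1) / a1
    sd_f = config.noise_sd["fluorescence"]
    flu = flu_tm_truth + rng.normal(0.0, sd_f, z.size)
    flu_ref = flu_ref_truth + rng.normal(0.0, sd_f, z.size)
    if config.quench:
        # daytime non-photochemical quenching: suppressed fluorescence yield
        # shallower than ~60 m
        supp = np.where(z < 60.0, 0.7, 1.0)
        flu = flu * supp
        flu_ref = flu_ref * supp

    salinity = 34.5 + 0.1 * np.tanh((z - config.mld_truth) / 100.0)
    return HydroProfile(station=station, depth=z, theta=theta,
                        salinity=salinity, sigma_theta=sigma, fluorescence=flu,
                        fluorescence_ref=flu_ref)


def _inverse_calibration(chl: np.ndarray, calibration) -> np.ndarray:
    (a1, b1), (a2, b2) = calibration
    flu_ref = (chl - b2) / a2
    return (flu_ref - b1) / a1


def generate_bottles(config: SyntheticConfig, station: int,
                     hydro: HydroProfile | None = None) -> BottleSet:
    """Discrete bottle samples at the configured depths.

    Nutrients follow slope * theta + intercept plus Gaussian noise,
    clipped at zero; chlorophyll comes from the truth profile plus noise.
    """
    config.validate()
    truth = station_truth(config, station)
    depths = np.asarray(config.bottle_depths, dtype=float)
    theta = np.interp(depths, truth.depth, truth.theta)
    rng = _rng(config, station, 3000)

    def sample(species):
        slope, intercept = config.nutrient_coeffs[species]
        sd = config.noise_sd.get(species, config.noise_sd.get("nutrient", 0.1))
        c = slope * theta + intercept + rng.normal(0.0, sd, depths.size)
        return np.maximum(c, 0.0)

    nitrate = sample("nitrate")
    phosphate = sample("phosphate")
    chl = np.maximum(np.interp(depths, truth.depth, truth.chlorophyll)
                     + rng.normal(0.0, config.noise_sd["chl"], depths.size), 0.0)
    return BottleSet(station=station, depth=depths, theta=theta,
                     nitrate=nitrate, phosphate=phosphate, chlorophyll=chl)
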