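"""Microstructure shear processing: dissipation, stratification and mixing.

Turns free-fall shear-probe records into depth-binned turbulent kinetic
energy dissipation rates via spectral integration against the empirical
Nasmyth reference spectrum, resorts potential-density profiles (Thorpe
resorting) to obtain the buoyancy frequency, detects the surface mixed
layer, and combines the two into the Osborn eddy diffusivity
K_rho = Gamma * epsilon / N^2 with constant mixing efficiency Gamma = 0.2.

Conventions: depth in metres, positive downward, profiles ordered
surface -> bottom. Wavenumbers are cyclic (cpm). All spectra are
one-sided densities in s^-2 cpm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "GRAVITY",
    "RHO_0",
    "MIXING_EFFICIENCY",
    "MLD_DENSITY_THRESHOLD",
    "ShearRecord",
    "ShearSegment",
    "ShearSpectrum",
    "DissipationProfile",
    "StratificationProfile",
    "DiffusivityProfile",
    "kinematic_viscosity",
    "segment_shear",
    "shear_spectrum",
    "nasmyth_spectrum",
    "nasmyth_resolved_fraction",
    "estimate_epsilon",
    "dissipation_profile",
    "combine_probes_and_casts",
    "thorpe_resort",
    "buoyancy_frequency",
    "mixed_layer_depth",
    "osborn_diffusivity",
]

GRAVITY = 9.81          # m s^-2
RHO_0 = 1027.0          # kg m^-3, reference density
MIXING_EFFICIENCY = 0.2  # Osborn's Gamma
MLD_DENSITY_THRESHOLD = 0.03  # kg m^-3 deviation from uppermost sigma_theta

# epsilon = SHEAR_VARIANCE_FACTOR * nu * <(du'/dz)^2> under isotropy
SHEAR_VARIANCE_FACTOR = 7.5


def kinematic_viscosity(temperature_c):
    """Kinematic viscosity of seawater, m^2 s^-1, from temperature in deg C.

    Temperature-only fit (salinity dependence is a ~1% effect at oceanic
    salinities); gives 1.00e-6 at 20 degC and 1.35e-6 at 10 degC.
    """
    t = np.asarray(temperature_c, dtype=float)
    return 1.792e-6 / (1.0 + 0.0337 * t + 0.000221 * t * t)


# ---------------------------------------------------------------------------
# containers


@dataclass
class ShearRecord:
    """Raw free-fall microstructure shear time series.

    ``shear`` has shape (n_samples, n_probes) with up to two probes.
    ``depth`` and ``temperature`` are per-sample tracks.
    """

    time: np.ndarray            # s
    shear: np.ndarray           # s^-1, (n, n_probes)
    depth: np.ndarray           # m, increasing
    temperature: np.ndarray     # degC
    fall_speed: float           # m s^-1
    sample_rate: float          # Hz
    station: str = ""
    cast: int = 0
    instrument: str = "TM"
    nu_constant: float | None = None  # override viscosity for tests

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.shear = np.atleast_2d(np.asarray(self.shear, dtype=float))
        if self.shear.shape[0] != self.time.size:
            self.shear = self.shear.T
        self.depth = np.asarray(self.depth, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.fall_speed <= 0:
            raise ValueError("fall_speed must be positive")
        d = np.diff(self.depth)
        if d.size and not np.all(d >= 0):
            raise ValueError("depth must be monotonically increasing along the record")

    @property
    def n_probes(self) -> int:
        return self.shear.shape[1]


@dataclass
class ShearSegment:
    """Detrended analysis segment of a single probe's shear series."""

    shear: np.ndarray           # detrended, s^-1
    sample_rate: float
    fall_speed: float
    depth_center: float         # m
    depth_span: tuple[float, float]
    nu: float                   # m^2 s^-1 at the segment's mean temperature
    probe: int = 0


@dataclass
class ShearSpectrum:
    """One-sided wavenumber spectrum of a shear segment."""

    k: np.ndarray               # cpm
    phi: np.ndarray             # s^-2 cpm^-1
    nu: float
    depth_center: float
    depth_span: tuple[float, float]
    variance: float             # windowed-corrected time-domain variance, s^-2
    probe: int = 0


@dataclass
class DissipationProfile:
    """Depth-binned dissipation with QC flags.

    ``flag`` is "accepted" or "rejected"; rejected bins hold NaN epsilon,
    never zero.
    """

    depth: np.ndarray           # bin centres, m
    epsilon: np.ndarray         # W kg^-1, NaN where rejected
    nu: np.ndarray              # m^2 s^-1
    flag: np.ndarray            # str per bin
    station: str = ""
    per_probe: list = field(default_factory=list)


@dataclass
class StratificationProfile:
    depth: np.ndarray           # m
    sigma_observed: np.ndarray  # kg m^-3
    sigma_resorted: np.ndarray  # kg m^-3, non-decreasing
    thorpe_displacement: np.ndarray  # m
    n2: np.ndarray | None = None     # s^-2
    n2_flag: np.ndarray | None = None
    mld: float | None = None    # m
    station: str = ""


@dataclass
class DiffusivityProfile:
    depth: np.ndarray
    k_rho: np.ndarray           # m^2 s^-1, NaN where masked
    gamma: float
    mask_reason: np.ndarray     # "" | "mixed-layer" | "rejected-eps" | "n2-floor"
    station: str = ""


# ---------------------------------------------------------------------------
# segmentation and spectra


def segment_shear(record: ShearRecord, segment_seconds: float = 4.0,
                  overlap_fraction: float = 0.5) -> list[ShearSegment]:
    """Split a shear record into detrended, half-overlapping segments.

    Each segment is tagged with its mean depth and viscosity from the
    mean in-segment temperature. Segments are produced per probe.
    """
    nseg = int(round(segment_seconds * record.sample_rate))
    if nseg < 256:
        raise ValueError("segment must contain at least 256 samples")
    n = record.time.size
    if n < nseg:
        raise ValueError(
            f"record of {n} samples shorter than one segment ({nseg} samples)")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    step = max(1, int(round(nseg * (1.0 - overlap_fraction))))
    starts = list(range(0, n - nseg + 1, step))
    # cover the record tail so every sample belongs to >= 1 segment
    if starts[-1] + nseg < n:
        starts.append(n - nseg)

    segments: list[ShearSegment] = []
    for probe in range(record.n_probes):
        for s in starts:
            sl = slice(s, s + nseg)
            x = signal.detrend(record.shear[sl, probe])
            t_mean = float(np.mean(record.temperature[sl]))
            nu = (record.nu_constant if record.nu_constant is not None
                  else float(kinematic_viscosity(t_mean)))
            d = record.depth[sl]
            segments.append(ShearSegment(
                shear=x, sample_rate=record.sample_rate,
                fall_speed=record.fall_speed,
                depth_center=float(np.mean(d)),
                depth_span=(float(d[0]), float(d[-1])),
                nu=nu, probe=probe))
    return segments


def shear_spectrum(segment: ShearSegment, window: str = "hann") -> ShearSpectrum:
    """One-sided wavenumber spectrum of a segment (Taylor frozen field).

    The frequency spectrum of the windowed, power-corrected segment is
    mapped to wavenumber with k = f / W_fall and Phi(k) = Phi(f) * W_fall,
    so that integral(Phi dk) equals the windowed-corrected variance of the
    detrended segment (discrete Parseval).
    """
    if segment.fall_speed <= 0:
        raise ValueError("fall speed must be positive")
    x = segment.shear
    f, pxx = signal.periodogram(x, fs=segment.sample_rate, window=window,
                                detrend=False, scaling="density")
    # drop the zero wavenumber
    f, pxx = f[1:], pxx[1:]
    k = f / segment.fall_speed
    phi = pxx * segment.fall_speed
    w = signal.get_window(window, x.size)
    variance = float(np.sum((w * x) ** 2) / np.sum(w ** 2))
    return ShearSpectrum(k=k, phi=phi, nu=segment.nu,
                         depth_center=segment.depth_center,
                         depth_span=segment.depth_span,
                         variance=variance, probe=segment.probe)


# ---------------------------------------------------------------------------
# Nasmyth reference spectrum

# Closed-form empirical fit in x = k / k_s with k_s = (eps/nu^3)^(1/4) cpm;
# the constants make 7.5 * integral equal 1 (i.e. integral = 2/15).
_NASMYTH_A = 8.05
_NASMYTH_B = 20.6
_NASMYTH_P = 3.715


def _nasmyth_shape(x):
    x = np.asarray(x, dtype=float)
    return _NASMYTH_A * np.cbrt(x) / (1.0 + (_NASMYTH_B * x) ** _NASMYTH_P)


# cumulative variance fraction of the fit, precomputed once
_XGRID = np.logspace(-6.0, 1.5, 3000)
_CUM = cumulative_trapezoid(_nasmyth_shape(_XGRID), _XGRID, initial=0.0)
_CUM /= _CUM[-1]


def _cumulative_fraction(x):
    """Fraction of Nasmyth shear variance at nondimensional wavenumbers < x."""
    x = np.asarray(x, dtype=float)
    return np.interp(x, _XGRID, _CUM, left=0.0, right=1.0)


def _x_at_fraction(frac: float) -> float:
    return float(np.interp(frac, _CUM, _XGRID))


def nasmyth_spectrum(epsilon: float, nu: float, k) -> np.ndarray:
    """Nasmyth shear spectrum Phi_N(k) in s^-2 cpm^-1 for k in cpm.

    Dimensionalized by the Kolmogorov wavenumber k_s = (eps/nu^3)^(1/4)
    so that 7.5 * nu * integral(Phi_N dk) = epsilon.
    """
    k = np.asarray(k, dtype=float)
    if epsilon <= 0 or nu <= 0:
        raise ValueError("epsilon and nu must be positive")
    if np.any(k <= 0):
        raise ValueError("wavenumbers must be positive")
    ks = (epsilon / nu ** 3) ** 0.25
    return (epsilon ** 3 / nu) ** 0.25 * _nasmyth_shape(k / ks)


def nasmyth_resolved_fraction(epsilon: float, nu: float,
                              k_lo: float, k_hi: float) -> float:
    """Fraction of total Nasmyth shear variance inside [k_lo, k_hi] (cpm)."""
    ks = (epsilon / nu ** 3) ** 0.25
    return float(_cumulative_fraction(k_hi / ks) - _cumulative_fraction(k_lo / ks))


# ---------------------------------------------------------------------------
# dissipation estimation


def estimate_epsilon(spectrum: ShearSpectrum, k_min: float = 1.0,
                     resolved_target: float = 0.9,
                     qc_log_ratio: float = np.log10(3.0),
                     max_iter: int = 50,
                     rtol: float = 0.01) -> tuple[float, str]:
    """Estimate epsilon by iterative spectral integration.

    Integrates the observed spectrum from ``k_min`` up to a cutoff, forms
    eps = 7.5 nu var, then refines the cutoff from the Nasmyth spectrum of
    the current estimate (wavenumber resolving ``resolved_target`` of the
    model variance, capped by the observed band) and adds back the model
    variance fraction outside the integration band, iterating to
    convergence (< ``rtol`` relative change).

    QC replaces the traditional visual spectral check: the segment is
    accepted when mean |log10(Phi_obs / Phi_N)| over the integration band
    is below ``qc_log_ratio``. Returns ``(epsilon, flag)`` with flag
    "accepted" or "rejected"; a rejected estimate is still returned for
    diagnostics.
    """
    k, phi, nu = spectrum.k, spectrum.phi, spectrum.nu
    k_max = float(k[-1])
    k_cut = k_max
    eps = np.nan
    for _ in range(max_iter):
        band = (k >= k_min) & (k <= k_cut)
        if band.sum() < 4:
            return np.nan, "rejected"
        var_obs = float(np.trapezoid(phi[band], k[band]))
        eps_new = SHEAR_VARIANCE_FACTOR * nu * var_obs
        if eps_new <= 0:
            return np.nan, "rejected"
        # add unresolved model variance outside [k_min, k_cut]
        frac = nasmyth_resolved_fraction(eps_new, nu, k_min, k_cut)
        frac = max(frac, 0.05)
        eps_new = eps_new / frac
        ks = (eps_new / nu ** 3) ** 0.25
        k_cut = min(_x_at_fraction(resolved_target) * ks, k_max)
        k_cut = max(k_cut, 2.0 * k_min)
        if np.isfinite(eps) and abs(eps_new - eps) <= rtol * eps:
            eps = eps_new
            break
        eps = eps_new
    else:
        return eps, "rejected"

    # spectral-consistency QC. The band extends past the integration
    # cutoff into the Nasmyth roll-off (up to k = 0.5 k_s) when resolved:
    # the roll-off is what discriminates turbulence from broadband noise,
    # which can mimic the near-flat inertial subrange over a narrow band.
    ks = (eps / nu ** 3) ** 0.25
    k_qc = min(k_max, max(k_cut, 0.5 * ks))
    band = (k >= k_min) & (k <= k_qc) & (phi > 0)
    if band.sum() < 4:
        return eps, "rejected"
    model = nasmyth_spectrum(eps, nu, k[band])
    mis = float(np.mean(np.abs(np.log10(phi[band] / model))))
    return eps, ("accepted" if mis < qc_log_ratio else "rejected")


def dissipation_profile(record: ShearRecord, segment_seconds: float = 4.0,
                        overlap_fraction: float = 0.5, bin_size: float = 5.0,
                        k_min: float = 1.0,
                        qc_log_ratio: float = np.log10(3.0),
                        probe_disagreement_factor: float = 10.0,
                        ) -> DissipationProfile:
    """Depth-binned dissipation profile from one record (all probes).

    Per-probe segment estimates are averaged within ``bin_size`` depth
    bins; the per-probe bin values are then combined by their mean, except
    that when two probes disagree by more than
    ``probe_disagreement_factor`` the smaller value is kept (probe
    contamination raises, not lowers, apparent variance).
    """
    segments = segment_shear(record, segment_seconds, overlap_fraction)
    results = []
    for seg in segments:
        spec = shear_spectrum(seg)
        eps, flag = estimate_epsilon(spec, k_min=k_min, qc_log_ratio=qc_log_ratio)
        results.append((seg.probe, seg.depth_center, seg.nu, eps, flag))

    d_lo = float(record.depth[0])
    d_hi = float(record.depth[-1])
    edges = np.arange(np.floor(d_lo / bin_size) * bin_size,
                      d_hi + bin_size, bin_size)
    centers = 0.5 * (edges[:-1] + edges[1:])

    per_probe = np.full((record.n_probes, centers.size), np.nan)
    nu_bin = np.full(centers.size, np.nan)
    for p in range(record.n_probes):
        for i in range(centers.size):
            vals = [eps for (pr, d, nu, eps, fl) in results
                    if pr == p and edges[i] <= d < edges[i + 1]
                    and fl == "accepted" and np.isfinite(eps)]
            nus = [nu for (pr, d, nu, eps, fl) in results
                   if pr == p and edges[i] <= d < edges[i + 1]]
            if vals:
                per_probe[p, i] = np.mean(vals)
            if nus and np.isnan(nu_bin[i]):
                nu_bin[i] = np.mean(nus)

    eps_bin = np.full(centers.size, np.nan)
    for i in range(centers.size):
        vals = per_probe[:, i]
        ok = np.isfinite(vals)
        if not ok.any():
            continue
        v = vals[ok]
        if v.size == 2 and max(v) > probe_disagreement_factor * min(v):
            eps_bin[i] = min(v)
        else:
            eps_bin[i] = v.mean()
    flag = np.where(np.isfinite(eps_bin), "accepted", "rejected")
    return DissipationProfile(depth=centers, epsilon=eps_bin, nu=nu_bin,
                              flag=flag.astype(object), station=record.station,
                              per_probe=[per_probe[p] for p in range(record.n_probes)])


def combine_probes_and_casts(profiles: Sequence[DissipationProfile]
                             ) -> DissipationProfile:
    """Average several dissipation profiles on a common depth grid.

    Per-bin mean over the accepted members; a bin with every member
    rejected stays missing (NaN).
    """
    if not profiles:
        raise ValueError("need at least one profile")
    depth = profiles[0].depth
    for p in profiles[1:]:
        if p.depth.size != depth.size or not np.allclose(p.depth, depth):
            raise ValueError("profiles must share a common depth grid")
    def masked_mean(stack):
        cnt = np.sum(np.isfinite(stack), axis=0)
        return np.where(cnt > 0, np.nansum(stack, axis=0) / np.maximum(cnt, 1),
                        np.nan)

    eps = masked_mean(np.vstack([p.epsilon for p in profiles]))
    nu = masked_mean(np.vstack([p.nu for p in profiles]))
    flag = np.where(np.isfinite(eps), "accepted", "rejected")
    return DissipationProfile(depth=depth.copy(), epsilon=eps, nu=nu,
                              flag=flag.astype(object),
                              station=profiles[0].station)


# ---------------------------------------------------------------------------
# stratification


def thorpe_resort(depth, sigma, station: str = "") -> StratificationProfile:
    """Resort a potential-density profile into stable (non-decreasing) order.

    Stable sort; Thorpe displacement is the original depth of each sample
    minus the depth it lands at after resorting. NaNs are excluded from
    the sort and reinserted as gaps.
    """
    depth = np.asarray(depth, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if depth.shape != sigma.shape:
        raise ValueError("depth and sigma must have the same shape")
    resorted = np.full_like(sigma, np.nan)
    disp = np.full_like(sigma, np.nan)
    ok = np.isfinite(sigma)
    order = np.argsort(sigma[ok], kind="stable")
    resorted[ok] = sigma[ok][order]
    d_ok = depth[ok]
    disp[ok] = d_ok[order] - d_ok
    return StratificationProfile(depth=depth, sigma_observed=sigma,
                                 sigma_resorted=resorted,
                                 thorpe_displacement=disp, station=station)


def buoyancy_frequency(strat: StratificationProfile,
                       smoothing_scale: float = 10.0,
                       n2_floor: float = 1e-7) -> StratificationProfile:
    """Buoyancy frequency squared from the resorted density profile.

    N^2 = (g / rho_0) * d(rho_s)/d(depth) (depth positive down), via a
    centred difference across ``smoothing_scale`` metres, one-sided at the
    edges. Values below ``n2_floor`` are floored and flagged "floor".
    Fills ``strat.n2`` / ``strat.n2_flag`` in place and returns strat.
    """
    depth, rho = strat.depth, strat.sigma_resorted
    if depth.size < 3:
        raise ValueError("need at least 3 points for N^2")
    dz = float(np.median(np.diff(depth)))
    h = max(1, int(round(smoothing_scale / (2.0 * dz))))
    n = depth.size
    n2 = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - h), min(n - 1, i + h)
        if hi == lo:
            continue
        n2[i] = (GRAVITY / RHO_0) * (rho[hi] - rho[lo]) / (depth[hi] - depth[lo])
    flag = np.where(n2 < n2_floor, "floor", "ok").astype(object)
    flag[~np.isfinite(n2)] = "missing"
    n2 = np.where(np.isfinite(n2), np.maximum(n2, n2_floor), np.nan)
    strat.n2 = n2
    strat.n2_flag = flag
    return strat


def mixed_layer_depth(depth, sigma,
                      threshold: float = MLD_DENSITY_THRESHOLD
                      ) -> tuple[float, bool]:
    """Mixed-layer depth by the density-threshold criterion.

    Shallowest depth at which sigma_theta exceeds the uppermost value by
    ``threshold`` (kg m^-3), linearly interpolated between the bracketing
    samples. Returns ``(mld, reached)``; if the criterion is never met the
    deepest depth is returned with ``reached=False``.
    """
    depth = np.asarray(depth, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    ok = np.isfinite(sigma)
    depth, sigma = depth[ok], sigma[ok]
    if depth.size < 2:
        raise ValueError("profile too short for mixed-layer detection")
    dev = sigma - sigma[0]
    idx = np.nonzero(dev >= threshold)[0]
    if idx.size == 0:
        return float(depth[-1]), False
    i = idx[0]
    if i == 0:
        return float(depth[0]), True
    # linear interpolation between the bracketing points
    f = (threshold - dev[i - 1]) / (dev[i] - dev[i - 1])
    return float(depth[i - 1] + f * (depth[i] - depth[i - 1])), True


def osborn_diffusivity(dissipation: DissipationProfile,
                       strat: StratificationProfile,
                       gamma: float = MIXING_EFFICIENCY) -> DiffusivityProfile:
    """Osborn eddy diffusivity K_rho = gamma * eps / N^2.

    Masked (NaN) inside the surface mixed layer, where epsilon was
    rejected, and where N^2 sits at the floor; each masked bin carries the
    reason.
    """
    if strat.n2 is None or strat.mld is None:
        raise ValueError("stratification profile needs n2 and mld")
    n2 = np.interp(dissipation.depth, strat.depth, strat.n2)
    n2_flag = np.asarray(strat.n2_flag, dtype=object)
    # nearest flag for each dissipation bin
    idx = np.clip(np.searchsorted(strat.depth, dissipation.depth), 0,
                  strat.depth.size - 1)
    flags = n2_flag[idx]

    k_rho = np.full(dissipation.depth.size, np.nan)
    reason = np.full(dissipation.depth.size, "", dtype=object)
    for i, d in enumerate(dissipation.depth):
        if d <= strat.mld:
            reason[i] = "mixed-layer"
        elif not np.isfinite(dissipation.epsilon[i]):
            reason[i] = "rejected-eps"
        elif flags[i] == "floor" or not np.isfinite(n2[i]):
            reason[i] = "n2-floor"
        else:
            k_rho[i] = gamma * dissipation.epsilon[i] / n2[i]
    return DiffusivityProfile(depth=dissipation.depth.copy(), k_rho=k_rho,
                              gamma=gamma, mask_reason=reason,
                              station=dissipation.station)
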