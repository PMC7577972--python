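"""Nutrient reconstruction and fluorescence calibration.

Bottle nutrient data on a cruise are far too sparse to map a section, but
nitrate and phosphate correlate linearly with potential temperature in
the upper thermocline. This module fits and applies those theta->nutrient
regressions (a pooled model plus per-station overrides for anomalous
stations), with 95% Student-t confidence limits, and the two-stage affine
calibration chain that maps profiler fluorescence to reference (CTD)
fluorescence and then to bottle chlorophyll a, fitted only on samples at
or below a minimum depth to avoid daytime non-photochemical quenching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "RegressionModel",
    "CalibrationChain",
    "NutrientProfile",
    "fit_linear",
    "published_nutrient_registry",
    "published_calibration_chain",
    "select_nutrient_model",
    "nutrient_from_theta",
    "apply_calibration_chain",
    "fit_calibration_chain",
]

THETA_VALIDITY_MIN = 15.0  # degC: regressions hold in the warm upper layer


@dataclass
class RegressionModel:
    """Linear model y = slope * x + intercept with 95% confidence limits.

    ``valid_range`` bounds the predictor; prediction outside it yields a
    masked value rather than an extrapolation.
    """

    slope: float
    intercept: float
    slope_ci: float = 0.0        # 95% half-width
    intercept_ci: float = 0.0
    n: int = 0
    valid_range: tuple[float | None, float | None] = (None, None)
    label: str = ""

    def __post_init__(self):
        if self.slope_ci < 0 or self.intercept_ci < 0:
            raise ValueError("confidence half-widths must be non-negative")

    def in_range(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        ok = np.isfinite(x)
        lo, hi = self.valid_range
        if lo is not None:
            ok &= x > lo
        if hi is not None:
            ok &= x <= hi
        return ok

    def predict(self, x) -> np.ndarray:
        """Evaluate the line; NaN outside the validity range."""
        x = np.asarray(x, dtype=float)
        y = self.slope * x + self.intercept
        return np.where(self.in_range(x), y, np.nan)

    @property
    def relative_slope_uncertainty(self) -> float:
        if self.slope == 0:
            raise ZeroDivisionError("slope is zero")
        return self.slope_ci / abs(self.slope)


@dataclass
class NutrientProfile:
    """Predicted concentrations with masking/clipping provenance."""

    values: np.ndarray           # mmol m^-3, NaN where masked
    masked: np.ndarray           # bool: predictor outside validity range
    clipped: np.ndarray          # bool: negative prediction clipped to 0
    model: RegressionModel | None = None


def fit_linear(x, y, confidence: float = 0.95) -> RegressionModel:
    """Ordinary least squares with Student-t confidence half-widths."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 finite points")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, n - 2)
    return RegressionModel(slope=float(res.slope), intercept=float(res.intercept),
                           slope_ci=float(tcrit * res.stderr),
                           intercept_ci=float(tcrit * res.intercept_stderr),
                           n=n)


# ---------------------------------------------------------------------------
# nutrient models

def published_nutrient_registry() -> dict:
    """Published theta->nutrient regressions (theta valid over 15-27 degC).

    Pooled models for the section, with separate coefficients for the
    anomalous ridge station L4, whose temperature profile differs from
    the rest of the line.
    """
    rng = (THETA_VALIDITY_MIN, 27.0)
    return {
        ("nitrate", "default"): RegressionModel(-0.540, 14.077, 0.085, 1.881,
                                                valid_range=rng,
                                                label="nitrate pooled"),
        ("phosphate", "default"): RegressionModel(-0.032, 0.819, 0.006, 0.138,
                                                  valid_range=rng,
                                                  label="phosphate pooled"),
        ("nitrate", "L4"): RegressionModel(-0.939, 24.666, 0.380, 8.776,
                                           valid_range=rng,
                                           label="nitrate L4"),
        ("phosphate", "L4"): RegressionModel(-0.065, 1.720, 0.031, 0.719,
                                             valid_range=rng,
                                             label="phosphate L4"),
    }


def select_nutrient_model(station: str, species: str, registry: dict
                          ) -> RegressionModel:
    """Station-specific model when registered, else the pooled default."""
    if not registry:
        raise ValueError("empty model registry")
    if (species, station) in registry:
        return registry[(species, station)]
    try:
        return registry[(species, "default")]
    except KeyError:
        raise KeyError(f"no default model for species {species!r}") from None


def nutrient_from_theta(theta, model: RegressionModel) -> NutrientProfile:
    """Reconstruct a nutrient profile from potential temperature.

    Masked (NaN) where theta falls outside the model validity range;
    negative predictions are clipped to zero and flagged.
    """
    theta = np.asarray(theta, dtype=float)
    raw = model.predict(theta)
    masked = ~model.in_range(theta)
    clipped = np.isfinite(raw) & (raw < 0)
    values = np.where(clipped, 0.0, raw)
    return NutrientProfile(values=values, masked=masked, clipped=clipped,
                           model=model)


# ---------------------------------------------------------------------------
# fluorescence -> chlorophyll calibration


@dataclass
class CalibrationChain:
    """Two affine stages: probe flu -> reference flu -> chlorophyll a."""

    stage1: RegressionModel
    stage2: RegressionModel
    min_depth: float = 100.0     # m; shallower samples are quenching-suspect

    def composed(self) -> tuple[float, float]:
        """(slope, intercept) of the composed affine map probe flu -> chl."""
        a = self.stage2.slope * self.stage1.slope
        b = self.stage2.slope * self.stage1.intercept + self.stage2.intercept
        return a, b


def published_calibration_chain() -> CalibrationChain:
    return CalibrationChain(
        stage1=RegressionModel(1.42, 0.10, 0.09, 0.01, label="TM->SBE fluorescence"),
        stage2=RegressionModel(1.11, -0.08, 0.25, 0.05, label="SBE flu->chl a"),
    )


def apply_calibration_chain(flu_profile, chain: CalibrationChain) -> NutrientProfile:
    """Convert profiler fluorescence to chlorophyll a (mg m^-3).

    Applies both affine stages; negative chlorophyll is clipped to zero
    and flagged.
    """
    if chain.stage1 is None or chain.stage2 is None:
        raise ValueError("calibration chain is missing a stage")
    flu = np.asarray(flu_profile, dtype=float)
    a, b = chain.composed()
    raw = a * flu + b
    clipped = np.isfinite(raw) & (raw < 0)
    values = np.where(clipped, 0.0, raw)
    return NutrientProfile(values=values, masked=~np.isfinite(raw),
                           clipped=clipped)


def _match_depths(depth_a, values_a, depth_b, values_b, min_depth, tol=2.0):
    """Pair samples from two depth series within ``tol`` metres, >= min_depth."""
    xa, xb = [], []
    depth_b = np.asarray(depth_b, dtype=float)
    for d, va in zip(np.asarray(depth_a, float), np.asarray(values_a, float)):
        if d < min_depth or not np.isfinite(va):
            continue
        j = int(np.argmin(np.abs(depth_b - d)))
        if abs(depth_b[j] - d) <= tol and np.isfinite(values_b[j]):
            xa.append(va)
            xb.append(values_b[j])
    return np.array(xa), np.array(xb)


def _as_casts(casts):
    """Normalize to a list of (depth, values) casts."""
    if len(casts) == 2 and np.ndim(casts[0]) == 1 and np.ndim(casts[1]) == 1 \
            and not isinstance(casts[0], (list, tuple)):
        return [casts]
    return list(casts)


def fit_calibration_chain(tm_casts, ctd_casts, bottles,
                          min_depth: float = 100.0) -> CalibrationChain:
    """Fit both calibration stages from co-located casts and bottles.

    ``tm_casts``, ``ctd_casts`` and ``bottles`` are matching sequences of
    ``(depth, values)`` pairs, one per station (a single pair is also
    accepted); profiler and reference fluorescence casts are paired by
    depth within each station, bottle chlorophyll likewise against the
    reference cast. Stage 1 regresses reference (CTD) fluorescence on
    profiler fluorescence; stage 2 regresses bottle chlorophyll on
    reference fluorescence. Only samples at or below ``min_depth`` enter
    either fit, to avoid near-surface non-photochemical quenching.
    """
    tm_casts = _as_casts(tm_casts)
    ctd_casts = _as_casts(ctd_casts)
    bottles = _as_casts(bottles)
    x1 = np.empty(0)
    y1 = np.empty(0)
    for (td, tf_), (cd, cf) in zip(tm_casts, ctd_casts):
        a, b = _match_depths(td, tf_, cd, cf, min_depth)
        x1, y1 = np.append(x1, a), np.append(y1, b)
    if x1.size < 3:
        raise ValueError("fewer than 3 qualifying fluorescence pairs for stage 1")
    stage1 = replace(fit_linear(x1, y1), label="probe->reference fluorescence")

    chl2 = np.empty(0)
    flu2 = np.empty(0)
    for (bd, bc), (cd, cf) in zip(bottles, ctd_casts):
        a, b = _match_depths(bd, bc, cd, cf, min_depth)
        chl2, flu2 = np.append(chl2, a), np.append(flu2, b)
    if chl2.size < 3:
        raise ValueError("fewer than 3 qualifying chlorophyll pairs for stage 2")
    stage2 = replace(fit_linear(flu2, chl2), label="reference fluorescence->chl a")
    return CalibrationChain(stage1=stage1, stage2=stage2, min_depth=min_depth)
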