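"""CSV interchange formats for profiles, records and bottles.

All files are comma-separated UTF-8 with a header row; units live in the
column names (depth_m, epsilon_W_kg, ...). Leading ``# key: value`` lines
carry the file kind and per-file metadata (station, fall speed, sample
rate); every reader validates the declared kind, required columns and
depth monotonicity and reports malformed rows with line numbers.
Missing values are empty fields. Depth is metres, positive down.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .microstructure import (DissipationProfile, ShearRecord,
                             StratificationProfile)
from .synthetic import BottleSet, HydroProfile

__all__ = [
    "read_profiles",
    "write_shear_record",
    "write_hydro_profile",
    "write_bottles",
    "write_profile_table",
]

REQUIRED_COLUMNS = {
    "shear": ["time_s", "depth_m", "temperature_C", "shear1_s1"],
    "ctd": ["depth_m", "theta_C", "salinity_psu", "sigma_theta_kg_m3",
            "fluorescence"],
    "bottle": ["station", "depth_m", "theta_C", "nitrate_mmol_m3",
               "phosphate_mmol_m3", "chl_mg_m3"],
    "profile": ["station", "depth_m"],
}


def _write_with_header(path, kind: str, meta: dict, frame: pd.DataFrame):
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# kind: {kind}\n")
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        # %.17g keeps write->read lossless for float64
        frame.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")


def _read_with_header(path) -> tuple[dict, pd.DataFrame, int]:
    path = Path(path)
    meta: dict[str, str] = {}
    n_meta = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
        else:
            raise ValueError(f"{path}: no data rows")
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    return meta, frame, n_meta


def read_profiles(path, kind: str | None = None):
    """Read a CSV file into its typed container.

    ``kind`` (shear / ctd / bottle / profile) must match the kind the
    file declares in its header; pass None to accept whatever is
    declared. Returns ShearRecord, HydroProfile, BottleSet or a
    DataFrame (profile tables).
    """
    meta, frame, n_meta = _read_with_header(path)
    declared = meta.get("kind")
    if declared is None:
        raise ValueError(f"{path}: header does not declare a kind")
    if kind is not None and declared != kind:
        raise ValueError(f"{path}: declared kind {declared!r} != requested {kind!r}")
    kind = declared
    if kind not in REQUIRED_COLUMNS:
        raise ValueError(f"{path}: unknown kind {kind!r}")
    missing = [c for c in REQUIRED_COLUMNS[kind] if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    # malformed rows: non-numeric entries in (predominantly) numeric columns;
    # free-text columns such as QC flags are left alone
    candidates = [c for c in frame.columns if c != "station"]
    for col in candidates:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        raw_na = frame[col].isna()
        newly_bad = coerced.isna() & ~raw_na
        n_values = int((~raw_na).sum())
        if n_values and newly_bad.sum() * 2 > n_values:
            continue  # text column
        if newly_bad.any():
            lines = [i + n_meta + 2 for i in frame.index[newly_bad]]  # +header
            raise ValueError(
                f"{path}: malformed numeric value(s) in {col!r} at line(s) {lines}")
        frame[col] = coerced

    if kind in ("shear", "ctd") and "depth_m" in frame:
        d = frame["depth_m"].to_numpy(dtype=float)
        if d.size > 1 and np.any(np.diff(d) < 0):
            raise ValueError(f"{path}: depth_m must be non-decreasing")

    if kind == "shear":
        probes = [c for c in frame.columns if c.startswith("shear")]
        return ShearRecord(
            time=frame["time_s"].to_numpy(),
            shear=frame[probes].to_numpy(),
            depth=frame["depth_m"].to_numpy(),
            temperature=frame["temperature_C"].to_numpy(),
            fall_speed=float(meta.get("fall_speed_m_s", 0.6)),
            sample_rate=float(meta.get("sample_rate_hz", 512.0)),
            station=meta.get("station", ""),
            cast=int(meta.get("cast", 0)))
    if kind == "ctd":
        return HydroProfile(
            station=meta.get("station", ""),
            depth=frame["depth_m"].to_numpy(),
            theta=frame["theta_C"].to_numpy(),
            salinity=frame["salinity_psu"].to_numpy(),
            sigma_theta=frame["sigma_theta_kg_m3"].to_numpy(),
            fluorescence=frame["fluorescence"].to_numpy(),
            fluorescence_ref=(frame["fluorescence_ref"].to_numpy()
                              if "fluorescence_ref" in frame else None))
    if kind == "bottle":
        return BottleSet(
            station=frame["station"].iloc[0] if len(frame) else "",
            depth=frame["depth_m"].to_numpy(),
            theta=frame["theta_C"].to_numpy(),
            nitrate=frame["nitrate_mmol_m3"].to_numpy(),
            phosphate=frame["phosphate_mmol_m3"].to_numpy(),
            chlorophyll=frame["chl_mg_m3"].to_numpy())
    return frame


def write_shear_record(path, record: ShearRecord):
    cols = {"time_s": record.time, "depth_m": record.depth,
            "temperature_C": record.temperature}
    for p in range(record.n_probes):
        cols[f"shear{p + 1}_s1"] = record.shear[:, p]
    meta = {"fall_speed_m_s": record.fall_speed,
            "sample_rate_hz": record.sample_rate,
            "station": record.station, "cast": record.cast,
            "instrument": record.instrument}
    _write_with_header(path, "shear", meta, pd.DataFrame(cols))


def write_hydro_profile(path, hydro: HydroProfile):
    cols = {"depth_m": hydro.depth, "theta_C": hydro.theta,
            "salinity_psu": hydro.salinity,
            "sigma_theta_kg_m3": hydro.sigma_theta,
            "fluorescence": hydro.fluorescence}
    if hydro.fluorescence_ref is not None:
        cols["fluorescence_ref"] = hydro.fluorescence_ref
    _write_with_header(path, "ctd", {"station": hydro.station},
                       pd.DataFrame(cols))


def write_bottles(path, bottles: BottleSet | list[BottleSet]):
    sets = bottles if isinstance(bottles, list) else [bottles]
    frames = [pd.DataFrame({
        "station": b.station, "depth_m": b.depth, "theta_C": b.theta,
        "nitrate_mmol_m3": b.nitrate, "phosphate_mmol_m3": b.phosphate,
        "chl_mg_m3": b.chlorophyll}) for b in sets]
    _write_with_header(path, "bottle", {}, pd.concat(frames, ignore_index=True))


def write_profile_table(path, frame: pd.DataFrame, meta: dict | None = None):
    """Write a tidy per-station profile table (epsilon / N2 / K / flux)."""
    _write_with_header(path, "profile", meta or {}, frame)
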