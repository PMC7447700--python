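"""CSV readers/writers for the pipeline's tabular schemas, plus run
configuration.

All files are UTF-8 CSV with a header row, comma separator and '.' decimal
point; both LF and CRLF line endings are accepted. Schemas:

* gas-exchange curve: ``driver_kind, driver, pn, cultivar, stage, date``
* chamber log: ``time_s, chamber_id, co2_ppm[, ppfd]``
* trait table: ``cultivar, year, replicate, trait, value, unit``
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ricephys.chamber import ChamberSeries, FluxEstimate
from ricephys.curves import GasExchangeCurve
from ricephys.errors import SchemaError
from ricephys.traits import TRAIT_COLUMNS, TraitTable

__all__ = [
    "RunConfig",
    "read_curve_csv",
    "write_curve_csv",
    "read_chamber_csv",
    "write_chamber_csv",
    "read_trait_csv",
    "write_trait_csv",
    "write_flux_csv",
    "write_fit_report",
]

CURVE_COLUMNS = ("driver_kind", "driver", "pn", "cultivar", "stage", "date")
CHAMBER_COLUMNS = ("time_s", "chamber_id", "co2_ppm")


@dataclass
class RunConfig:
    """Pipeline configuration with documented defaults.

    Loadable from a flat JSON object; unknown keys are rejected so typos
    fail loudly rather than silently falling back to defaults.
    """

    kc: float = 404.0
    ko: float = 278.0
    o: float = 210.0
    gamma_star: float = 45.0
    trim_head: float = 5.0
    closed_duration: float = 45.0
    open_duration: float = 495.0
    n_chambers: int = 10
    air_temperature: float = 303.15
    pressure: float = 101325.0
    alpha: float = 0.05
    output_dir: str = "."
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _read_csv(path, required, label: str) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    # text columns: absent values are empty strings, not NaN
    for col in ("cultivar", "stage", "date", "unit"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} file {path}: missing column(s) {missing}")
    return df


def _check_numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for col in cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
            )
        if converted.isna().any():
            raise SchemaError(f"{path}: missing value in column {col!r}")
        df[col] = converted
    return df


def read_curve_csv(path) -> GasExchangeCurve:
    """Read one gas-exchange curve; mixed driver kinds in one file are a
    schema error."""
    df = _read_csv(path, ("driver_kind", "driver", "pn"), "curve")
    df = _check_numeric(df, ("driver", "pn"), path)
    try:
        return GasExchangeCurve.from_dataframe(df)
    except Exception as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_curve_csv(curve: GasExchangeCurve, path) -> None:
    curve.to_dataframe().to_csv(path, index=False)


def read_chamber_csv(path) -> dict:
    """Read a chamber log; returns ``{chamber_id: ChamberSeries}``.

    Rows may interleave chambers; within each chamber time must strictly
    increase and non-1 Hz gaps are flagged with a warning.
    """
    df = _read_csv(path, CHAMBER_COLUMNS, "chamber log")
    df = _check_numeric(df, ("time_s", "co2_ppm"), path)
    has_ppfd = "ppfd" in df.columns
    if has_ppfd:
        df = _check_numeric(df, ("ppfd",), path)
    out = {}
    for cid, grp in df.groupby("chamber_id", sort=False):
        t = grp["time_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise SchemaError(f"{path}: time not strictly increasing for chamber {cid}")
        out[str(cid)] = ChamberSeries(
            t,
            grp["co2_ppm"].to_numpy(float),
            str(cid),
            grp["ppfd"].to_numpy(float) if has_ppfd else None,
        )
    return out


def write_chamber_csv(series_by_id: dict, path) -> None:
    frames = []
    for cid, s in series_by_id.items():
        d = {"time_s": s.timestamps, "chamber_id": cid, "co2_ppm": s.co2}
        if s.ppfd is not None:
            d["ppfd"] = s.ppfd
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trait_csv(path) -> TraitTable:
    df = _read_csv(path, TRAIT_COLUMNS, "trait table")
    df = _check_numeric(df, ("value",), path)
    return TraitTable(df)


def write_trait_csv(table: TraitTable, path) -> None:
    table.df.to_csv(path, index=False)


def write_flux_csv(estimates, path) -> None:
    """Per-closure flux estimates as CSV."""
    rows = [
        {
            "chamber_id": e.chamber_id,
            "window_start_s": e.window[0],
            "window_end_s": e.window[1],
            "slope_ppm_s": e.slope,
            "flux_umol_m2_s": e.flux,
            "slope_se": e.slope_se,
            "r_squared": e.r_squared,
            "mean_ppfd": e.mean_ppfd,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fit_report(result, path) -> None:
    """Serialize a FitResult (or anything with ``to_dict``) as JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(result.to_dict(), fh, indent=2)
        fh.write("\n")
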