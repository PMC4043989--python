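"""CSV schemas for acoustic, catch, donor and result tables.

All files are UTF-8 comma-separated with a header row, ``.`` decimal
separator and empty fields for missing values. Months are integers 1-12.
Longitude is accepted in either signed degrees [-180, 180] or degrees east
[0, 360) and normalized to degrees east internally and on write, keeping
the North Pacific contiguous across the dateline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "normalize_lon",
    "read_acoustic", "write_acoustic",
    "read_catches", "write_catches",
    "read_donors", "write_donors",
    "write_realization", "write_percentiles",
]

ACOUSTIC_FILE_COLUMNS = ["station_id", "lon", "lat", "month",
                         "hours_analyzed", "hours_present", "call_type"]
CATCH_FILE_COLUMNS = ["catch_id", "year", "month", "lon", "lat", "category",
                      "region_id", "rect_lat_min", "rect_lat_max",
                      "rect_lon_min", "rect_lon_max", "expedition_id",
                      "op_month_start", "op_month_end", "sex", "length_m",
                      "maturity"]
DONOR_FILE_COLUMNS = ["species", "lon", "lat", "month", "year",
                      "expedition_id", "region_id"]


def normalize_lon(lon):
    """Map longitudes to degrees east in [0, 360)."""
    lon = np.asarray(lon, dtype=float)
    out = np.where(lon < 0, lon + 360.0, lon)
    if np.any((out < 0) | (out >= 360.0)):
        raise ValueError("longitude outside [-180, 360)")
    return out


def _read_csv(path, required):
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as err:
        raise ValueError(f"{path}: empty file") from err
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_acoustic(path) -> pd.DataFrame:
    """Read station-month call presence records.

    Validates counts and months row by row (errors cite the file line
    number, header = line 1) and returns the internal schema with
    ``lon_east`` and ``n_hours``/``k_hours`` columns.
    """
    df = _read_csv(path, ACOUSTIC_FILE_COLUMNS)
    for i, row in df.iterrows():
        line = i + 2
        if not 1 <= row["month"] <= 12:
            raise ValueError(f"{path}:{line}: month {row['month']} not in 1-12")
        if row["hours_analyzed"] < 0 or row["hours_present"] < 0:
            raise ValueError(f"{path}:{line}: negative hours")
        if row["hours_present"] > row["hours_analyzed"]:
            raise ValueError(
                f"{path}:{line}: hours_present {row['hours_present']} exceeds "
                f"hours_analyzed {row['hours_analyzed']}")
        if row["call_type"] not in ("east", "west"):
            raise ValueError(f"{path}:{line}: call_type must be east or west")
    out = pd.DataFrame({
        "station_id": df["station_id"].astype(str),
        "lon_east": normalize_lon(df["lon"]),
        "lat": df["lat"].astype(float),
        "month": df["month"].astype(int),
        "n_hours": df["hours_analyzed"].astype(int),
        "k_hours": df["hours_present"].astype(int),
        "call_type": df["call_type"].astype(str),
    })
    return out


def write_acoustic(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "station_id": df["station_id"], "lon": df["lon_east"],
        "lat": df["lat"], "month": df["month"],
        "hours_analyzed": df["n_hours"], "hours_present": df["k_hours"],
        "call_type": df["call_type"],
    })
    out.to_csv(path, index=False)


def read_catches(path) -> pd.DataFrame:
    df = _read_csv(path, CATCH_FILE_COLUMNS)
    out = df.copy()
    out["lon_east"] = np.where(df["lon"].notna(),
                               normalize_lon(df["lon"].fillna(0.0)), np.nan)
    for col in ("rect_lon_min", "rect_lon_max"):
        out[col] = np.where(df[col].notna(),
                            normalize_lon(df[col].fillna(0.0)), np.nan)
    out = out.drop(columns=["lon"])
    bad = out["month"].notna() & ~out["month"].between(1, 12)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path}:{line}: month not in 1-12")
    return out


def write_catches(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["lon"] = out.pop("lon_east")
    out[CATCH_FILE_COLUMNS].to_csv(path, index=False)


def read_donors(path) -> pd.DataFrame:
    df = _read_csv(path, DONOR_FILE_COLUMNS)
    out = df.copy()
    out["lon_east"] = normalize_lon(df["lon"])
    out = out.drop(columns=["lon"])
    bad = ~out["month"].between(1, 12)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path}:{line}: month not in 1-12")
    return out


def write_donors(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["lon"] = out.pop("lon_east")
    out[DONOR_FILE_COLUMNS].to_csv(path, index=False)


def write_realization(realization, path) -> None:
    t = realization.table.copy()
    t["realization_seed"] = realization.realization_seed
    t.to_csv(path, index=False)


def write_percentiles(pct, path) -> None:
    """Percentile table CSV; the totals row carries year = 'total'."""
    t = pct.table.copy()
    t["year"] = t["year"].astype(object)
    t.loc[t["year"] == -1, "year"] = "total"
    t.to_csv(path, index=False)
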