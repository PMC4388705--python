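"""Readers and writers for the plain-CSV table dialects.

All tables are delimited text with ISO-8601 timestamps (local standard
time, no DST).  Writers round-trip floats at full precision.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from . import windows
from .errors import DuplicateRecordError, MissingColumnError

log = logging.getLogger("neeflux")

FLUX_COLUMNS = ["timestamp", "nee", "par", "t_air", "t_soil", "vwc",
                "precip", "valid"]
REFLECTANCE_COLUMNS = ["date", "rho_blue", "rho_red", "rho_nir", "rho_swir",
                       "qc_ok"]
INDEX_COLUMNS = ["date", "ndvi", "evi", "lswi", "filled"]
PARAM_COLUMNS = ["window_start", "alpha0", "se_alpha0", "gx", "se_gx",
                 "b0", "se_b0", "b", "se_b", "n_obs", "rss", "converged"]


def _require(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        if col not in df.columns:
            raise MissingColumnError(col, str(path))


def read_flux_table(path) -> pd.DataFrame:
    """Read, sort and regularize a half-hourly flux table.

    Rows are snapped onto the full 30-minute grid between the first and
    last timestamp; grid slots with no row are inserted as invalid
    records (count conserved: original valid rows are untouched).
    Timestamps off the 30-minute grid trigger a warning and are dropped
    from the regularized output.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, FLUX_COLUMNS, path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if df["timestamp"].duplicated().any():
        raise DuplicateRecordError(f"duplicate timestamps in {path}")
    df = df.sort_values("timestamp").reset_index(drop=True)
    df["valid"] = df["valid"].astype(bool)

    on_grid = (df["timestamp"].dt.minute % 30 == 0) & \
              (df["timestamp"].dt.second == 0)
    if not on_grid.all():
        log.warning("%s: %d timestamps off the 30-min grid dropped",
                    path, int((~on_grid).sum()))
        df = df[on_grid]

    grid = pd.date_range(df["timestamp"].min(), df["timestamp"].max(),
                         freq="30min")
    if len(grid) != len(df):
        log.warning("%s: %d missing half-hours inserted as invalid",
                    path, len(grid) - len(df))
    out = df.set_index("timestamp").reindex(grid)
    missing_rows = out["valid"].isna()
    out.loc[missing_rows, "valid"] = False
    out["valid"] = out["valid"].astype(bool)
    return out.rename_axis("timestamp").reset_index()[FLUX_COLUMNS]


def write_flux_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    out[FLUX_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_reflectance_table(path) -> pd.DataFrame:
    """Read an 8-day reflectance table; sanitize obviously bad records.

    Reflectances outside [0, 1] with ``qc_ok`` true are demoted to
    ``qc_ok`` false with a warning.  Duplicate composite dates are an
    error; dates off the 8-day window grid only warn.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, REFLECTANCE_COLUMNS, path)
    df["date"] = pd.to_datetime(df["date"])
    if df["date"].duplicated().any():
        raise DuplicateRecordError(f"duplicate composite dates in {path}")
    df = df.sort_values("date").reset_index(drop=True)
    df["qc_ok"] = df["qc_ok"].astype(bool)

    bands = ["rho_blue", "rho_red", "rho_nir", "rho_swir"]
    in_range = df[bands].apply(lambda c: c.between(0, 1)).all(axis=1)
    demote = df["qc_ok"] & ~in_range
    if demote.any():
        log.warning("%s: %d out-of-range records demoted to qc_ok=False",
                    path, int(demote.sum()))
        df.loc[demote, "qc_ok"] = False

    off_grid = df["date"] != windows.window_start(df["date"])
    if off_grid.any():
        log.warning("%s: %d composite dates off the 8-day grid",
                    path, int(off_grid.sum()))
    return df[REFLECTANCE_COLUMNS]


def write_reflectance_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[REFLECTANCE_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_index_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, INDEX_COLUMNS, path)
    df["date"] = pd.to_datetime(df["date"])
    df["filled"] = df["filled"].astype(bool)
    return df[INDEX_COLUMNS]


def write_index_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[INDEX_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_param_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, PARAM_COLUMNS, path)
    df["window_start"] = pd.to_datetime(df["window_start"])
    df["converged"] = df["converged"].astype(bool)
    return df[PARAM_COLUMNS]


def write_param_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["window_start"] = pd.to_datetime(out["window_start"]).dt.strftime(
        "%Y-%m-%d")
    out[PARAM_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def write_report(report, out_dir) -> None:
    """Overall metrics as JSON plus the windowed R^2 series as CSV."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clean = {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
             for k, v in report.to_dict().items()}
    with open(out_dir / "report.json", "w") as fh:
        json.dump(clean, fh, indent=2)
    win = report.windowed.copy()
    if len(win):
        win["window_start"] = pd.to_datetime(win["window_start"]).dt.strftime(
            "%Y-%m-%d")
    win.to_csv(out_dir / "windowed_r2.csv", index=False)
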