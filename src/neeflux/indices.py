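"""Vegetation indices from 8-day composite surface reflectance.

NDVI, EVI and LSWI are computed from the blue, red, near-infrared
(841-875 nm) and shortwave-infrared (1628-1652 nm) bands.  Records failing
quality control (or falling outside [0, 1]) are masked and the index time
series is gap-filled onto the full 8-day window grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import windows
from .errors import AllBadRecordsError, EmptyInputError, UndefinedRatioError

INDEX_NAMES = ("ndvi", "evi", "lswi")

REFLECTANCE_COLUMNS = ("rho_blue", "rho_red", "rho_nir", "rho_swir")


@dataclass(frozen=True)
class EviConstants:
    """Coefficients of the enhanced vegetation index."""

    g: float = 2.5
    c1: float = 6.0
    c2: float = 7.5
    l: float = 1.0


def _ratio(num, den, what: str):
    scalar = np.isscalar(num) and np.isscalar(den)
    den = np.asarray(den, dtype=float)
    if np.any(den == 0):
        raise UndefinedRatioError(f"{what}: zero denominator")
    out = np.asarray(num, dtype=float) / den
    return float(out) if scalar else out


def ndvi(rho_nir, rho_red):
    """Normalized difference vegetation index ``(nir-red)/(nir+red)``."""
    return _ratio(np.subtract(rho_nir, rho_red), np.add(rho_nir, rho_red), "ndvi")


def evi(rho_nir, rho_red, rho_blue, constants: EviConstants = EviConstants()):
    """Enhanced vegetation index
    ``G*(nir-red) / (L + nir + C1*red - C2*blue)``."""
    c = constants
    den = c.l + np.asarray(rho_nir, dtype=float) + c.c1 * np.asarray(
        rho_red, dtype=float) - c.c2 * np.asarray(rho_blue, dtype=float)
    return _ratio(c.g * np.subtract(rho_nir, rho_red), den, "evi")


def lswi(rho_nir, rho_swir):
    """Land surface water index ``(nir-swir)/(nir+swir)``."""
    return _ratio(np.subtract(rho_nir, rho_swir), np.add(rho_nir, rho_swir), "lswi")


def compute_indices(records: pd.DataFrame,
                    constants: EviConstants = EviConstants()) -> pd.DataFrame:
    """Per-record index values (no QC, no filling).

    ``records`` needs columns ``rho_blue, rho_red, rho_nir, rho_swir``.
    Returns a frame with ``ndvi, evi, lswi`` columns aligned to the input.
    """
    return pd.DataFrame(
        {
            "ndvi": ndvi(records["rho_nir"].to_numpy(), records["rho_red"].to_numpy()),
            "evi": evi(records["rho_nir"].to_numpy(), records["rho_red"].to_numpy(),
                       records["rho_blue"].to_numpy(), constants),
            "lswi": lswi(records["rho_nir"].to_numpy(), records["rho_swir"].to_numpy()),
        },
        index=records.index,
    )


def _quality_mask(records: pd.DataFrame) -> pd.Series:
    ok = records["qc_ok"].astype(bool).copy()
    for col in REFLECTANCE_COLUMNS:
        ok &= records[col].between(0.0, 1.0) & records[col].notna()
    # zero denominators are unusable regardless of the QC flag
    ok &= (records["rho_nir"] + records["rho_red"]) != 0
    ok &= (records["rho_nir"] + records["rho_swir"]) != 0
    evi_den = (1.0 + records["rho_nir"] + 6.0 * records["rho_red"]
               - 7.5 * records["rho_blue"])
    ok &= evi_den != 0
    return ok


def build_index_series(records: pd.DataFrame, fill: str = "linear",
                       constants: EviConstants = EviConstants()) -> pd.DataFrame:
    """QC-screen, compute and gap-fill the three index series.

    Parameters
    ----------
    records
        Columns ``date, rho_blue, rho_red, rho_nir, rho_swir, qc_ok``;
        at most one record per 8-day window.
    fill
        ``"linear"`` — linear interpolation between nearest valid
        neighbours for interior gaps, nearest-value extension at the
        edges; ``"none"`` — leave gaps as NaN.

    Returns
    -------
    DataFrame with columns ``date, ndvi, evi, lswi, filled`` covering
    every 8-day window spanned by the input period.
    """
    if len(records) == 0:
        raise EmptyInputError("no reflectance records")
    if fill not in ("linear", "none"):
        raise ValueError(f"unknown fill method {fill!r}")

    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    rec = rec.sort_values("date")
    rec["window"] = windows.window_start(rec["date"])

    good = rec[_quality_mask(rec)]
    if len(good) == 0:
        raise AllBadRecordsError("no reflectance record passed QC")

    grid = windows.window_range(rec["date"].min(), rec["date"].max())
    vals = compute_indices(good, constants).set_index(good["window"].to_numpy())
    vals = vals[~vals.index.duplicated(keep="first")]
    out = vals.reindex(grid)
    filled = out["ndvi"].isna()

    if fill == "linear":
        # interpolate on the window ordinal so irregular year-ends carry
        # unit weight like any other step
        out = out.reset_index(drop=True).interpolate(
            method="index", limit_direction="both", limit_area=None)
        out.index = grid

    result = out.reset_index(names="date")
    result["filled"] = filled.to_numpy()
    return result
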