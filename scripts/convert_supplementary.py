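#!/usr/bin/env python
"""One-shot converter: site XLSX workbooks -> the package CSV dialects.

The original site data ship as spreadsheets.  This helper maps their
columns onto the flux dialect (timestamp, nee, par, t_air, t_soil, vwc,
precip, valid) or the reflectance dialect (date, rho_blue, rho_red,
rho_nir, rho_swir, qc_ok) so the pipeline can consume them.  Column names
vary between distributions, so the mapping is given on the command line:

    python scripts/convert_supplementary.py flux S1.xlsx out.csv \
        --map timestamp=Date --map nee=NEE --map par=PAR \
        --map t_air=Ta --map t_soil=Ts5 --map vwc=VWC --map precip=Prec

    python scripts/convert_supplementary.py reflectance S3.xlsx out.csv \
        --map date=DOY --map rho_blue=b3 --map rho_red=b1 \
        --map rho_nir=b2 --map rho_swir=b6 --map qc_ok=QC

Unmapped optional columns are filled with defaults (valid=True on rows
with finite NEE; qc_ok=True).  Requires openpyxl.
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

FLUX_REQUIRED = ["timestamp", "nee", "par", "t_air", "t_soil"]
FLUX_OPTIONAL = ["vwc", "precip", "valid"]
REFL_REQUIRED = ["date", "rho_blue", "rho_red", "rho_nir", "rho_swir"]
REFL_OPTIONAL = ["qc_ok"]


def parse_map(entries):
    out = {}
    for e in entries or []:
        dst, _, src = e.partition("=")
        if not src:
            raise SystemExit(f"bad --map entry {e!r}")
        out[dst] = src
    return out


def convert(kind, src, dst, mapping, sheet):
    df = pd.read_excel(src, sheet_name=sheet)
    required = FLUX_REQUIRED if kind == "flux" else REFL_REQUIRED
    optional = FLUX_OPTIONAL if kind == "flux" else REFL_OPTIONAL
    out = pd.DataFrame()
    for col in required:
        name = mapping.get(col, col)
        if name not in df.columns:
            raise SystemExit(f"column {name!r} (for {col}) not in {src}; "
                             f"available: {list(df.columns)}")
        out[col] = df[name]
    for col in optional:
        name = mapping.get(col, col)
        out[col] = df[name] if name in df.columns else np.nan

    if kind == "flux":
        out["timestamp"] = pd.to_datetime(out["timestamp"])
        if out["valid"].isna().all():
            out["valid"] = np.isfinite(pd.to_numeric(out["nee"],
                                                     errors="coerce"))
        out["valid"] = out["valid"].astype(bool)
    else:
        out["date"] = pd.to_datetime(out["date"])
        if out["qc_ok"].isna().all():
            out["qc_ok"] = True
        out["qc_ok"] = out["qc_ok"].astype(bool)
    out.to_csv(dst, index=False)
    print(f"wrote {len(out)} rows to {dst}")


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("kind", choices=["flux", "reflectance"])
    ap.add_argument("src", type=Path)
    ap.add_argument("dst", type=Path)
    ap.add_argument("--map", action="append", dest="maps",
                    help="dialect_column=source_column")
    ap.add_argument("--sheet", default=0)
    args = ap.parse_args(argv)
    convert(args.kind, args.src, args.dst, parse_map(args.maps), args.sheet)


if __name__ == "__main__":
    sys.exit(main())
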