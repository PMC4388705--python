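"""Forward simulation of half-hourly NEE and validation scoring.

R^2 is the squared Pearson correlation of modeled vs observed NEE (the
coefficient of determination of their linear regression), reported
overall, split into day (PAR >= threshold) and night, and per 8-day
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import core, windows
from .errors import InsufficientDataError, UnmappedTimestampError

#: PAR below this (micromol m^-2 s^-1) counts as night.
NIGHT_PAR_THRESHOLD = 5.0

#: Windowed R^2 entries need at least this many pairs.
MIN_WINDOW_PAIRS = 10


@dataclass
class ValidationReport:
    """R^2 / regression summaries of modeled vs observed NEE."""

    r2_all: float
    slope: float
    intercept: float
    n_all: int
    r2_day: float
    n_day: int
    r2_night: float
    n_night: int
    windowed: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "r2_all": self.r2_all, "slope": self.slope,
            "intercept": self.intercept, "n_all": self.n_all,
            "r2_day": self.r2_day, "n_day": self.n_day,
            "r2_night": self.r2_night, "n_night": self.n_night,
        }


def simulate_series(flux: pd.DataFrame, params: pd.DataFrame,
                    ca: float = core.CA_DEFAULT) -> pd.Series:
    """Modeled NEE for every flux record, using its window's parameters.

    ``params`` is a parameter table with ``window_start`` and the four
    parameter columns (inverted or predicted).  Records whose window has
    no parameter row raise :class:`UnmappedTimestampError`; records that
    are invalid, or whose window's parameters are NaN, yield NaN.
    """
    rec = flux.copy()
    rec["timestamp"] = pd.to_datetime(rec["timestamp"])
    rec["_window"] = windows.window_start(rec["timestamp"])

    par_tab = params.copy()
    par_tab["window_start"] = pd.to_datetime(par_tab["window_start"])
    par_tab = par_tab.set_index("window_start")[["alpha0", "gx", "b0", "b"]]

    missing = ~rec["_window"].isin(par_tab.index)
    if missing.any():
        first = rec.loc[missing, "timestamp"].iloc[0]
        raise UnmappedTimestampError(
            f"{int(missing.sum())} records outside all windows "
            f"(first: {first})")

    theta = par_tab.reindex(rec["_window"]).to_numpy(dtype=float)
    modeled = core.nee(
        rec["par"].to_numpy(dtype=float), rec["t_air"].to_numpy(dtype=float),
        rec["t_soil"].to_numpy(dtype=float),
        theta[:, 0], theta[:, 1], theta[:, 2], theta[:, 3], ca)
    if "valid" in rec.columns:
        modeled = np.where(rec["valid"].astype(bool), modeled, np.nan)
    return pd.Series(modeled, index=flux.index, name="nee_model")


def r_squared(x, y) -> float:
    """Squared Pearson correlation; NaN when either side is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(stats.pearsonr(x, y).statistic ** 2)


def validate(modeled, observed, par, timestamps=None,
             night_par_threshold: float = NIGHT_PAR_THRESHOLD,
             min_window_pairs: int = MIN_WINDOW_PAIRS) -> ValidationReport:
    """Score modeled against observed NEE.

    All inputs are aligned sequences; pairs with a non-finite side are
    dropped.  ``timestamps`` (optional) enables the windowed seasonal R^2
    series.  Day/night is an exhaustive, exclusive split on
    ``par >= night_par_threshold``.
    """
    modeled = np.asarray(modeled, dtype=float)
    observed = np.asarray(observed, dtype=float)
    par = np.asarray(par, dtype=float)
    ok = np.isfinite(modeled) & np.isfinite(observed) & np.isfinite(par)
    if ok.sum() < 3:
        raise InsufficientDataError(f"only {int(ok.sum())} valid pairs")

    m, o, p = modeled[ok], observed[ok], par[ok]
    reg = stats.linregress(o, m)
    day = p >= night_par_threshold

    windowed = pd.DataFrame(columns=["window_start", "r2", "n"])
    if timestamps is not None:
        ts = pd.to_datetime(pd.Series(np.asarray(timestamps)[ok]))
        frame = pd.DataFrame({
            "window_start": windows.window_start(ts).to_numpy(),
            "m": m, "o": o})
        rows = []
        for wstart, grp in frame.groupby("window_start"):
            if len(grp) >= min_window_pairs:
                rows.append({"window_start": wstart,
                             "r2": r_squared(grp["m"], grp["o"]),
                             "n": len(grp)})
        if rows:
            windowed = pd.DataFrame(rows)

    return ValidationReport(
        r2_all=float(reg.rvalue ** 2), slope=float(reg.slope),
        intercept=float(reg.intercept), n_all=int(len(m)),
        r2_day=r_squared(m[day], o[day]) if day.sum() >= 3 else np.nan,
        n_day=int(day.sum()),
        r2_night=r_squared(m[~day], o[~day]) if (~day).sum() >= 3 else np.nan,
        n_night=int((~day).sum()),
        windowed=windowed,
    )
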