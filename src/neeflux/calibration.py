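"""Regression of inverted parameters on vegetation indices and climate.

Every parameter x predictor pair gets a simple ordinary-least-squares
linear fit; per parameter the significant candidate with the highest R^2
(squared Pearson correlation) is selected.  Photosynthesis and reference
respiration (``alpha0``, ``gx``, ``b0``) are predicted from vegetation
indices; the temperature sensitivity ``b`` additionally admits the
environmental predictors (it tracks temperature, not greenness).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import windows
from .errors import InsufficientDataError
from .inversion import DEFAULT_BOUNDS, PARAM_NAMES

VI_PREDICTORS = ("ndvi", "evi", "lswi")
ENV_PREDICTORS = ("t_air", "t_soil", "vwc")
ALL_PREDICTORS = VI_PREDICTORS + ENV_PREDICTORS

#: Which predictors compete for each parameter.
DEFAULT_ALLOWED: dict[str, tuple[str, ...]] = {
    "alpha0": VI_PREDICTORS,
    "gx": VI_PREDICTORS,
    "b0": VI_PREDICTORS,
    "b": ALL_PREDICTORS,
}

MIN_PAIRS = 3


@dataclass(frozen=True)
class CalibrationFunction:
    """A fitted linear map ``parameter = intercept + slope * predictor``.

    ``predictor == "constant"`` marks the fallback used when no candidate
    was significant; it predicts ``intercept`` everywhere.
    """

    parameter: str
    predictor: str
    intercept: float
    slope: float
    r2: float = np.nan
    p_value: float = np.nan
    n: int = 0

    @property
    def is_fallback(self) -> bool:
        return self.predictor == "constant"

    def predict(self, x):
        if self.is_fallback:
            return np.full_like(np.asarray(x, dtype=float), self.intercept)
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class CalibrationSuite:
    """One selected function per parameter plus the full candidate table."""

    functions: dict[str, CalibrationFunction]
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self, path) -> None:
        payload = {
            "functions": {
                p: {k: (None if isinstance(v, float) and np.isnan(v) else v)
                    for k, v in vars(f).items()}
                for p, f in self.functions.items()
            },
            "candidates": self.candidates.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)

    @classmethod
    def from_json(cls, path) -> "CalibrationSuite":
        with open(path) as fh:
            payload = json.load(fh)
        funcs = {}
        for p, d in payload["functions"].items():
            d = {k: (np.nan if v is None else v) for k, v in d.items()}
            d["n"] = int(d["n"])
            funcs[p] = CalibrationFunction(**d)
        return cls(functions=funcs,
                   candidates=pd.DataFrame(payload["candidates"]))


def window_environment(flux: pd.DataFrame) -> pd.DataFrame:
    """Window means of the environmental drivers over valid half-hours.

    Returns a frame indexed by nothing with columns
    ``window_start, t_air, t_soil, vwc``.
    """
    rec = flux.copy()
    rec["timestamp"] = pd.to_datetime(rec["timestamp"])
    if "valid" in rec.columns:
        rec = rec[rec["valid"].astype(bool)]
    rec["window_start"] = windows.window_start(rec["timestamp"])
    cols = [c for c in ("t_air", "t_soil", "vwc") if c in rec.columns]
    out = rec.groupby("window_start")[cols].mean().reset_index()
    return out


def fit_candidates(params: pd.DataFrame, predictors: pd.DataFrame,
                   parameters=PARAM_NAMES,
                   predictor_names=ALL_PREDICTORS) -> pd.DataFrame:
    """OLS fit of every parameter x predictor pair.

    ``params`` is a parameter table (``window_start``, parameter columns,
    ``converged``); only converged windows enter the fits.  ``predictors``
    carries ``window_start`` plus predictor columns.  Returns a candidate
    table (parameter, predictor, slope, intercept, r2, p, n).
    """
    par = params.copy()
    par["window_start"] = pd.to_datetime(par["window_start"])
    if "converged" in par.columns:
        par = par[par["converged"].astype(bool)]
    pred = predictors.copy()
    pred["window_start"] = pd.to_datetime(pred["window_start"])
    merged = par.merge(pred, on="window_start", how="inner",
                       suffixes=("", "_pred"))
    if len(merged) < MIN_PAIRS:
        raise InsufficientDataError(
            f"only {len(merged)} aligned parameter/predictor windows")

    rows = []
    for parameter in parameters:
        for predictor in predictor_names:
            if predictor not in merged.columns or parameter not in merged.columns:
                continue
            pair = merged[[parameter, predictor]].dropna()
            if len(pair) < MIN_PAIRS:
                continue
            x = pair[predictor].to_numpy(dtype=float)
            y = pair[parameter].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                continue
            fit = stats.linregress(x, y)
            rows.append({
                "parameter": parameter, "predictor": predictor,
                "slope": fit.slope, "intercept": fit.intercept,
                "r2": fit.rvalue ** 2, "p": fit.pvalue, "n": len(pair),
            })
    return pd.DataFrame(
        rows, columns=["parameter", "predictor", "slope", "intercept",
                       "r2", "p", "n"])


def select_suite(candidates: pd.DataFrame, significance: float = 0.05,
                 allowed: dict[str, tuple[str, ...]] | None = None,
                 fallback: dict[str, float] | None = None) -> CalibrationSuite:
    """Pick, per parameter, the significant candidate with maximal R^2.

    When no candidate passes the significance gate the parameter falls
    back to a constant function at ``fallback[parameter]`` (typically the
    median inverted value; default 0).
    """
    allowed = allowed or DEFAULT_ALLOWED
    fallback = fallback or {}
    functions: dict[str, CalibrationFunction] = {}
    for parameter in PARAM_NAMES:
        pool = candidates[
            (candidates["parameter"] == parameter)
            & candidates["predictor"].isin(allowed.get(parameter, ALL_PREDICTORS))
            & (candidates["p"] < significance)
        ]
        if len(pool) == 0:
            functions[parameter] = CalibrationFunction(
                parameter=parameter, predictor="constant",
                intercept=float(fallback.get(parameter, 0.0)), slope=0.0)
            continue
        best = pool.loc[pool["r2"].idxmax()]
        functions[parameter] = CalibrationFunction(
            parameter=parameter, predictor=str(best["predictor"]),
            intercept=float(best["intercept"]), slope=float(best["slope"]),
            r2=float(best["r2"]), p_value=float(best["p"]), n=int(best["n"]))
    return CalibrationSuite(functions=functions, candidates=candidates)


def predict_parameters(suite: CalibrationSuite, predictors: pd.DataFrame,
                       bounds: dict[str, tuple[float, float]] | None = None
                       ) -> pd.DataFrame:
    """Apply the selected calibration functions to an 8-day predictor series.

    Output has one row per predictor window with the four parameters
    clipped to the inversion bounds; slots missing a needed predictor get
    NaN parameters and ``complete=False``.
    """
    bounds = bounds or DEFAULT_BOUNDS
    pred = predictors.copy()
    pred["window_start"] = pd.to_datetime(pred["window_start"])
    out = pd.DataFrame({"window_start": pred["window_start"]})
    complete = np.ones(len(pred), dtype=bool)
    for parameter, func in suite.functions.items():
        if func.is_fallback:
            vals = np.full(len(pred), func.intercept)
        elif func.predictor in pred.columns:
            x = pred[func.predictor].to_numpy(dtype=float)
            vals = func.predict(x)
            complete &= np.isfinite(x)
        else:
            vals = np.full(len(pred), np.nan)
            complete &= False
        lo, hi = bounds[parameter]
        out[parameter] = np.clip(vals, lo, hi)
    out["complete"] = complete
    return out
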