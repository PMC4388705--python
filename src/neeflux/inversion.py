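"""Windowed least-squares inversion of the four NEE-model parameters.

For every 8-day window all valid half-hourly NEE observations are fitted
with bounded trust-region nonlinear least squares.  Standard errors come
from the linearized covariance ``rss/(n-k) * diag((J'J)^-1)`` at the
optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import core, windows
from .errors import InsufficientDataError

PARAM_NAMES = ("alpha0", "gx", "b0", "b")

#: Physically plausible parameter bounds; 0.125 is the theoretical
#: quantum-efficiency ceiling.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha0": (0.0, 0.125),
    "gx": (0.0, 1.0),
    "b0": (0.0, 20.0),
    "b": (0.0, 0.5),
}

DEFAULT_X0 = (0.02, 0.01, 1.0, 0.1)

#: Jacobian columns with squared norm below this are treated as
#: unidentifiable (standard error reported as +inf).
_IDENTIFIABILITY_EPS = 1e-12


@dataclass
class InversionOptions:
    """Knobs of the per-window fit."""

    min_obs: int = 96
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))
    x0: tuple[float, float, float, float] = DEFAULT_X0
    n_starts: int = 3
    jitter_seed: int = 0


@dataclass
class ParameterSet:
    """Inverted (or predicted) parameters of one 8-day window."""

    window_start: pd.Timestamp
    alpha0: float
    gx: float
    b0: float
    b: float
    se_alpha0: float = np.nan
    se_gx: float = np.nan
    se_b0: float = np.nan
    se_b: float = np.nan
    n_obs: int = 0
    converged: bool = False
    rss: float = np.nan

    def values(self) -> tuple[float, float, float, float]:
        return (self.alpha0, self.gx, self.b0, self.b)

    def std_errors(self) -> tuple[float, float, float, float]:
        return (self.se_alpha0, self.se_gx, self.se_b0, self.se_b)


def params_to_frame(sets: list[ParameterSet]) -> pd.DataFrame:
    cols = ["window_start"]
    for p in PARAM_NAMES:
        cols += [p, f"se_{p}"]
    cols += ["n_obs", "rss", "converged"]
    rows = [
        {
            "window_start": s.window_start, "alpha0": s.alpha0, "gx": s.gx,
            "b0": s.b0, "b": s.b, "se_alpha0": s.se_alpha0, "se_gx": s.se_gx,
            "se_b0": s.se_b0, "se_b": s.se_b, "n_obs": s.n_obs,
            "rss": s.rss, "converged": s.converged,
        }
        for s in sets
    ]
    return pd.DataFrame(rows, columns=cols)


def frame_to_params(df: pd.DataFrame) -> list[ParameterSet]:
    return [
        ParameterSet(
            window_start=pd.Timestamp(r.window_start), alpha0=r.alpha0,
            gx=r.gx, b0=r.b0, b=r.b, se_alpha0=r.se_alpha0, se_gx=r.se_gx,
            se_b0=r.se_b0, se_b=r.se_b, n_obs=int(r.n_obs), rss=r.rss,
            converged=bool(r.converged),
        )
        for r in df.itertuples()
    ]


def _valid_records(records: pd.DataFrame) -> pd.DataFrame:
    sel = records
    if "valid" in sel.columns:
        sel = sel[sel["valid"].astype(bool)]
    need = ["nee", "par", "t_air", "t_soil"]
    return sel.dropna(subset=[c for c in need if c in sel.columns])


def _fit(obs, par, t_air, t_soil, ca, free_names, fixed, x0_full, bounds):
    """One bounded least-squares run over the free parameters."""
    idx = {n: i for i, n in enumerate(PARAM_NAMES)}

    def full_theta(theta_free):
        full = list(x0_full)
        for n, v in fixed.items():
            full[idx[n]] = v
        for n, v in zip(free_names, theta_free):
            full[idx[n]] = v
        return full

    def residuals(theta_free):
        a0, gx, b0, b = full_theta(theta_free)
        return core.nee(par, t_air, t_soil, a0, gx, b0, b, ca) - obs

    lo = [bounds[n][0] for n in free_names]
    hi = [bounds[n][1] for n in free_names]
    x0 = np.clip([x0_full[idx[n]] for n in free_names], lo, hi)
    res = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
    return res, full_theta(res.x)


def invert_window(records: pd.DataFrame, ca: float = core.CA_DEFAULT,
                  options: InversionOptions | None = None,
                  x0: tuple | None = None,
                  fix: dict[str, float] | None = None) -> ParameterSet:
    """Fit the NEE model to all valid half-hours of one 8-day window.

    ``fix`` maps parameter names (``"b"`` and/or ``"b0"``) to values held
    constant; their standard errors are reported as 0.  Raises
    :class:`InsufficientDataError` below ``options.min_obs`` valid records.
    Non-convergence (or unidentifiable parameters) is reported through
    ``converged=False`` with the best-found parameters retained.
    """
    options = options or InversionOptions()
    fix = dict(fix or {})
    for name in fix:
        if name not in PARAM_NAMES:
            raise ValueError(f"cannot fix unknown parameter {name!r}")

    sel = _valid_records(records)
    if len(sel) < options.min_obs:
        raise InsufficientDataError(
            f"{len(sel)} valid records < min_obs={options.min_obs}")

    obs = sel["nee"].to_numpy(dtype=float)
    par = sel["par"].to_numpy(dtype=float)
    t_air = sel["t_air"].to_numpy(dtype=float)
    t_soil = sel["t_soil"].to_numpy(dtype=float)
    wstart = windows.window_start(pd.Timestamp(sel["timestamp"].iloc[0])) \
        if "timestamp" in sel.columns else pd.NaT

    free_names = [n for n in PARAM_NAMES if n not in fix]
    x0_full = list(x0 if x0 is not None else options.x0)
    bounds = options.bounds

    best, theta = _fit(obs, par, t_air, t_soil, ca, free_names, fix,
                       x0_full, bounds)
    # restart from jittered points when the first solution sits on a bound
    # (the exponential term is prone to local minima there)
    at_bound = any(
        np.isclose(v, bounds[n][0]) or np.isclose(v, bounds[n][1])
        for n, v in zip(PARAM_NAMES, theta) if n in free_names
    )
    if at_bound and options.n_starts > 1:
        rng = np.random.default_rng(options.jitter_seed)
        for _ in range(options.n_starts - 1):
            trial_x0 = [
                rng.uniform(bounds[n][0], min(bounds[n][1], 4 * abs(x) + 0.01))
                if n in free_names else x
                for n, x in zip(PARAM_NAMES, x0_full)
            ]
            trial, trial_theta = _fit(obs, par, t_air, t_soil, ca,
                                      free_names, fix, trial_x0, bounds)
            if trial.cost < best.cost:
                best, theta = trial, trial_theta

    rss = float(2 * best.cost)
    n, k = len(obs), len(free_names)
    se = {name: 0.0 for name in fix}
    identifiable = True
    jtj = best.jac.T @ best.jac
    dof = max(n - k, 1)
    s2 = rss / dof
    cov = s2 * np.linalg.pinv(jtj)
    for i, name in enumerate(free_names):
        if jtj[i, i] < _IDENTIFIABILITY_EPS:
            se[name] = np.inf
            identifiable = False
        else:
            se[name] = float(np.sqrt(max(cov[i, i], 0.0)))

    a0, gx, b0, b = theta
    return ParameterSet(
        window_start=wstart, alpha0=a0, gx=gx, b0=b0, b=b,
        se_alpha0=se["alpha0"], se_gx=se["gx"], se_b0=se["b0"], se_b=se["b"],
        n_obs=n, converged=bool(best.success) and identifiable, rss=rss,
    )


def invert_window_fixed(records: pd.DataFrame, fix: dict[str, float],
                        ca: float = core.CA_DEFAULT,
                        options: InversionOptions | None = None,
                        x0: tuple | None = None) -> ParameterSet:
    """Three-parameter fit with one respiration parameter held constant."""
    if not fix or not set(fix) <= {"b", "b0"}:
        raise ValueError("fix must name b and/or b0")
    return invert_window(records, ca=ca, options=options, x0=x0, fix=fix)


def invert_series(records: pd.DataFrame, ca: float = core.CA_DEFAULT,
                  options: InversionOptions | None = None,
                  fix: dict[str, float] | None = None) -> list[ParameterSet]:
    """Invert every 8-day window of a half-hourly flux table.

    Windows with insufficient data yield a flagged (NaN, converged=False)
    entry; a failing window never aborts the series.  Each window is
    warm-started from the previous converged estimate.
    """
    options = options or InversionOptions()
    rec = records.copy()
    rec["timestamp"] = pd.to_datetime(rec["timestamp"])
    rec["_window"] = windows.window_start(rec["timestamp"])
    grid = windows.window_range(rec["timestamp"].min(), rec["timestamp"].max())

    out: list[ParameterSet] = []
    prev_x0 = None
    groups = dict(tuple(rec.groupby("_window")))
    for wstart in grid:
        group = groups.get(wstart)
        if group is None:
            out.append(ParameterSet(window_start=wstart, alpha0=np.nan,
                                    gx=np.nan, b0=np.nan, b=np.nan))
            continue
        try:
            ps = invert_window(group, ca=ca, options=options, x0=prev_x0,
                               fix=fix)
        except InsufficientDataError:
            out.append(ParameterSet(window_start=wstart, alpha0=np.nan,
                                    gx=np.nan, b0=np.nan, b=np.nan,
                                    n_obs=len(_valid_records(group))))
            continue
        ps.window_start = wstart
        if ps.converged:
            prev_x0 = ps.values()
        out.append(ps)
    return out
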