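"""Forward model of half-hourly net ecosystem CO2 exchange (NEE).

Gross primary productivity (GPP) follows a rectangular-hyperbola light
response whose initial slope (apparent quantum use efficiency, ``alpha``)
and asymptote (apparent maximum photosynthetic rate, ``beta``) are derived
from two temperature-independent parameters — the apparent maximum quantum
use efficiency ``alpha0`` and the carboxylation conductance ``gx`` —
through the temperature-dependent CO2 compensation point ``tau``:

    alpha = alpha0 * (Ca - tau) / (Ca + 2*tau)
    beta  = gx * (Ca - tau)
    GPP   = alpha * beta * PAR / (beta + alpha * PAR)

Ecosystem respiration follows a Van't Hoff exponential of soil temperature
at 5 cm with a 0 degC reference rate:

    Reco = b0 * exp(b * Tsoil)

The model output uses the micrometeorological sign convention,

    NEE = Reco - GPP,

so negative values denote net ecosystem uptake.

All functions broadcast over NumPy arrays and accept plain scalars, in
which case they return Python floats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidStateError

#: Default ambient CO2 concentration, micromol mol^-1.
CA_DEFAULT = 350.0

#: Celsius -> Kelvin offset.
KELVIN_OFFSET = 273.15

#: Reference temperature of the compensation-point quadratic, Kelvin.
TAU_REF_KELVIN = 298.0

#: tau is clipped to [0, TAU_CLIP_FRACTION * Ca] so that alpha and beta stay
#: well defined at extreme cold/hot inputs (the quadratic is only a local
#: approximation).
TAU_CLIP_FRACTION = 0.99


@dataclass(frozen=True)
class PhotosynthesisParams:
    """Temperature-independent photosynthesis parameters.

    alpha0
        Apparent maximum quantum use efficiency,
        micromol CO2 (micromol PAR)^-1.
    gx
        Carboxylation conductance: proportionality between the apparent
        maximum photosynthetic rate and the available CO2 ``Ca - tau``.
        The asymptote is ``beta = gx * (Ca - tau)`` in
        micromol CO2 m^-2 s^-1, so ``gx`` carries the units of
        ``beta / (Ca - tau)``; the literature labels it both as
        micromol CO2 m^-2 s^-1 (per micromol mol^-1) and as m s^-1.
    """

    alpha0: float
    gx: float

    def __post_init__(self):
        if self.alpha0 < 0 or self.gx < 0:
            raise InvalidStateError("alpha0 and gx must be non-negative")


@dataclass(frozen=True)
class RespirationParams:
    """Van't Hoff respiration parameters.

    b0
        Ecosystem respiration rate at 0 degC, micromol CO2 m^-2 s^-1.
    b
        Temperature-sensitivity coefficient, degC^-1 (Q10 = exp(10*b)).
    """

    b0: float
    b: float

    def __post_init__(self):
        if self.b0 < 0:
            raise InvalidStateError("b0 must be non-negative")


@dataclass(frozen=True)
class AtmosphericConstants:
    """Ambient-atmosphere constants; ``ca`` in micromol mol^-1."""

    ca: float = CA_DEFAULT

    def __post_init__(self):
        if self.ca <= 0:
            raise InvalidStateError("Ca must be positive")


@dataclass(frozen=True)
class EnvironmentState:
    """Instantaneous drivers: PAR (micromol m^-2 s^-1), air and soil
    temperature (degC)."""

    par: float
    t_air: float
    t_soil: float

    def __post_init__(self):
        if self.par < 0:
            raise InvalidStateError("PAR must be non-negative")


def _maybe_float(x, scalar: bool):
    return float(x) if scalar else x


def compensation_point(t_air, ca: float = CA_DEFAULT):
    """CO2 compensation-point concentration tau (micromol mol^-1).

    Quadratic in Kelvin temperature around 298 K:
    ``tau = 42.7 + 1.68*(T - 298) + 0.0012*(T - 298)**2`` with
    ``T = t_air + 273.15``.  The result is clipped to
    ``[0, TAU_CLIP_FRACTION * ca]``.
    """
    scalar = np.isscalar(t_air)
    dt = np.asarray(t_air, dtype=float) + KELVIN_OFFSET - TAU_REF_KELVIN
    tau = 42.7 + 1.68 * dt + 0.0012 * dt * dt
    tau = np.clip(tau, 0.0, TAU_CLIP_FRACTION * ca)
    return _maybe_float(tau, scalar)


def _check_tau(tau, ca):
    if np.any(np.asarray(tau) >= ca) or np.any(np.asarray(tau) < 0):
        raise InvalidStateError(f"tau must satisfy 0 <= tau < Ca = {ca}")


def apparent_quantum_efficiency(alpha0, tau, ca: float = CA_DEFAULT):
    """Apparent quantum use efficiency ``alpha = alpha0*(Ca-tau)/(Ca+2*tau)``."""
    scalar = np.isscalar(alpha0) and np.isscalar(tau)
    _check_tau(tau, ca)
    tau = np.asarray(tau, dtype=float)
    alpha = np.asarray(alpha0, dtype=float) * (ca - tau) / (ca + 2.0 * tau)
    return _maybe_float(alpha, scalar)


def apparent_max_photosynthesis(gx, tau, ca: float = CA_DEFAULT):
    """Apparent maximum photosynthetic rate ``beta = gx * (Ca - tau)``."""
    scalar = np.isscalar(gx) and np.isscalar(tau)
    _check_tau(tau, ca)
    beta = np.asarray(gx, dtype=float) * (ca - np.asarray(tau, dtype=float))
    return _maybe_float(beta, scalar)


def gpp(par, t_air, alpha0, gx, ca: float = CA_DEFAULT):
    """Gross primary productivity, micromol CO2 m^-2 s^-1 (>= 0).

    Rectangular hyperbola ``alpha*beta*PAR / (beta + alpha*PAR)``;
    returns 0 where the denominator vanishes (degenerate parameters or
    zero light).
    """
    scalar = all(np.isscalar(v) for v in (par, t_air, alpha0, gx))
    par = np.asarray(par, dtype=float)
    tau = compensation_point(t_air, ca)
    alpha = apparent_quantum_efficiency(alpha0, tau, ca)
    beta = apparent_max_photosynthesis(gx, tau, ca)
    denom = np.asarray(beta + alpha * par, dtype=float)
    num = np.asarray(alpha * beta * par, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return _maybe_float(out, scalar)


def reco(t_soil, b0, b):
    """Ecosystem respiration ``b0 * exp(b * t_soil)``, micromol CO2 m^-2 s^-1."""
    scalar = all(np.isscalar(v) for v in (t_soil, b0, b))
    out = np.asarray(b0, dtype=float) * np.exp(
        np.asarray(b, dtype=float) * np.asarray(t_soil, dtype=float)
    )
    return _maybe_float(out, scalar)


def nee(par, t_air, t_soil, alpha0, gx, b0, b, ca: float = CA_DEFAULT):
    """Net ecosystem exchange ``Reco - GPP``; negative = net uptake."""
    return reco(t_soil, b0, b) - gpp(par, t_air, alpha0, gx, ca)


def net_uptake_composite(par, t_air, t_soil, alpha0, gx, b0, b,
                         ca: float = CA_DEFAULT):
    """Single-expression net-uptake form (GPP - Reco, positive = uptake).

    Evaluates the combined rational expression

        (Ca - tau) * alpha0 * gx * PAR / ((Ca + 2*tau)*gx + PAR*alpha0)
            - b0 * exp(b * Tsoil)

    directly, without factoring through ``alpha``/``beta``.  Kept as an
    independent cross-check of the factored route: it must equal
    ``gpp(...) - reco(...)`` (equivalently ``-nee(...)``) everywhere.
    """
    scalar = all(np.isscalar(v)
                 for v in (par, t_air, t_soil, alpha0, gx, b0, b))
    par = np.asarray(par, dtype=float)
    alpha0 = np.asarray(alpha0, dtype=float)
    gx = np.asarray(gx, dtype=float)
    tau = np.asarray(compensation_point(t_air, ca), dtype=float)
    denom = np.asarray((ca + 2.0 * tau) * gx + par * alpha0, dtype=float)
    num = (ca - tau) * alpha0 * gx * par
    with np.errstate(divide="ignore", invalid="ignore"):
        gpp_part = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    out = gpp_part - np.asarray(reco(t_soil, b0, b), dtype=float)
    return _maybe_float(out, scalar)
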