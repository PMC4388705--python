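"""Synthetic flux-tower and reflectance scenarios.

Generates complete half-hourly driver/NEE tables and 8-day reflectance
tables with the statistical structure the model assumes: truncated
sinusoidal diurnal PAR modulated by daylength, seasonal + diurnal air
temperature with a lagged, damped soil temperature, and band reflectances
constructed so the derived vegetation indices follow configurable
seasonal curves.  Window-level "true" parameters are linear maps of the
indices / soil temperature plus noise, and NEE is the forward model plus
observation noise — so every downstream stage can be tested against known
truth without any download.

Reflectance construction note: the three indices share four bands, so
exact joint targeting is overdetermined.  NDVI is the primary target
(rho_nir is solved from the red band and the NDVI curve); EVI and LSWI
follow from the constructed bands, with the SWIR band given its own
(moisture-driven, phase-shifted) seasonal curve so LSWI decorrelates from
the greenness indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core, indices, windows
from .errors import InvalidConfigError

FLUX_COLUMNS = ("timestamp", "nee", "par", "t_air", "t_soil", "vwc",
                "precip", "valid")


@dataclass(frozen=True)
class ParameterMap:
    """Generating linear map predictor -> parameter (plus Gaussian noise)."""

    predictor: str
    intercept: float
    slope: float
    noise_sd: float = 0.0


def _default_maps() -> dict[str, ParameterMap]:
    # alpha0/gx/b0 track greenness-type indices, b anti-tracks soil
    # temperature, mirroring the relationships the model is built around
    # intercepts/slopes chosen so parameters stay inside the inversion
    # bounds over the full predictor ranges (no clipping distortion)
    return {
        "alpha0": ParameterMap("lswi", 0.015, 0.035, 0.0008),
        "gx": ParameterMap("evi", 0.003, 0.050, 0.0008),
        "b0": ParameterMap("evi", 0.40, 5.0, 0.08),
        "b": ParameterMap("t_soil", 0.150, -0.004, 0.003),
    }


@dataclass
class ScenarioConfig:
    """Everything needed to generate one reproducible scenario."""

    start: str = "2003-01-01"
    end: str = "2003-12-31"
    latitude: float = 30.5

    par_max: float = 1800.0

    t_air_mean: float = 2.0
    t_air_seasonal_amp: float = 9.0
    t_air_diurnal_amp: float = 14.0
    t_air_peak_doy: float = 205.0
    t_soil_damping: float = 0.75
    t_soil_lag_days: float = 15.0
    t_soil_diurnal_factor: float = 0.45

    # greenness curve (drives NDVI and the red band)
    ndvi_base: float = 0.12
    ndvi_amp: float = 0.40
    green_peak_doy: float = 215.0
    green_width_days: float = 50.0
    red_base: float = 0.12
    red_green_drop: float = 0.05
    #: wet-soil darkening of the red band; decorrelates EVI from NDVI
    #: (the NDVI target is unaffected because rho_nir is solved from red)
    red_wet_drop: float = 0.03
    blue_reflectance: float = 0.04

    # moisture curve (drives the SWIR band, hence LSWI, and soil water)
    swir_base: float = 0.26
    swir_wet_drop: float = 0.13
    wet_peak_doy: float = 230.0
    wet_width_days: float = 60.0
    vwc_base: float = 0.06
    vwc_amp: float = 0.22
    #: day-to-day AR(1) log-fluctuation of soil water (rain pulses and
    #: drydowns); gives GPP suppression within-window structure the model
    #: cannot absorb into rescaled parameters
    vwc_daily_sd: float = 0.0
    vwc_daily_rho: float = 0.7

    maps: dict[str, ParameterMap] = field(default_factory=_default_maps)
    nee_noise_sd: float = 0.5

    #: fractional per-year jitter of the greenness/moisture amplitudes,
    #: giving inter-annual contrast for multi-year calibrations
    year_jitter: float = 0.0

    drought: bool = False
    drought_vwc_factor: float = 0.35
    #: GPP is multiplied by clip(vwc / vwc_crit, 0, 1) when suppression is
    #: on — a process the NEE model itself does not represent
    gpp_suppression: bool = False
    vwc_crit: float = 0.10

    qc_fail_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if pd.Timestamp(self.end) < pd.Timestamp(self.start):
            raise InvalidConfigError("end precedes start")
        for name in ("par_max", "t_air_seasonal_amp", "t_air_diurnal_amp",
                     "ndvi_amp", "swir_wet_drop", "vwc_amp", "vwc_daily_sd", "nee_noise_sd",
                     "year_jitter", "qc_fail_fraction"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")
        if not 0 <= self.qc_fail_fraction < 1:
            raise InvalidConfigError("qc_fail_fraction must be in [0, 1)")
        span_days = (pd.Timestamp(self.end) - pd.Timestamp(self.start)).days
        if span_days + 1 < windows.WINDOW_DAYS:
            raise InvalidConfigError("scenario must span at least one window")


@dataclass
class SyntheticScenario:
    """Outputs of one scenario run."""

    flux: pd.DataFrame
    reflectance: pd.DataFrame
    truth: pd.DataFrame
    config: ScenarioConfig


def _year_amp_factors(cfg: ScenarioConfig, year: int) -> tuple[float, float]:
    """Deterministic per-year amplitude factors, independent of call order."""
    if cfg.year_jitter == 0:
        return 1.0, 1.0
    r = np.random.default_rng([cfg.seed, int(year)])
    green, wet = 1.0 + cfg.year_jitter * r.uniform(-1, 1, size=2)
    return float(green), float(wet)


def _seasonal_curves(cfg: ScenarioConfig, when: pd.Series):
    """Greenness and wetness in [0, 1] for a datetime series."""
    doy = when.dt.dayofyear.to_numpy(dtype=float)
    years = when.dt.year.to_numpy()
    gf = np.ones(len(when))
    wf = np.ones(len(when))
    for year in np.unique(years):
        g, w = _year_amp_factors(cfg, int(year))
        sel = years == year
        gf[sel], wf[sel] = g, w
    green = gf * np.exp(-((doy - cfg.green_peak_doy) / cfg.green_width_days) ** 2)
    wet = wf * np.exp(-((doy - cfg.wet_peak_doy) / cfg.wet_width_days) ** 2)
    return green, wet


def _solar_par(cfg: ScenarioConfig, when: pd.Series) -> np.ndarray:
    doy = when.dt.dayofyear.to_numpy(dtype=float)
    hour = (when.dt.hour + when.dt.minute / 60.0).to_numpy(dtype=float)
    decl = np.deg2rad(23.45) * np.sin(2 * np.pi * (284 + doy) / 365.0)
    lat = np.deg2rad(cfg.latitude)
    hang = np.deg2rad(15.0 * (hour - 12.0))
    cosz = (np.sin(lat) * np.sin(decl)
            + np.cos(lat) * np.cos(decl) * np.cos(hang))
    return cfg.par_max * np.clip(cosz, 0.0, None)


def generate_drivers(cfg: ScenarioConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Half-hourly drivers (NEE left NaN) and clean 8-day reflectances."""
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    ts = pd.date_range(pd.Timestamp(cfg.start),
                       pd.Timestamp(cfg.end) + pd.Timedelta(hours=23, minutes=30),
                       freq="30min")
    when = pd.Series(ts)
    doy = when.dt.dayofyear.to_numpy(dtype=float)
    hour = (when.dt.hour + when.dt.minute / 60.0).to_numpy(dtype=float)

    par = _solar_par(cfg, when)
    seasonal = np.cos(2 * np.pi * (doy - cfg.t_air_peak_doy) / 365.25)
    diurnal = np.cos(2 * np.pi * (hour - 14.0) / 24.0)
    t_air = (cfg.t_air_mean + cfg.t_air_seasonal_amp * seasonal
             + 0.5 * cfg.t_air_diurnal_amp * diurnal)
    soil_seasonal = np.cos(
        2 * np.pi * (doy - cfg.t_air_peak_doy - cfg.t_soil_lag_days) / 365.25)
    t_soil = (cfg.t_air_mean
              + cfg.t_soil_damping * cfg.t_air_seasonal_amp * soil_seasonal
              + cfg.t_soil_diurnal_factor * 0.5 * cfg.t_air_diurnal_amp
              * np.cos(2 * np.pi * (hour - 16.0) / 24.0))

    _, wet = _seasonal_curves(cfg, when)
    amp = cfg.vwc_amp * (cfg.drought_vwc_factor if cfg.drought else 1.0)
    vwc = cfg.vwc_base + amp * wet
    if cfg.vwc_daily_sd > 0:
        day_ord = when.dt.normalize().factorize()[0]
        n_days = day_ord.max() + 1
        shocks = rng.normal(0.0, cfg.vwc_daily_sd, n_days)
        wiggle = np.empty(n_days)
        level = 0.0
        for i in range(n_days):
            level = cfg.vwc_daily_rho * level + shocks[i]
            wiggle[i] = level
        vwc = vwc * np.exp(wiggle[day_ord])
    # sparse precipitation events in the wet season; not load-bearing
    precip = np.where(rng.random(len(ts)) < 0.01 * wet,
                      rng.gamma(2.0, 1.5, len(ts)), 0.0)

    flux = pd.DataFrame({
        "timestamp": ts, "nee": np.nan, "par": par, "t_air": t_air,
        "t_soil": t_soil, "vwc": vwc, "precip": precip, "valid": True,
    })

    grid = windows.window_range(cfg.start, cfg.end)
    mid = pd.Series(grid + pd.Timedelta(days=windows.WINDOW_DAYS / 2))
    green_w, wet_w = _seasonal_curves(cfg, mid)
    ndvi_target = cfg.ndvi_base + cfg.ndvi_amp * green_w
    rho_red = np.clip(cfg.red_base - cfg.red_green_drop * green_w
                      - cfg.red_wet_drop * wet_w, 0.02, None)
    rho_nir = rho_red * (1 + ndvi_target) / (1 - ndvi_target)
    rho_swir = cfg.swir_base - cfg.swir_wet_drop * wet_w
    reflectance = pd.DataFrame({
        "date": grid,
        "rho_blue": cfg.blue_reflectance,
        "rho_red": rho_red,
        "rho_nir": rho_nir,
        "rho_swir": rho_swir,
        "qc_ok": True,
    })
    return flux, reflectance


def window_truth(cfg: ScenarioConfig, flux: pd.DataFrame,
                 reflectance: pd.DataFrame,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Window-level predictors and generating parameters."""
    vi = indices.compute_indices(reflectance)
    vi["window_start"] = pd.to_datetime(reflectance["date"]).to_numpy()

    rec = flux.copy()
    rec["window_start"] = windows.window_start(rec["timestamp"])
    env = rec.groupby("window_start")[["t_air", "t_soil", "vwc"]].mean()
    truth = vi.merge(env, on="window_start", how="left")

    from .inversion import DEFAULT_BOUNDS
    for name, pmap in cfg.maps.items():
        x = truth[pmap.predictor].to_numpy(dtype=float)
        noise = rng.normal(0.0, pmap.noise_sd, len(truth)) \
            if pmap.noise_sd > 0 else 0.0
        lo, hi = DEFAULT_BOUNDS[name]
        truth[name] = np.clip(pmap.intercept + pmap.slope * x + noise, lo, hi)
    cols = (["window_start", "ndvi", "evi", "lswi", "t_air", "t_soil", "vwc"]
            + list(cfg.maps))
    return truth[cols]


def generate_fluxes(flux: pd.DataFrame, reflectance: pd.DataFrame,
                    cfg: ScenarioConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill in NEE from window-level true parameters; return (flux, truth)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    truth = window_truth(cfg, flux, reflectance, rng)

    rec = flux.copy()
    wcol = windows.window_start(rec["timestamp"])
    theta = truth.set_index("window_start")[["alpha0", "gx", "b0", "b"]]
    th = theta.reindex(wcol).to_numpy(dtype=float)

    par = rec["par"].to_numpy(dtype=float)
    gpp_val = core.gpp(par, rec["t_air"].to_numpy(dtype=float),
                       th[:, 0], th[:, 1])
    reco_val = core.reco(rec["t_soil"].to_numpy(dtype=float),
                         th[:, 2], th[:, 3])
    if cfg.gpp_suppression:
        factor = np.clip(rec["vwc"].to_numpy(dtype=float) / cfg.vwc_crit,
                         0.0, 1.0)
        gpp_val = gpp_val * factor
    noise = rng.normal(0.0, cfg.nee_noise_sd, len(rec)) \
        if cfg.nee_noise_sd > 0 else 0.0
    rec["nee"] = reco_val - gpp_val + noise
    return rec, truth


def corrupt_reflectance(reflectance: pd.DataFrame, fraction: float,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Randomly fail QC on a fraction of composites (cloud-like noise)."""
    out = reflectance.copy()
    bad = rng.random(len(out)) < fraction
    out.loc[bad, "qc_ok"] = False
    for col in indices.REFLECTANCE_COLUMNS:
        out.loc[bad, col] = np.clip(
            out.loc[bad, col] * rng.uniform(0.2, 3.0, int(bad.sum())), 0, 1)
    return out


def generate_scenario(cfg: ScenarioConfig) -> SyntheticScenario:
    """Drivers + fluxes + truth from a single seeded random stream."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    flux, reflectance = generate_drivers(cfg, rng)
    flux, truth = generate_fluxes(flux, reflectance, cfg, rng)
    if cfg.qc_fail_fraction > 0:
        reflectance = corrupt_reflectance(reflectance, cfg.qc_fail_fraction, rng)
    return SyntheticScenario(flux=flux, reflectance=reflectance, truth=truth,
                             config=cfg)
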