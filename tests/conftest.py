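import numpy as np
import pandas as pd
import pytest

from neeflux import calibration, core, indices, inversion, synthetic


@pytest.fixture(scope="session")
def driver_year():
    """One noiseless year of synthetic drivers (no NEE)."""
    cfg = synthetic.ScenarioConfig(start="2003-01-01", end="2003-12-31",
                                   nee_noise_sd=0.0, seed=2)
    flux, refl = synthetic.generate_drivers(cfg)
    return flux, refl


@pytest.fixture(scope="session")
def midseason_window(driver_year):
    """Drivers of one full 8-day midsummer window (384 half-hours)."""
    flux, _ = driver_year
    sub = flux[(flux["timestamp"] >= "2003-07-12")
               & (flux["timestamp"] < "2003-07-20")]
    assert len(sub) == 384
    return sub.reset_index(drop=True)


@pytest.fixture(scope="session")
def make_window(midseason_window):
    """Factory: forward-simulate NEE on the midsummer window."""

    def _make(theta, noise_sd=0.0, rng=None):
        d = midseason_window.copy()
        clean = core.nee(d["par"].to_numpy(), d["t_air"].to_numpy(),
                         d["t_soil"].to_numpy(), *theta)
        if noise_sd:
            rng = rng or np.random.default_rng(0)
            clean = clean + rng.normal(0.0, noise_sd, len(d))
        d["nee"] = clean
        return d

    return _make


@pytest.fixture(scope="session")
def calib_scenario():
    """Four-year scenario whose parameters are linear maps of
    LSWI/EVI/EVI/t_soil; years 2003-2005 calibrate, 2006 validates."""
    cfg = synthetic.ScenarioConfig(
        start="2003-01-01", end="2006-12-31", nee_noise_sd=0.2,
        year_jitter=0.15, seed=42)
    return synthetic.generate_scenario(cfg)


@pytest.fixture(scope="session")
def calib_results(calib_scenario):
    """Inversion + calibration artifacts of the calibration years."""
    sc = calib_scenario
    cal_flux = sc.flux[sc.flux["timestamp"].dt.year <= 2005]
    params = inversion.params_to_frame(inversion.invert_series(cal_flux))
    vi = indices.build_index_series(sc.reflectance).rename(
        columns={"date": "window_start"})
    predictors = vi.merge(calibration.window_environment(cal_flux),
                          on="window_start", how="left")
    candidates = calibration.fit_candidates(params, predictors)
    suite = calibration.select_suite(candidates)
    predictors_all = vi.merge(calibration.window_environment(sc.flux),
                              on="window_start", how="left")
    return {
        "params": params, "vi": vi, "predictors": predictors,
        "predictors_all": predictors_all, "candidates": candidates,
        "suite": suite,
    }
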