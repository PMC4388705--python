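"""End-to-end pipeline: indices -> invert -> calibrate -> predict -> validate."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, calibration, core, indices, inversion, io, validation
from .errors import InvalidConfigError

log = logging.getLogger("neeflux")


@dataclass
class PipelineConfig:
    flux_path: str = ""
    reflectance_path: str = ""
    output_dir: str = "neeflux_out"
    ca: float = core.CA_DEFAULT
    min_obs: int = 96
    fix: dict = field(default_factory=dict)
    significance: float = 0.05
    night_par_threshold: float = validation.NIGHT_PAR_THRESHOLD
    min_window_pairs: int = validation.MIN_WINDOW_PAIRS
    fill: str = "linear"
    #: calendar years used to invert+calibrate / to predict+score;
    #: ``None`` means all years for both
    calibration_years: list[int] | None = None
    validation_years: list[int] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise InvalidConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _year_mask(ts: pd.Series, years) -> pd.Series:
    if years is None:
        return pd.Series(True, index=ts.index)
    return ts.dt.year.isin(list(years))


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage, writing each intermediate artifact to disk.

    Returns a mapping stage-name -> artifact path.  Fails fast on the
    first stage error with a stage-named message.
    """
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("read")
        flux = io.read_flux_table(cfg.flux_path)
        reflectance = io.read_reflectance_table(cfg.reflectance_path)
    except Exception as exc:
        raise RuntimeError(f"stage 'read' failed: {exc}") from exc

    try:
        stage("indices")
        vi = indices.build_index_series(reflectance, fill=cfg.fill)
        artifacts["indices"] = out_dir / "indices.csv"
        io.write_index_table(vi, artifacts["indices"])
    except Exception as exc:
        raise RuntimeError(f"stage 'indices' failed: {exc}") from exc

    cal_flux = flux[_year_mask(flux["timestamp"], cfg.calibration_years)]
    val_flux = flux[_year_mask(flux["timestamp"], cfg.validation_years)]
    if len(cal_flux) == 0 or len(val_flux) == 0:
        raise RuntimeError("stage 'split' failed: empty calibration or "
                           "validation subset")

    try:
        stage("invert")
        opts = inversion.InversionOptions(min_obs=cfg.min_obs,
                                          jitter_seed=cfg.seed)
        sets = inversion.invert_series(cal_flux, ca=cfg.ca, options=opts,
                                       fix=cfg.fix or None)
        params = inversion.params_to_frame(sets)
        artifacts["parameters"] = out_dir / "parameters.csv"
        io.write_param_table(params, artifacts["parameters"])
    except Exception as exc:
        raise RuntimeError(f"stage 'invert' failed: {exc}") from exc

    try:
        stage("calibrate")
        vi_windows = vi.rename(columns={"date": "window_start"})
        env = calibration.window_environment(cal_flux)
        predictors = vi_windows.merge(env, on="window_start", how="left")
        candidates = calibration.fit_candidates(params, predictors)
        fallback = {p: float(np.nanmedian(
            params.loc[params["converged"], p])) if params["converged"].any()
            else 0.0 for p in inversion.PARAM_NAMES}
        suite = calibration.select_suite(candidates,
                                         significance=cfg.significance,
                                         fallback=fallback)
        artifacts["calibration"] = out_dir / "calibration.json"
        suite.to_json(artifacts["calibration"])
        artifacts["candidates"] = out_dir / "candidates.csv"
        candidates.to_csv(artifacts["candidates"], index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'calibrate' failed: {exc}") from exc

    try:
        stage("predict")
        env_all = calibration.window_environment(flux)
        predictors_all = vi_windows.merge(env_all, on="window_start",
                                          how="left")
        predicted = calibration.predict_parameters(suite, predictors_all)
        modeled = validation.simulate_series(val_flux, predicted, ca=cfg.ca)
        pred_out = val_flux[["timestamp"]].copy()
        pred_out["nee_model"] = modeled
        artifacts["predictions"] = out_dir / "predictions.csv"
        pred_out.to_csv(artifacts["predictions"], index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'predict' failed: {exc}") from exc

    try:
        stage("validate")
        report = validation.validate(
            modeled, val_flux["nee"], val_flux["par"],
            timestamps=val_flux["timestamp"],
            night_par_threshold=cfg.night_par_threshold,
            min_window_pairs=cfg.min_window_pairs)
        io.write_report(report, out_dir)
        artifacts["report"] = out_dir / "report.json"
    except Exception as exc:
        raise RuntimeError(f"stage 'validate' failed: {exc}") from exc

    manifest = {"config": asdict(cfg), "version": __version__,
                "seed": cfg.seed,
                "stages": {k: str(v) for k, v in artifacts.items()}}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    artifacts["manifest"] = out_dir / "manifest.json"
    return artifacts
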