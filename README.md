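# neeflux

Satellite-driven semi-empirical modelling of net ecosystem CO₂ exchange
(NEE) for half-hourly eddy-covariance sites.

The model estimates NEE as the balance of two components:

- **GPP** — a rectangular-hyperbola light response whose initial slope
  (apparent quantum use efficiency) and asymptote (apparent maximum
  photosynthetic rate) derive from two parameters, `alpha0` and `gx`,
  through the temperature-dependent CO₂ compensation point;
- **Reco** — a Van't Hoff exponential of 5-cm soil temperature with
  reference rate `b0` (at 0 °C) and sensitivity `b`.

Sign convention: `NEE = Reco − GPP`, negative = net uptake.

The package covers the full workflow:

| module | what it does |
| --- | --- |
| `neeflux.core` | forward model (GPP, Reco, NEE) |
| `neeflux.indices` | NDVI / EVI / LSWI from 8-day band reflectance, QC screening, gap filling |
| `neeflux.inversion` | bounded nonlinear least-squares estimation of (`alpha0`, `gx`, `b0`, `b`) per 8-day window from half-hourly NEE, with analytic standard errors |
| `neeflux.calibration` | OLS regression of inverted parameters on vegetation indices / environment, predictor selection, parameter prediction |
| `neeflux.validation` | forward simulation of half-hourly NEE and R² scoring (overall, day/night, per-window seasonal series) |
| `neeflux.synthetic` | reproducible synthetic flux + reflectance scenarios with known generating parameters |
| `neeflux.io`, `neeflux.pipeline`, `neeflux.cli` | CSV dialects, YAML-configured pipeline, command line |

## Command line

```sh
# generate a synthetic scenario (flux.csv, reflectance.csv, truth.csv)
neeflux simulate --config scenario.yaml --out demo/

# stage by stage
neeflux indices   --in demo/reflectance.csv --out demo/indices.csv
neeflux invert    --flux demo/flux.csv --out demo/params.csv [--fix b=0.1]
neeflux calibrate --params demo/params.csv --indices demo/indices.csv \
                  --flux demo/flux.csv --out demo/calib.json
neeflux predict   --flux demo/flux.csv --calib demo/calib.json \
                  --indices demo/indices.csv --out demo/pred.csv
neeflux validate  --pred demo/pred.csv --flux demo/flux.csv --report demo/report

# or everything from one YAML config
neeflux run --config pipeline.yaml
```

Pipeline config keys: `flux_path`, `reflectance_path`, `output_dir`,
`ca` (ambient CO₂, default 350 µmol mol⁻¹), `min_obs`, `fix`,
`significance`, `night_par_threshold`, `calibration_years`,
`validation_years`, `seed`. Exit codes: 0 ok, 1 user error, 2 internal.

## Table dialects (plain CSV, ISO-8601 timestamps)

- flux: `timestamp, nee, par, t_air, t_soil, vwc, precip, valid`
- reflectance: `date, rho_blue, rho_red, rho_nir, rho_swir, qc_ok`
- indices: `date, ndvi, evi, lswi, filled`
- parameters: `window_start, alpha0, se_alpha0, gx, se_gx, b0, se_b0, b,
  se_b, n_obs, rss, converged`

All series align on the 8-day composite grid anchored at day-of-year
1, 9, …, 361.

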