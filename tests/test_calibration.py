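import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neeflux import calibration, windows
from neeflux.errors import InsufficientDataError


def make_params(window_starts, alpha0, converged=True):
    n = len(window_starts)
    return pd.DataFrame({
        "window_start": window_starts,
        "alpha0": alpha0,
        "gx": np.full(n, 0.01), "b0": np.full(n, 1.0),
        "b": np.full(n, 0.1),
        "converged": converged if np.iterable(converged) else [converged] * n,
    })


@pytest.fixture
def grid():
    return windows.window_range("2003-01-01", "2003-12-27")


class TestFitCandidates:
    def test_perfect_proportionality(self, grid):
        x = np.linspace(0.1, 0.5, len(grid))
        params = make_params(grid, 0.05 * x)
        predictors = pd.DataFrame({"window_start": grid, "lswi": x})
        cand = calibration.fit_candidates(params, predictors,
                                          parameters=("alpha0",),
                                          predictor_names=("lswi",))
        row = cand.iloc[0]
        assert row["r2"] == pytest.approx(1.0, abs=1e-12)
        assert row["slope"] == pytest.approx(0.05, rel=1e-9)
        assert row["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_permuted_predictor_null(self, grid):
        """Independent predictor: r2 near 0, p roughly uniform."""
        rng = np.random.default_rng(17)
        n = 100
        ws = pd.date_range("2003-01-01", periods=n, freq="8D")[:46]
        pvals, r2s = [], []
        for _ in range(200):
            x = rng.normal(size=46)
            y = rng.normal(size=46)
            fit = stats.linregress(x, y)
            pvals.append(fit.pvalue)
            r2s.append(fit.rvalue ** 2)
        assert np.mean(r2s) < 0.05
        # p-values approximately uniform under the null
        assert 0.4 < np.mean(pvals) < 0.6
        assert np.mean(np.array(pvals) < 0.05) < 0.12

    def test_generative_recovery_within_2se(self, grid):
        rng = np.random.default_rng(23)
        x = 0.1 + 0.4 * rng.random(len(grid))
        true_slope, true_icept, noise = 0.05, 0.004, 0.002
        y = true_icept + true_slope * x + rng.normal(0, noise, len(grid))
        params = make_params(grid, y)
        predictors = pd.DataFrame({"window_start": grid, "lswi": x})
        cand = calibration.fit_candidates(params, predictors,
                                          parameters=("alpha0",),
                                          predictor_names=("lswi",))
        fit = stats.linregress(x, y)
        row = cand.iloc[0]
        assert abs(row["slope"] - true_slope) < 2 * fit.stderr
        assert abs(row["intercept"] - true_icept) < 2 * fit.intercept_stderr

    def test_unconverged_windows_excluded(self, grid):
        conv = [True] * len(grid)
        conv[0] = False
        params = make_params(grid, np.linspace(0.01, 0.03, len(grid)),
                             converged=conv)
        predictors = pd.DataFrame({"window_start": grid,
                                   "lswi": np.linspace(0, 1, len(grid))})
        cand = calibration.fit_candidates(params, predictors)
        assert (cand["n"] == len(grid) - 1).all()

    def test_insufficient_pairs(self):
        grid = windows.window_range("2003-01-01", "2003-01-09")
        params = make_params(grid, [0.01, 0.02])
        predictors = pd.DataFrame({"window_start": grid, "lswi": [0.1, 0.2]})
        with pytest.raises(InsufficientDataError):
            calibration.fit_candidates(params, predictors)

    def test_r2_invariant_to_affine_predictor_rescale(self, grid):
        rng = np.random.default_rng(5)
        x = rng.random(len(grid))
        y = 0.01 + 0.02 * x + rng.normal(0, 0.003, len(grid))
        params = make_params(grid, y)
        r2s = []
        for a, b in [(1.0, 0.0), (10.0, -3.0), (0.01, 100.0)]:
            predictors = pd.DataFrame({"window_start": grid,
                                       "lswi": a * x + b})
            cand = calibration.fit_candidates(
                params, predictors, parameters=("alpha0",),
                predictor_names=("lswi",))
            r2s.append(cand["r2"].iloc[0])
        assert np.ptp(r2s) < 1e-12


class TestSelectSuite:
    def make_candidates(self, r2s, ps):
        return pd.DataFrame({
            "parameter": ["alpha0"] * 3,
            "predictor": ["ndvi", "evi", "lswi"],
            "slope": [1.0, 2.0, 3.0],
            "intercept": [0.0, 0.0, 0.0],
            "r2": r2s, "p": ps, "n": [40] * 3,
        })

    def test_argmax_among_significant(self):
        cand = self.make_candidates([0.5, 0.7, 0.3], [0.01, 0.01, 0.01])
        suite = calibration.select_suite(cand)
        assert suite.functions["alpha0"].predictor == "evi"
        assert suite.functions["alpha0"].r2 == 0.7

    def test_insignificant_best_skipped(self):
        cand = self.make_candidates([0.5, 0.7, 0.3], [0.01, 0.50, 0.01])
        suite = calibration.select_suite(cand)
        assert suite.functions["alpha0"].predictor == "ndvi"

    def test_fallback_constant(self):
        cand = self.make_candidates([0.5, 0.7, 0.3], [0.9, 0.9, 0.9])
        suite = calibration.select_suite(cand, fallback={"alpha0": 0.0123})
        f = suite.functions["alpha0"]
        assert f.is_fallback
        assert f.intercept == 0.0123
        assert f.slope == 0.0
        np.testing.assert_allclose(f.predict(np.array([0.0, 5.0])), 0.0123)

    def test_selected_r2_is_maximal(self, calib_results):
        cand = calib_results["candidates"]
        for p, f in calib_results["suite"].functions.items():
            pool = cand[(cand["parameter"] == p)
                        & (cand["p"] < 0.05)
                        & cand["predictor"].isin(
                            calibration.DEFAULT_ALLOWED[p])]
            assert f.r2 >= pool["r2"].max() - 1e-12


class TestPredictParameters:
    def test_zero_slope_constant(self, grid):
        funcs = {p: calibration.CalibrationFunction(p, "ndvi", i * 0.01, 0.0)
                 for i, p in enumerate(("alpha0", "gx", "b0", "b"))}
        suite = calibration.CalibrationSuite(functions=funcs)
        predictors = pd.DataFrame({"window_start": grid,
                                   "ndvi": np.linspace(0, 1, len(grid))})
        out = calibration.predict_parameters(suite, predictors)
        assert (out["gx"] == 0.01).all()
        assert (out["b0"] == 0.02).all()

    def test_round_trip_refit_identical(self, grid):
        rng = np.random.default_rng(31)
        x = 0.1 + 0.4 * rng.random(len(grid))
        funcs = {
            "alpha0": calibration.CalibrationFunction("alpha0", "lswi",
                                                      0.004, 0.05),
            "gx": calibration.CalibrationFunction("gx", "lswi", 0.002, 0.03),
            "b0": calibration.CalibrationFunction("b0", "lswi", 0.5, 2.0),
            "b": calibration.CalibrationFunction("b", "lswi", 0.15, -0.05),
        }
        suite = calibration.CalibrationSuite(functions=funcs)
        predictors = pd.DataFrame({"window_start": grid, "lswi": x})
        predicted = calibration.predict_parameters(suite, predictors)
        predicted["converged"] = True
        cand = calibration.fit_candidates(predicted, predictors,
                                          predictor_names=("lswi",))
        for p, f in funcs.items():
            row = cand[cand["parameter"] == p].iloc[0]
            assert row["slope"] == pytest.approx(f.slope, rel=1e-9)
            assert row["intercept"] == pytest.approx(f.intercept,
                                                     rel=1e-9, abs=1e-12)

    def test_clipped_to_bounds(self, grid):
        funcs = {p: calibration.CalibrationFunction(p, "ndvi", 0.0, 1.0)
                 for p in ("alpha0", "gx", "b0", "b")}
        suite = calibration.CalibrationSuite(functions=funcs)
        predictors = pd.DataFrame({"window_start": grid,
                                   "ndvi": np.full(len(grid), 5.0)})
        out = calibration.predict_parameters(suite, predictors)
        assert (out["alpha0"] == 0.125).all()
        assert (out["b"] == 0.5).all()

    def test_missing_predictor_flagged(self, grid):
        funcs = {p: calibration.CalibrationFunction(p, "ndvi", 0.01, 0.0)
                 for p in ("alpha0", "gx", "b0", "b")}
        suite = calibration.CalibrationSuite(functions=funcs)
        ndvi = np.linspace(0, 1, len(grid))
        ndvi[3] = np.nan
        predictors = pd.DataFrame({"window_start": grid, "ndvi": ndvi})
        out = calibration.predict_parameters(suite, predictors)
        assert not out["complete"].iloc[3]
        assert out["complete"].drop(3).all()


class TestSuiteSerialization:
    def test_json_round_trip(self, tmp_path, calib_results):
        suite = calib_results["suite"]
        path = tmp_path / "calib.json"
        suite.to_json(path)
        back = calibration.CalibrationSuite.from_json(path)
        for p, f in suite.functions.items():
            g = back.functions[p]
            assert g.predictor == f.predictor
            assert g.slope == pytest.approx(f.slope, rel=1e-12)
            assert g.intercept == pytest.approx(f.intercept, rel=1e-12)
            assert g.n == f.n


def test_window_environment_means(driver_year):
    flux, _ = driver_year
    env = calibration.window_environment(flux)
    assert {"window_start", "t_air", "t_soil", "vwc"} <= set(env.columns)
    w = pd.Timestamp("2003-07-12")
    sub = flux[(flux["timestamp"] >= w)
               & (flux["timestamp"] < w + pd.Timedelta(days=8))]
    row = env[env["window_start"] == w].iloc[0]
    assert row["t_soil"] == pytest.approx(sub["t_soil"].mean(), rel=1e-12)
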