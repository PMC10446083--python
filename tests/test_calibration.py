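"""Robust calibration fits, prediction intervals and stability detection."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from pocpipe.calibration import (calibrate_runs, detect_unstable_run,
                                 fit_calibration, predict_mass)


def _standards(x, mass, run=1, set_="calibration"):
    return pd.DataFrame(dict(run=run, set=set_, known_mass_ug=mass, response=x))


def test_recovers_line_with_intercept_against_ols(rng):
    x = np.linspace(10, 600, 11)
    mass = 0.5 * x + 3.0 + rng.normal(0, 0.1, x.size)
    fit = fit_calibration(_standards(x, mass))
    ols = sm.OLS(mass, sm.add_constant(x)).fit()
    assert fit.intercept is not None
    assert fit.slope == pytest.approx(ols.params[1], abs=2 * ols.bse[1])
    assert fit.intercept == pytest.approx(ols.params[0], abs=2 * ols.bse[0])


def test_single_gross_outlier_barely_moves_robust_slope(rng):
    x = np.linspace(5, 300, 11)
    mass = 2.0 * x + rng.normal(0, 0.5, x.size)
    clean_slope = sm.OLS(mass, sm.add_constant(x)).fit().params[1]
    contaminated = mass.copy()
    contaminated[7] *= 10.0
    robust_slope = fit_calibration(_standards(x, contaminated)).slope
    ols_slope = sm.OLS(contaminated, sm.add_constant(x)).fit().params[1]
    assert abs(robust_slope - clean_slope) / clean_slope < 0.01
    assert abs(ols_slope - clean_slope) > abs(robust_slope - clean_slope)


def test_nonsignificant_intercept_is_pruned(rng):
    x = np.linspace(5, 300, 11)
    noise = rng.normal(0, 0.05, x.size)
    noise -= noise.mean()  # keep the example away from the 0.05 borderline
    mass = 2.0 * x + noise
    ols = sm.OLS(mass, sm.add_constant(x)).fit()
    assert ols.pvalues[0] > 0.05  # oracle agrees the intercept is noise
    fit = fit_calibration(_standards(x, mass))
    assert fit.intercept is None
    assert fit.slope == pytest.approx(2.0, rel=1e-3)


def test_noise_free_standards_reproduce_line_exactly():
    x = np.linspace(5, 300, 11)
    fit = fit_calibration(_standards(x, 2.0 * x + 1.0))
    assert fit.slope == pytest.approx(2.0, abs=1e-12)
    assert fit.intercept == pytest.approx(1.0, abs=1e-9)
    assert fit.sigma_res == 0.0
    mass, sigma = predict_mass(fit, 50.0)
    assert mass == pytest.approx(101.0, abs=1e-9)
    assert sigma == 0.0


def test_slope_robust_to_single_mass_perturbation(rng):
    x = np.linspace(5, 300, 22)
    mass = 1.8 * x + 2.0 + rng.normal(0, 1.0, x.size)
    base = fit_calibration(_standards(x, mass)).slope
    bumped = mass.copy()
    bumped[4] *= 1.5
    pert = fit_calibration(_standards(x, bumped)).slope
    assert abs(pert - base) / base < 0.05


def test_too_few_or_degenerate_standards_rejected():
    with pytest.raises(ValueError, match=">= 3"):
        fit_calibration(_standards(np.array([1.0, 2.0]), np.array([2.0, 4.0])))
    x = np.full(5, 3.0)
    with pytest.raises(ValueError, match="zero variance"):
        fit_calibration(_standards(x, 2 * x))


def test_sigma_m_minimal_at_mean_response_and_monotone(rng):
    x = np.linspace(5, 300, 11)
    mass = 2.0 * x + 1.0 + rng.normal(0, 2.0, x.size)
    fit = fit_calibration(_standards(x, mass))
    grid = fit.x_mean + np.linspace(0, 120, 25)
    _, sig_up = predict_mass(fit, grid)
    assert np.all(np.diff(sig_up) > 0)
    _, sig_down = predict_mass(fit, fit.x_mean - np.linspace(0, 120, 25))
    assert np.all(np.diff(sig_down) > 0)
    _, at_mean = predict_mass(fit, fit.x_mean)
    assert at_mean == pytest.approx(
        fit.t_crit * fit.sigma_res * np.sqrt(1 + 1 / fit.n_standards))


def test_prediction_interval_formula_frozen_example():
    # n_S = 11, sigma_res = 1 ug, s_x = 10, x - xbar = 20:
    # sigma_M = t(9 df, 84%) * sqrt(1 + 1/11 + 400/1000) = 1.28515...
    from pocpipe.calibration import CalibrationFit
    fit = CalibrationFit(run_id=1, slope=1.0, intercept=None, sigma_res=1.0,
                         n_standards=11, x_mean=0.0, x_sd=10.0,
                         t_crit=float(stats.t.ppf(0.84, 9)), slope_se=0.0,
                         intercept_se=None, x_range=(-30.0, 30.0))
    _, sigma = predict_mass(fit, 20.0)
    assert sigma == pytest.approx(1.2851507594088374, abs=1e-12)


def test_prediction_interval_matches_statsmodels_oracle(rng):
    # 50 random designs: with sigma_res set to the OLS residual SE, the PI
    # half-width must match statsmodels' observation interval to 1e-10.
    from pocpipe.calibration import _make_fit
    for _ in range(50):
        n = int(rng.integers(5, 20))
        x = np.sort(rng.uniform(0, 100, n))
        if np.ptp(x) < 1.0:
            continue
        mass = rng.uniform(0.5, 3) * x + rng.uniform(-5, 5) \
            + rng.normal(0, rng.uniform(0.5, 3), n)
        ols = sm.OLS(mass, sm.add_constant(x)).fit()
        s = np.sqrt(ols.scale)
        fit = _make_fit(1, ols.params[1], ols.params[0], s, x, n,
                        ols.bse[1], ols.bse[0])
        x_new = rng.uniform(-20, 120)
        frame = ols.get_prediction(
            np.array([[1.0, x_new]])).summary_frame(alpha=0.32)
        half = float(frame["obs_ci_upper"].iloc[0] - frame["mean"].iloc[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            _, sigma = predict_mass(fit, x_new)
        assert sigma == pytest.approx(half, abs=1e-10)


def test_extrapolation_warns_not_errors(rng):
    x = np.linspace(5, 300, 11)
    fit = fit_calibration(_standards(x, 2 * x + rng.normal(0, 1, x.size)))
    with pytest.warns(UserWarning, match="extrapolating"):
        predict_mass(fit, 10 * fit.x_range[1])


def test_identical_standard_sets_are_stable(rng):
    x = np.linspace(5, 300, 11)
    mass = 2 * x + 1 + rng.normal(0, 1, x.size)
    f1 = fit_calibration(_standards(x, mass), prune_intercept=False)
    f2 = fit_calibration(_standards(x, mass), prune_intercept=False)
    assert detect_unstable_run(f1, f2) is False


def test_diverging_slopes_detected_unstable(rng):
    x = np.linspace(5, 300, 11)
    cal = fit_calibration(
        _standards(x, 2.0 * x + rng.normal(0, 0.5, x.size)))
    stab = fit_calibration(
        _standards(x, 3.0 * x + rng.normal(0, 0.5, x.size)))
    assert detect_unstable_run(cal, stab) is True


def test_mismatched_run_ids_rejected(rng):
    x = np.linspace(5, 300, 11)
    f1 = fit_calibration(_standards(x, 2 * x, run=1))
    f2 = fit_calibration(_standards(x, 2 * x, run=2))
    with pytest.raises(ValueError, match="different runs"):
        detect_unstable_run(f1, f2)


def test_calibrate_runs_flags_configured_unstable_runs(small_cruise,
                                                       small_config):
    ds, _ = small_cruise
    fits = calibrate_runs(ds.standards)
    flagged = {rid for rid, f in fits.items() if not f.stable}
    assert set(small_config.unstable_run_ids) <= flagged
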