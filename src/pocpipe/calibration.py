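"""Per-run robust calibration of the CHN analyser.

Each analytical run carries pre-weighed acetanilide standards whose known
carbon masses are regressed on the instrument response, ``M = m x + b``,
with iteratively reweighted least squares (Tukey bisquare) so that single
aberrant standards do not distort the line.  A non-significant intercept
(p > 0.05) is pruned by a single refit through the origin.  The mass of an
unknown filter is predicted from the line, with a 68% prediction-interval
half-width as its uncertainty:

    sigma_M = t_{1-a/2; n_S-2} * sigma_res
              * sqrt(1 + 1/n_S + (x - xbar)^2 / ((n_S - 1) s_x^2)),  a = 0.32,

where ``sigma_res`` is the robust (interpercentile) standard deviation of
the mass residuals.  Runs whose calibration and stability standards yield
significantly different coefficients are flagged unstable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .uncertainty import robust_sd

__all__ = [
    "CalibrationFit",
    "fit_calibration",
    "predict_mass",
    "detect_unstable_run",
    "calibrate_runs",
]

PI_ALPHA = 0.32  # 68% prediction interval, the one-standard-deviation notion
INTERCEPT_P = 0.05
_EXACT_TOL = 1e-9


@dataclass
class CalibrationFit:
    """Fitted response-to-mass line for one CHN run."""

    run_id: int | str
    slope: float  # ug per response unit
    intercept: float | None  # ug; None when pruned
    sigma_res: float  # robust SD of mass residuals, ug
    n_standards: int
    x_mean: float
    x_sd: float  # SD (ddof=1) of standard responses
    t_crit: float  # Student-t quantile, n_S - 2 df, alpha = 0.32
    slope_se: float
    intercept_se: float | None
    x_range: tuple[float, float]
    stable: bool = True

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")
        if self.n_standards < 3:
            raise ValueError("need >= 3 standards")
        if self.sigma_res < 0 or self.x_sd <= 0:
            raise ValueError("sigma_res >= 0 and x_sd > 0 required")


def fit_calibration(standards: pd.DataFrame, include_stability: bool = True,
                    run_id=None, prune_intercept: bool = True) -> CalibrationFit:
    """Fit the robust calibration line for one run's standards.

    ``standards`` needs ``known_mass_ug`` and ``response`` columns plus,
    when ``include_stability`` is False and a ``set`` column is present,
    only the ``calibration`` rows are used.  The intercept is kept only if
    significant (p <= 0.05 under the robust fit); on an exactly collinear
    (noise-free) set the generating line is reproduced and the intercept is
    kept whenever it is non-zero.
    """
    df = standards
    if not include_stability and "set" in df.columns:
        df = df[df["set"] == "calibration"]
    mass = df["known_mass_ug"].to_numpy(dtype=float)
    x = df["response"].to_numpy(dtype=float)
    if run_id is None and "run" in df.columns and len(df):
        run_id = df["run"].iloc[0]
    if mass.size < 3:
        raise ValueError("need >= 3 standards to fit a calibration")
    if np.std(x) == 0.0:
        raise ValueError("standard responses have zero variance")

    scale = float(np.max(np.abs(mass))) or 1.0
    # Noise-free fast path: an exact line (possibly through the origin).
    slope_exact, icept_exact = np.polyfit(x, mass, 1)
    resid_exact = mass - (slope_exact * x + icept_exact)
    if np.max(np.abs(resid_exact)) < _EXACT_TOL * scale:
        intercept = float(icept_exact)
        keep = abs(intercept) > _EXACT_TOL * scale
        return _make_fit(run_id, float(slope_exact),
                         intercept if keep else None, 0.0, x, mass.size,
                         0.0, 0.0 if keep else None)

    exog = sm.add_constant(x)
    rlm = sm.RLM(mass, exog, M=sm.robust.norms.TukeyBiweight()).fit()
    p_int = float(rlm.pvalues[0])
    if not prune_intercept or not np.isfinite(p_int) or p_int <= INTERCEPT_P:
        slope = float(rlm.params[1])
        intercept = float(rlm.params[0])
        slope_se = float(rlm.bse[1])
        intercept_se = float(rlm.bse[0])
        resid = mass - (slope * x + intercept)
    else:
        rlm0 = sm.RLM(mass, x[:, None], M=sm.robust.norms.TukeyBiweight()).fit()
        slope = float(rlm0.params[0])
        intercept = None
        slope_se = float(rlm0.bse[0])
        intercept_se = None
        resid = mass - slope * x
    sigma_res = robust_sd(resid)
    return _make_fit(run_id, slope, intercept, sigma_res, x, mass.size,
                     slope_se, intercept_se)


def _make_fit(run_id, slope, intercept, sigma_res, x, n, slope_se,
              intercept_se) -> CalibrationFit:
    t_crit = float(stats.t.ppf(1.0 - PI_ALPHA / 2.0, n - 2))
    return CalibrationFit(
        run_id=run_id, slope=slope, intercept=intercept, sigma_res=sigma_res,
        n_standards=n, x_mean=float(np.mean(x)), x_sd=float(np.std(x, ddof=1)),
        t_crit=t_crit, slope_se=slope_se, intercept_se=intercept_se,
        x_range=(float(np.min(x)), float(np.max(x))),
    )


def predict_mass(fit: CalibrationFit, response):
    """Predicted carbon mass and 68%-PI uncertainty for instrument responses.

    Returns ``(mass, sigma_M)`` (scalars for scalar input).  Responses far
    outside the standards' range trigger an extrapolation warning, not an
    error (the prediction interval already widens away from the mean).
    """
    x = np.asarray(response, dtype=float)
    lo, hi = fit.x_range
    span = hi - lo
    if np.any((x < lo - 0.1 * span) | (x > hi + 0.1 * span)):
        warnings.warn(
            f"run {fit.run_id}: response outside the calibrated range "
            f"[{lo:.3g}, {hi:.3g}]; extrapolating", stacklevel=2)
    mass = fit.slope * x + (fit.intercept or 0.0)
    n = fit.n_standards
    sigma = fit.t_crit * fit.sigma_res * np.sqrt(
        1.0 + 1.0 / n + (x - fit.x_mean) ** 2 / ((n - 1) * fit.x_sd**2)
    )
    if mass.ndim == 0:
        return float(mass), float(sigma)
    return mass, sigma


def detect_unstable_run(fit_cal: CalibrationFit, fit_stab: CalibrationFit,
                        alpha: float = 0.05,
                        test_intercept: bool = False) -> bool:
    """True when the two standard sets disagree on the calibration line.

    Welch-style two-sample t-test on the slope (by default; with
    ``test_intercept`` also on the intercept when both fits retain one);
    significance at ``alpha`` flags the run unstable.
    """
    if fit_cal.run_id != fit_stab.run_id:
        raise ValueError(
            f"fits from different runs: {fit_cal.run_id} vs {fit_stab.run_id}")

    def differs(est1, se1, df1, est2, se2, df2) -> bool:
        var = se1**2 + se2**2
        if var == 0.0:
            return est1 != est2
        t_stat = (est1 - est2) / np.sqrt(var)
        denom = (se1**4 / df1 if df1 > 0 else 0.0) + \
                (se2**4 / df2 if df2 > 0 else 0.0)
        df = var**2 / denom if denom > 0 else df1 + df2
        p = 2.0 * stats.t.sf(abs(t_stat), df)
        return bool(p < alpha)

    df1 = fit_cal.n_standards - 2
    df2 = fit_stab.n_standards - 2
    if differs(fit_cal.slope, fit_cal.slope_se, df1,
               fit_stab.slope, fit_stab.slope_se, df2):
        return True
    if test_intercept and fit_cal.intercept is not None \
            and fit_stab.intercept is not None:
        return differs(fit_cal.intercept, fit_cal.intercept_se, df1,
                       fit_stab.intercept, fit_stab.intercept_se, df2)
    return False


def calibrate_runs(standards: pd.DataFrame, include_stability: bool = True,
                   alpha: float = 0.05) -> dict:
    """Fit every run and flag unstable ones.

    The working fit pools calibration and stability standards (the default);
    stability is judged by fitting the two sets separately and comparing
    coefficients.  Returns ``{run_id: CalibrationFit}``.
    """
    fits = {}
    for run_id, grp in standards.groupby("run"):
        fit = fit_calibration(grp, include_stability=include_stability,
                              run_id=run_id)
        cal = grp[grp["set"] == "calibration"] if "set" in grp else grp
        stab = grp[grp["set"] == "stability"] if "set" in grp else grp.iloc[0:0]
        if len(cal) >= 3 and len(stab) >= 3:
            # compare un-pruned fits: pruning the intercept would fold it
            # into the slope differently for the two mass ranges and mimic
            # instability
            fit.stable = not detect_unstable_run(
                fit_calibration(cal, run_id=run_id, prune_intercept=False),
                fit_calibration(stab, run_id=run_id, prune_intercept=False),
                alpha=alpha,
            )
        fits[run_id] = fit
    return fits
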