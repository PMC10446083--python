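"""Duplicate-based experimental uncertainty and the modelled budget.

Experimental route: duplicate concentration pairs give scaled differences
``delta = (D1 - D2)/sqrt(2)`` and relative differences ``delta_r = delta /
mean(D1, D2)``; the whole-dataset relative uncertainty per zone is the robust
standard deviation (half the P84-P16 interpercentile range) of the
``delta_r``, and each sample's experimental uncertainty is
``sigma_C = sigma_r * C``.

Modelled route (standard propagation of uncertainty): per-sample components
for the filtered volume, the calibration prediction interval and the
laboratory contamination, assembled into a budget of relative contributions
``u_x = sigma_C(x) / sigma_C`` with an unquantified remainder.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "robust_sd",
    "scaled_difference",
    "build_duplicate_pairs",
    "estimate_sigma_r",
    "sigma_c_experimental",
    "volume_uncertainty",
    "sigma_c_volume",
    "calibration_uncertainty",
    "contamination_uncertainty",
    "estimate_mass_correlation",
    "assemble_budget",
]

SQRT2 = math.sqrt(2.0)


def robust_sd(values: Iterable[float]) -> float:
    """Half the P84-P16 interpercentile range (linear interpolation).

    Equals the standard deviation for Gaussian data while resisting
    outliers.  Requires at least two finite values.
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("robust_sd needs at least 2 finite values")
    p16, p84 = np.percentile(arr, [16.0, 84.0])
    return float((p84 - p16) / 2.0)


def scaled_difference(d1, d2):
    """Scaled and relative duplicate differences.

    ``delta = (D1 - D2)/sqrt(2)`` (the single-measurement uncertainty implied
    by one pair) and ``delta_r = delta / mean(D1, D2)``; ``delta_r`` is NaN
    when the pair mean is zero.  Accepts scalars or arrays.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    delta = (d1 - d2) / SQRT2
    dbar = (d1 + d2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        delta_r = np.where(dbar != 0.0, delta / dbar, np.nan)
    if delta.ndim == 0:
        return float(delta), float(delta_r)
    return delta, delta_r


def build_duplicate_pairs(samples: pd.DataFrame,
                          unstable_runs: Iterable[int] = ()) -> pd.DataFrame:
    """Link each duplicate sample to its partner by shared station + depth.

    ``samples`` is the processed wide table (must carry ``station``,
    ``depth_m``, ``run``, ``zone``, ``concentration``, ``is_duplicate``).
    Returns one row per pair with d1/d2/dbar/delta/delta_r/zone and an
    ``excluded`` flag for pairs from unstable CHN runs.  Ties (several
    candidate partners) are broken by record order.
    """
    unstable = set(unstable_runs)
    main = samples[~samples["is_duplicate"]]
    rows = []
    for _, dup in samples[samples["is_duplicate"]].iterrows():
        partner = main[
            (main["station"] == dup["station"])
            & (main["depth_m"] == dup["depth_m"])
        ]
        if partner.empty:
            raise ValueError(
                f"duplicate {dup['sample_id']} has no partner at station "
                f"{dup['station']} depth {dup['depth_m']}"
            )
        p = partner.iloc[0]
        d1, d2 = float(p["concentration"]), float(dup["concentration"])
        delta, delta_r = scaled_difference(d1, d2)
        rows.append(
            dict(
                sample_id_1=p["sample_id"], sample_id_2=dup["sample_id"],
                run=p["run"], station=p["station"], depth_m=p["depth_m"],
                zone=p["zone"], d1=d1, d2=d2, dbar=(d1 + d2) / 2.0,
                delta=delta, delta_r=delta_r,
                excluded=(p["run"] in unstable) or (dup["run"] in unstable),
            )
        )
    return pd.DataFrame(rows)


def _pair_frame(pairs: pd.DataFrame) -> pd.DataFrame:
    df = pairs.copy()
    if "dbar" not in df:
        df["dbar"] = (df["d1"] + df["d2"]) / 2.0
    if "delta" not in df:
        df["delta"], df["delta_r"] = scaled_difference(df["d1"].to_numpy(),
                                                       df["d2"].to_numpy())
    if "excluded" not in df:
        df["excluded"] = False
    return df


def estimate_sigma_r(pairs: pd.DataFrame, by_zone: bool = True
                     ) -> tuple[dict[str, float], pd.DataFrame]:
    """Whole-dataset relative uncertainty per zone from duplicate pairs.

    Pairs flagged ``excluded`` (unstable CHN runs) and pairs with
    non-positive mean concentration are dropped (the latter with a warning).
    Returns ``(sigma_r, diagnostics)`` where ``diagnostics`` holds, per zone,
    the correlations of |delta| and |delta_r| against the pair mean together
    with ordinary least-squares fit lines (slope/intercept), which reveal
    whether the absolute differences scale with concentration while the
    relative ones do not.
    """
    df = _pair_frame(pairs)
    df = df[~df["excluded"].astype(bool)]
    bad = df["dbar"] <= 0
    if bad.any():
        logger.warning("dropping %d duplicate pairs with non-positive mean",
                       int(bad.sum()))
        df = df[~bad]
    groups = df.groupby("zone") if by_zone else [("all", df)]
    sigma_r: dict[str, float] = {}
    diag_rows = []
    for zone, g in groups:
        if len(g) < 2:
            raise ValueError(f"need >= 2 usable duplicate pairs in zone {zone!r}")
        sigma_r[zone] = robust_sd(g["delta_r"].to_numpy())
        row = dict(zone=zone, n_pairs=len(g))
        for label, y in (("delta", g["delta"].abs()),
                         ("delta_r", g["delta_r"].abs())):
            if g["dbar"].nunique() > 1 and y.nunique() > 1:
                r, p = stats.pearsonr(g["dbar"], y)
                fit = stats.linregress(g["dbar"], y)
                row.update({f"r_{label}": r, f"p_{label}": p,
                            f"slope_{label}": fit.slope,
                            f"intercept_{label}": fit.intercept})
            else:
                row.update({f"r_{label}": np.nan, f"p_{label}": np.nan,
                            f"slope_{label}": np.nan,
                            f"intercept_{label}": np.nan})
        diag_rows.append(row)
    return sigma_r, pd.DataFrame(diag_rows)


def sigma_c_experimental(concentration, sigma_r: float):
    """Per-sample experimental uncertainty ``sigma_C = sigma_r * C`` (mg/m3).

    Taken as a magnitude: negative concentrations (aDOC exceeding uPOC)
    yield ``sigma_r * |C|``.
    """
    if sigma_r < 0:
        raise ValueError("sigma_r must be >= 0")
    return np.abs(np.asarray(concentration, dtype=float)) * sigma_r


def volume_uncertainty(n_bottles, sigma_vn: float = 0.010):
    """Combined volume uncertainty sigma_V = sigma_Vn * sqrt(n) (L).

    Equal per-bottle reading uncertainties (default 10 mL, half a graduation
    mark) add in quadrature over the ``n`` bottles used for one filtration.
    """
    n = np.asarray(n_bottles)
    if np.any(n < 1):
        raise ValueError("n_bottles must be >= 1")
    if sigma_vn < 0:
        raise ValueError("sigma_vn must be >= 0")
    out = sigma_vn * np.sqrt(n.astype(float))
    return float(out) if out.ndim == 0 else out


def sigma_c_volume(mass, volume, sigma_v):
    """Concentration uncertainty from the volume term: ``M * sigma_V / V**2``."""
    volume = np.asarray(volume, dtype=float)
    if np.any(volume <= 0):
        raise ValueError("volume must be > 0")
    out = np.abs(np.asarray(mass, dtype=float)) * np.asarray(sigma_v) / volume**2
    return float(out) if out.ndim == 0 else out


def calibration_uncertainty(sigma_m_upoc, sigma_m_adoc, r, volume):
    """Concentration uncertainty from the calibration prediction intervals.

    ``sigma_C(M) = sqrt(s_u^2 + s_a^2 - 2 s_u s_a r) / V`` where ``r`` is the
    correlation between the predicted uPOC and aDOC masses.  Symmetric in the
    two sigmas and non-negative for any |r| <= 1.
    """
    s1 = np.asarray(sigma_m_upoc, dtype=float)
    s2 = np.asarray(sigma_m_adoc, dtype=float)
    r = np.asarray(r, dtype=float)
    volume = np.asarray(volume, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("|r| must be <= 1")
    if np.any(volume <= 0):
        raise ValueError("volume must be > 0")
    quad = np.maximum(s1**2 + s2**2 - 2.0 * s1 * s2 * np.clip(r, -1, 1), 0.0)
    out = np.sqrt(quad) / volume
    return float(out) if out.ndim == 0 else out


def contamination_uncertainty(acidified_masses, volume):
    """Concentration uncertainty from laboratory handling/contamination.

    ``sigma_eta`` is the standard error of the mean of the acidified filter
    blank masses in the sample's desiccator; the uPOC and aDOC filters are
    assumed equally affected, so ``sigma_C(eta) = sqrt(2) * sigma_eta / V``.
    """
    arr = np.asarray(acidified_masses, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 acidified blank masses")
    volume = np.asarray(volume, dtype=float)
    if np.any(volume <= 0):
        raise ValueError("volume must be > 0")
    sigma_eta = float(np.std(arr, ddof=1) / math.sqrt(arr.size))
    out = SQRT2 * sigma_eta / volume
    return float(out) if out.ndim == 0 else out


def estimate_mass_correlation(upoc_masses, adoc_masses,
                              pooled: tuple | None = None) -> float:
    """Pearson correlation of predicted uPOC and aDOC masses within a run.

    Falls back to the pooled cross-run correlation (``pooled`` pair of
    arrays) when fewer than 3 pairs are available, logging the fallback.
    The result is clamped to [-1, 1]; 0 when degenerate.
    """
    u = np.asarray(upoc_masses, dtype=float)
    a = np.asarray(adoc_masses, dtype=float)
    if u.size < 3:
        if pooled is not None:
            logger.info("fewer than 3 pairs in run; using pooled correlation")
            return estimate_mass_correlation(*pooled)
        return 0.0
    if np.std(u) == 0.0 or np.std(a) == 0.0:
        return 0.0
    r = float(np.corrcoef(u, a)[0, 1])
    if not np.isfinite(r):
        return 0.0
    return float(np.clip(r, -1.0, 1.0))


def assemble_budget(sigma_c, sigma_c_v, sigma_c_m, sigma_c_eta,
                    residual_mode: str = "linear") -> pd.DataFrame:
    """Relative uncertainty contributions and the unquantified remainder.

    ``u_x = sigma_C(x) / sigma_C`` per component.  The unquantified share is
    reported under both conventions — ``linear``: ``1 - sum(u_x)`` (the
    budget table's arithmetic) and ``variance``:
    ``sqrt(max(0, 1 - sum(u_x^2)))`` — with ``residual_mode`` selecting which
    one populates the ``unquantified`` column.  Samples with non-positive
    ``sigma_c`` get NaN contributions and ``undefined=True``.
    """
    if residual_mode not in ("linear", "variance"):
        raise ValueError("residual_mode must be 'linear' or 'variance'")
    sc = np.atleast_1d(np.asarray(sigma_c, dtype=float))
    comps = [np.broadcast_to(np.asarray(c, dtype=float), sc.shape)
             for c in (sigma_c_v, sigma_c_m, sigma_c_eta)]
    ok = sc > 0
    safe = np.where(ok, sc, np.nan)
    u_v, u_m, u_eta = (c / safe for c in comps)
    total = u_v + u_m + u_eta
    linear = 1.0 - total
    variance = np.sqrt(np.maximum(0.0, 1.0 - (u_v**2 + u_m**2 + u_eta**2)))
    out = pd.DataFrame(
        dict(
            sigma_c=sc, sigma_c_v=comps[0], sigma_c_m=comps[1],
            sigma_c_eta=comps[2], u_v=u_v, u_m=u_m, u_eta=u_eta,
            unquantified_linear=linear, unquantified_variance=variance,
            unquantified=linear if residual_mode == "linear" else variance,
            undefined=~ok,
        )
    )
    return out
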