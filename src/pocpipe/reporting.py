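"""Summary tables, correlations and blank-handling sensitivity scenarios.

All medians are reported with the robust standard deviation (half the
P84-P16 interpercentile range) as their spread, so single aberrant samples
do not distort the summaries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .uncertainty import robust_sd

logger = logging.getLogger(__name__)

__all__ = [
    "summarise",
    "adoc_poc_correlation",
    "particle_loss_correction",
    "blank_scenarios",
    "mass_ratio_summary",
]


def _median_rsd(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    med = float(np.median(values)) if values.size else np.nan
    rsd = robust_sd(values) if values.size >= 2 else 0.0
    return med, rsd


def summarise(df: pd.DataFrame, value_col: str,
              group_cols: list[str] | None = None,
              exclude: pd.Series | None = None) -> pd.DataFrame:
    """Median and robust SD of ``value_col`` per group.

    ``exclude`` is an optional boolean mask of rows to drop first (e.g.
    samples from unstable CHN runs).  Permutation-invariant and stable under
    duplication of the whole table.
    """
    data = df if exclude is None else df[~exclude.astype(bool)]
    rows = []
    if not group_cols:
        med, rsd = _median_rsd(data[value_col].to_numpy())
        rows.append(dict(group="all", n=len(data), median=med, robust_sd=rsd))
    else:
        for key, grp in data.groupby(group_cols, observed=True):
            if not isinstance(key, tuple):
                key = (key,)
            med, rsd = _median_rsd(grp[value_col].to_numpy())
            row = dict(zip(group_cols, key))
            row.update(n=len(grp), median=med, robust_sd=rsd)
            rows.append(row)
    return pd.DataFrame(rows)


def adoc_poc_correlation(samples: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of aDOC vs POC concentration, by grouping.

    aDOC concentration is the blank-corrected aDOC mass over the filtered
    volume.  Reports r and p overall, per zone and per province; groups with
    fewer than 3 samples or degenerate variance get NaN (flagged).
    """
    df = samples.copy()
    df["adoc_concentration"] = df["m_star_adoc"] / df["volume_l"]
    groups: list[tuple[str, pd.DataFrame]] = [("overall", df)]
    groups += [(f"zone:{z}", g) for z, g in df.groupby("zone")]
    if "province" in df.columns:
        groups += [(f"province:{p}", g) for p, g in df.groupby("province")]
    rows = []
    for label, g in groups:
        r = p = np.nan
        if len(g) >= 3 and g["concentration"].nunique() > 1 \
                and g["adoc_concentration"].nunique() > 1:
            r, p = stats.pearsonr(g["adoc_concentration"], g["concentration"])
        rows.append(dict(group=label, n=len(g), r=r, p=p))
    return pd.DataFrame(rows)


def particle_loss_correction(samples: pd.DataFrame,
                             deep_threshold: float = 200.0
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correct POC for particles lost from the upper to the lower filter.

    The typical adsorbed-DOC load is taken as the median corrected aDOC mass
    at depth (>= ``deep_threshold``); any per-sample excess over it is
    treated as lost particles and added back to the POC mass.  Returns the
    per-sample corrected table and a per-zone summary of the percent change.
    """
    deep = samples.loc[samples["depth_m"] >= deep_threshold, "m_star_adoc"]
    if deep.empty:
        raise ValueError(f"no samples at or below {deep_threshold} m")
    deep_median = float(deep.median())
    out = samples.copy()
    out["adoc_excess"] = out["m_star_adoc"] - deep_median
    out["poc_mass_loss_corrected"] = out["poc_mass"] + out["adoc_excess"]
    out["concentration_loss_corrected"] = (
        out["poc_mass_loss_corrected"] / out["volume_l"])
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pct_change"] = 100.0 * (
            out["concentration_loss_corrected"] - out["concentration"]
        ) / out["concentration"]
    summary = summarise(out, "pct_change", ["zone"])
    return out, summary


def blank_scenarios(samples: pd.DataFrame, blanks: dict,
                    deep_threshold: float = 200.0) -> pd.DataFrame:
    """Bias of simplified blank-handling schemes against the paired-blank POC.

    Four scenarios per sample, each a different substitute for the paired
    aDOC blank:

    a. no correction at all (raw uPOC mass / volume),
    b. subtract the median non-acidified (clean filter) blank mass,
    c. subtract the median acidified blank mass,
    d. subtract a single pooled deep (>= 200 m) median aDOC mass.

    Each scenario concentration is compared per sample to the paired-blank
    POC concentration as a percent difference, then summarised per zone as
    median with robust SD.  A missing blank type skips that scenario with a
    warning.
    """
    df = samples
    nac_all = np.concatenate(
        [b.nonacidified_masses for b in blanks.values()]) if blanks else np.array([])
    ac_all = np.concatenate(
        [b.acidified_masses for b in blanks.values()]) if blanks else np.array([])
    deep_adoc = df.loc[df["depth_m"] >= deep_threshold, "m_adoc"]

    scenarios: dict[str, float | None] = {
        "a_raw_upoc": 0.0,
        "b_minus_nonacidified_median": float(np.median(nac_all)) if nac_all.size
        else None,
        "c_minus_acidified_median": float(np.median(ac_all)) if ac_all.size
        else None,
        "d_minus_deep_adoc_median": float(deep_adoc.median())
        if len(deep_adoc) else None,
    }
    rows = []
    for name, subtract in scenarios.items():
        if subtract is None:
            logger.warning("scenario %s skipped: blank values unavailable", name)
            continue
        c_scen = (df["m_upoc"] - subtract) / df["volume_l"]
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * (c_scen - df["concentration"]) / df["concentration"]
        for zone, grp in pct.groupby(df["zone"]):
            med, rsd = _median_rsd(grp.to_numpy())
            rows.append(dict(scenario=name, zone=zone, n=len(grp),
                             median_pct_diff=med, robust_sd_pct=rsd))
    return pd.DataFrame(rows)


def mass_ratio_summary(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-zone aDOC/uPOC corrected-mass ratios, in percent.

    Ratios with a non-positive corrected uPOC mass are flagged (dropped from
    the summary but counted).  The overall min/max range is attached to each
    row.
    """
    df = samples.copy()
    valid = df["m_star_upoc"] > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        df["ratio_pct"] = np.where(
            valid, 100.0 * df["m_star_adoc"] / df["m_star_upoc"], np.nan)
    usable = df[valid]
    lo = float(usable["ratio_pct"].min()) if len(usable) else np.nan
    hi = float(usable["ratio_pct"].max()) if len(usable) else np.nan
    rows = []
    for zone, grp in df.groupby("zone"):
        med, rsd = _median_rsd(grp["ratio_pct"].to_numpy())
        rows.append(dict(zone=zone, n=len(grp),
                         n_flagged=int((~valid[grp.index]).sum()),
                         median_pct=med, robust_sd_pct=rsd,
                         range_min_pct=lo, range_max_pct=hi))
    return pd.DataFrame(rows)
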