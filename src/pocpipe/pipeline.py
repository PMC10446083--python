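"""End-to-end orchestration: calibrate, correct, propagate, budget.

`run_pipeline` takes a :class:`~pocpipe.io.CruiseDataset` and produces the
per-sample POC table (masses, concentrations, zones, detection-limit flags),
the duplicate-pair table with the per-zone experimental uncertainty, the
per-sample modelled uncertainty components and the assembled budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration as cal
from . import core, uncertainty as unc
from .io import CruiseDataset, assign_zone

logger = logging.getLogger(__name__)

__all__ = ["PipelineOptions", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineOptions:
    zone_boundary_m: float = 200.0
    sigma_vn_l: float = 0.010  # per-bottle volume reading uncertainty, L
    include_stability: bool = True
    unstable_alpha: float = 0.05
    exclude_unstable: bool = True  # from sigma_r estimation and summaries
    residual_mode: str = "linear"
    detection_quantile: float = 0.95


@dataclass
class PipelineResult:
    samples: pd.DataFrame
    pairs: pd.DataFrame
    fits: dict
    blanks: dict
    sigma_r: dict[str, float]
    sigma_r_diagnostics: pd.DataFrame
    detection: core.DetectionLimits
    capsule_masses: np.ndarray
    options: PipelineOptions

    @property
    def unstable_runs(self) -> list:
        return [rid for rid, f in self.fits.items() if not f.stable]

    def retained(self) -> pd.DataFrame:
        """Samples kept for reporting (unstable runs dropped when configured,
        duplicates excluded)."""
        df = self.samples[~self.samples["is_duplicate"]]
        if self.options.exclude_unstable:
            df = df[~df["run_unstable"]]
        return df


def _predict_table(df: pd.DataFrame, fits: dict) -> pd.DataFrame:
    """Attach predicted mass (and PI sigma) to a table with run + response."""
    out = df.copy()
    mass = np.empty(len(df))
    sigma = np.empty(len(df))
    for run_id, idx in df.groupby("run").groups.items():
        fit = fits[run_id]
        m, s = cal.predict_mass(fit, df.loc[idx, "response"].to_numpy())
        pos = out.index.get_indexer(idx)
        mass[pos] = np.atleast_1d(m)
        sigma[pos] = np.atleast_1d(s)
    out["mass_ug"] = mass
    out["sigma_m_ug"] = sigma
    return out


def run_pipeline(dataset: CruiseDataset,
                 options: PipelineOptions | None = None) -> PipelineResult:
    opts = options or PipelineOptions()

    # 1. per-run robust calibrations (pooled standards) + stability flags
    fits = cal.calibrate_runs(dataset.standards,
                              include_stability=opts.include_stability,
                              alpha=opts.unstable_alpha)
    unstable = {rid for rid, f in fits.items() if not f.stable}
    if unstable:
        logger.info("unstable CHN runs: %s", sorted(unstable))

    # 2. predicted carbon masses for blanks and filters
    capsules = _predict_table(dataset.capsules, fits)
    nonacid = _predict_table(dataset.nonacidified, fits)
    acid = _predict_table(dataset.acidified, fits)

    samples = dataset.samples()
    upoc_pred = _predict_table(
        samples.rename(columns={"upoc_response": "response"}), fits)
    adoc_pred = _predict_table(
        samples.rename(columns={"adoc_response": "response"}), fits)
    samples = samples.assign(
        m_upoc=upoc_pred["mass_ug"].to_numpy(),
        sigma_m_upoc=upoc_pred["sigma_m_ug"].to_numpy(),
        m_adoc=adoc_pred["mass_ug"].to_numpy(),
        sigma_m_adoc=adoc_pred["sigma_m_ug"].to_numpy(),
    )

    # 3. blank sets per (run, desiccator): capsules and non-acidified blanks
    #    pooled over the run, acidified blanks per desiccator
    blanks: dict[tuple, core.BlankSet] = {}
    cap_by_run = {k: g["mass_ug"].to_numpy() for k, g in capsules.groupby("run")}
    nac_by_run = {k: g["mass_ug"].to_numpy() for k, g in nonacid.groupby("run")}
    for (run_id, dess), g in acid.groupby(["run", "desiccator"]):
        blanks[(run_id, dess)] = core.BlankSet(
            run_id=run_id, desiccator_id=dess,
            capsule_masses=cap_by_run[run_id],
            acidified_masses=g["mass_ug"].to_numpy(),
            nonacidified_masses=nac_by_run[run_id],
        )

    # 4. blank correction, POC mass and concentration, zone assignment
    m_star_u = np.empty(len(samples))
    m_star_a = np.empty(len(samples))
    m_poc = np.empty(len(samples))
    sigma_eta = np.empty(len(samples))
    for i, row in enumerate(samples.itertuples(index=False)):
        bset = blanks[(row.run, row.desiccator)]
        m_star_u[i], m_star_a[i], m_poc[i] = core.blank_correct(
            row.m_upoc, row.m_adoc, bset,
            run_id=row.run, desiccator_id=row.desiccator)
        sigma_eta[i] = bset.sigma_eta
    samples["m_star_upoc"] = m_star_u
    samples["m_star_adoc"] = m_star_a
    samples["poc_mass"] = m_poc
    samples["concentration"] = core.concentration(
        m_poc, samples["volume_l"].to_numpy())
    samples["zone"] = [assign_zone(d, opts.zone_boundary_m)
                       for d in samples["depth_m"]]
    samples["run_unstable"] = samples["run"].isin(unstable)

    # 5. detection limits from all capsules pooled across runs
    detection = core.detection_limits(capsules["mass_ug"].to_numpy(),
                                      quantile=opts.detection_quantile)
    samples["below_ld"] = samples["poc_mass"] < detection.l_d
    samples["adoc_below_ld"] = samples["m_star_adoc"] < detection.l_d

    # 6. duplicate pairs and the per-zone experimental uncertainty
    pairs = unc.build_duplicate_pairs(
        samples, unstable_runs=unstable if opts.exclude_unstable else ())
    sigma_r, diagnostics = unc.estimate_sigma_r(pairs, by_zone=True)
    samples["sigma_c"] = unc.sigma_c_experimental(
        samples["concentration"].to_numpy(),
        1.0,  # placeholder, scaled per zone below
    ) * samples["zone"].map(sigma_r).to_numpy()

    # 7. modelled per-sample uncertainty components
    sigma_v = unc.volume_uncertainty(samples["n_bottles"].to_numpy(),
                                     opts.sigma_vn_l)
    samples["sigma_v_l"] = sigma_v
    samples["sigma_c_v"] = unc.sigma_c_volume(
        samples["poc_mass"].to_numpy(), samples["volume_l"].to_numpy(), sigma_v)

    pooled = (samples["m_upoc"].to_numpy(), samples["m_adoc"].to_numpy())
    r_by_run = {
        run_id: unc.estimate_mass_correlation(
            g["m_upoc"].to_numpy(), g["m_adoc"].to_numpy(), pooled=pooled)
        for run_id, g in samples.groupby("run")
    }
    samples["mass_correlation"] = samples["run"].map(r_by_run)
    samples["sigma_c_m"] = unc.calibration_uncertainty(
        samples["sigma_m_upoc"].to_numpy(), samples["sigma_m_adoc"].to_numpy(),
        samples["mass_correlation"].to_numpy(), samples["volume_l"].to_numpy())

    samples["sigma_eta_ug"] = sigma_eta
    samples["sigma_c_eta"] = (unc.SQRT2 * sigma_eta
                              / samples["volume_l"].to_numpy())

    # 8. the budget
    budget = unc.assemble_budget(
        samples["sigma_c"].to_numpy(), samples["sigma_c_v"].to_numpy(),
        samples["sigma_c_m"].to_numpy(), samples["sigma_c_eta"].to_numpy(),
        residual_mode=opts.residual_mode)
    for col in ("u_v", "u_m", "u_eta", "unquantified_linear",
                "unquantified_variance", "unquantified"):
        samples[col] = budget[col].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        samples["explained_variance_share"] = np.where(
            samples["sigma_c"] > 0,
            (samples["sigma_c_v"]**2 + samples["sigma_c_m"]**2
             + samples["sigma_c_eta"]**2) / samples["sigma_c"]**2,
            np.nan)

    return PipelineResult(
        samples=samples, pairs=pairs, fits=fits, blanks=blanks,
        sigma_r=sigma_r, sigma_r_diagnostics=diagnostics,
        detection=detection, capsule_masses=capsules["mass_ug"].to_numpy(),
        options=opts,
    )
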