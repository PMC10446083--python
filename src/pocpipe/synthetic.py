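"""Synthetic cruise generator with known ground truth.

Emulates the structure of a meridional-transect POC campaign: stations with
paired uPOC/aDOC filters at six depths in the upper 500 m, one duplicate pair
per station, filters batched into CHN runs each carrying calibration and
stability standards, tin-capsule blanks, and per-desiccator acidified and
non-acidified filter blanks.  Every generated record traces back to a
ground-truth entry, so the downstream estimators can be validated without any
field data.

The measurement model, per filter analysed in run ``k``:

* true POC mass        ``M = C(z) * (1 + eps) * V_true`` with
  ``eps ~ N(0, sigma_r_zone)`` (multiplicative subsampling/patchiness noise),
* adsorbed-DOC mass    ``A = a0 + f * M``,
* carrier material     capsule + clean-filter + acidification contamination,
* instrument response  ``x = (mass_total - b_k) / m_k + N(0, s_resp)``.

Standards respond as ``x = (known_mass - b_k)/m_k + noise``, so with all noise
terms at zero the full pipeline recovers the generating line and the true
concentrations exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cruise",
    "simulate_duplicate_pairs",
    "choose_volume",
]

# Latitude bands (degrees N) for the sampled biogeographical provinces and
# the relative surface-POC enrichment of each, qualitatively matching the
# transect pattern (temperate provinces rich, gyres poor).
_PROVINCE_BANDS = (
    ("NADR", 40.0),
    ("NAST", 30.0),
    ("NATL", 15.0),
    ("WTRA", -5.0),
    ("SATL", -35.0),
    ("SSTC", -90.0),
)

_DEFAULT_PROVINCE_FACTOR = {
    "NADR": 2.6,
    "NAST": 1.4,
    "NATL": 0.8,
    "WTRA": 1.0,
    "SATL": 0.75,
    "SSTC": 2.4,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of a synthetic cruise.

    Defaults describe the emulated campaign: 68 stations, six depths in the
    upper 500 m, 16 CHN runs with 11 calibration standards spanning
    5-300 ug C, three tin capsules per run and three acidified plus three
    non-acidified filter blanks per desiccator, filtered volumes of 1-8 L
    dispensed from ~2.2 L bottles, and true zone-wise relative duplicate
    noise of 12% (productive) and 35% (mesopelagic).
    """

    n_stations: int = 68
    depths_per_station: tuple[float, ...] = (5.0, 50.0, 125.0, 190.0, 300.0, 500.0)
    #: surface POC (mg/m3) before the province factor; scalar or one value
    #: per station.
    surface_poc_by_station: float | Sequence[float] = 26.0
    station_poc_lognormal_sd: float = 0.35
    poc_decay_scale: float = 90.0
    deep_poc_floor: float = 6.0
    province_poc_factor: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROVINCE_FACTOR)
    )

    # aDOC adsorption: mass = baseline + fraction * POC mass, which produces
    # the observed positive aDOC-POC correlation.
    adoc_baseline_mass: float = 2.0
    adoc_poc_fraction: float = 0.06

    # Carrier-material blanks (ug C).
    capsule_mass_mean: float = 2.0
    capsule_between_run_sd: float = 0.6
    capsule_mass_sd: float = 0.4
    clean_filter_extra_mass_mean: float = 1.0
    clean_filter_extra_mass_sd: float = 0.3
    acidification_contamination_mean: float = 1.0
    acidification_contamination_sd: float = 0.3

    # Instrument truth.
    instrument_slope: float = 2.0  # ug per response unit
    instrument_intercept: float = 1.0  # ug
    run_slope_jitter_sd: float = 0.03  # lognormal sd of per-run slope factor
    run_intercept_jitter_sd: float = 0.2  # ug
    response_noise_sd: float = 0.4  # response units

    # Batching.
    n_runs: int = 16
    calibration_standards_per_run: int = 11
    stability_standards_per_run: int = 8
    standard_mass_range: tuple[float, float] = (5.0, 300.0)
    n_desiccators_per_run: int = 2
    capsules_per_run: int = 3
    blanks_per_desiccator: int = 3

    # True relative duplicate noise per zone.
    sigma_r_true_productive: float = 0.12
    sigma_r_true_mesopelagic: float = 0.35
    zone_boundary_m: float = 200.0

    # Volume rule: aim for a target filter load, within the admissible range,
    # dispensed from ~2.2 L bottles; recorded volumes carry a per-bottle
    # reading uncertainty of 10 mL (half a graduation mark).
    target_filter_mass_ug: float = 40.0
    volume_range_l: tuple[float, float] = (1.0, 8.0)
    bottle_volume_l: float = 2.2
    volume_noise_sd_per_bottle_l: float = 0.010

    # Unstable-run emulation: stability standards drawn with the slope
    # multiplied by `unstable_slope_factor`, response noise inflated.
    unstable_run_ids: tuple[int, ...] = (4, 12)
    unstable_slope_factor: float = 1.3
    unstable_noise_factor: float = 3.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, (int, float)):
                if not math.isfinite(value):
                    raise ValueError(f"non-finite config value for {f.name!r}")
        sds = [
            self.station_poc_lognormal_sd,
            self.capsule_between_run_sd,
            self.capsule_mass_sd,
            self.clean_filter_extra_mass_sd,
            self.acidification_contamination_sd,
            self.run_slope_jitter_sd,
            self.run_intercept_jitter_sd,
            self.response_noise_sd,
            self.sigma_r_true_productive,
            self.sigma_r_true_mesopelagic,
            self.volume_noise_sd_per_bottle_l,
        ]
        if any(s < 0 for s in sds):
            raise ValueError("all standard deviations must be >= 0")
        masses = [
            self.adoc_baseline_mass,
            self.capsule_mass_mean,
            self.clean_filter_extra_mass_mean,
            self.acidification_contamination_mean,
            self.deep_poc_floor,
            self.target_filter_mass_ug,
        ]
        if any(m < 0 for m in masses):
            raise ValueError("all mean masses must be >= 0")
        if not 0.0 <= self.adoc_poc_fraction < 1.0:
            raise ValueError("adoc_poc_fraction must be in [0, 1)")
        if self.n_stations < 1 or self.n_runs < 1:
            raise ValueError("n_stations and n_runs must be >= 1")
        if self.calibration_standards_per_run < 3:
            raise ValueError("need at least 3 calibration standards per run")
        if min(self.depths_per_station) < 0:
            raise ValueError("depths must be >= 0")
        if self.instrument_slope <= 0:
            raise ValueError("instrument_slope must be > 0")
        lo, hi = self.volume_range_l
        if not 0 < lo <= hi:
            raise ValueError("invalid volume range")

    def noise_free(self) -> "SyntheticConfig":
        """A copy with every random perturbation switched off.

        Truth-level variability (depth profile, per-run calibration lines,
        province factors) is retained; only measurement noise, blank spread,
        duplicate noise and unstable-run drift are removed.
        """
        return replace(
            self,
            station_poc_lognormal_sd=0.0,
            capsule_between_run_sd=0.0,
            capsule_mass_sd=0.0,
            clean_filter_extra_mass_sd=0.0,
            acidification_contamination_sd=0.0,
            response_noise_sd=0.0,
            sigma_r_true_productive=0.0,
            sigma_r_true_mesopelagic=0.0,
            volume_noise_sd_per_bottle_l=0.0,
            unstable_run_ids=(),
        )


@dataclass
class GroundTruth:
    """True quantities behind one synthetic cruise.

    ``samples``: per sample_id the true POC and adsorbed-DOC masses (ug),
    true filtered volume (L) and the realised true concentration (mg/m3).
    ``runs``: per CHN run the true slope/intercept and the unstable flag.
    ``sigma_r``: the true relative duplicate noise per zone.
    """

    samples: pd.DataFrame
    runs: pd.DataFrame
    sigma_r: dict[str, float]


def _province(lat: float) -> str:
    for name, south_edge in _PROVINCE_BANDS:
        if lat >= south_edge:
            return name
    return _PROVINCE_BANDS[-1][0]


def choose_volume(
    expected_concentration: float,
    target_mass_ug: float = 40.0,
    volume_range_l: tuple[float, float] = (1.0, 8.0),
    bottle_volume_l: float = 2.2,
) -> tuple[float, int]:
    """Filtered volume (L) and bottle count for an expected concentration.

    The volume targets ``target_mass_ug`` of carbon on the filter, clipped to
    the admissible range and rounded to 0.1 L (the reading resolution of the
    measuring cylinder); the number of ~2.2 L bottles follows by ceiling
    division.
    """
    if expected_concentration <= 0:
        volume = volume_range_l[1]
    else:
        volume = float(
            np.clip(target_mass_ug / expected_concentration, *volume_range_l)
        )
    volume = round(volume, 1)
    n_bottles = int(math.ceil(volume / bottle_volume_l - 1e-9))
    return volume, max(n_bottles, 1)


def _zone(depth: float, boundary: float) -> str:
    return "mesopelagic" if depth >= boundary else "productive"


def generate_cruise(config: SyntheticConfig):
    """Generate a full synthetic cruise and its ground truth.

    Returns ``(dataset, truth)`` where ``dataset`` is a
    :class:`pocpipe.io.CruiseDataset` in exactly the tabular layout the
    reader consumes, and ``truth`` is a :class:`GroundTruth`.
    Identical config (including ``rng_seed``) yields byte-identical tables.
    """
    from .io import CruiseDataset  # deferred to avoid an import cycle

    config.validate()
    ss = np.random.SeedSequence(config.rng_seed)
    streams = ss.spawn(6)
    rng_field = np.random.default_rng(streams[0])
    rng_cal = np.random.default_rng(streams[1])
    rng_blank = np.random.default_rng(streams[2])
    rng_filters = np.random.default_rng(streams[3])
    rng_dup = np.random.default_rng(streams[4])
    rng_vol = np.random.default_rng(streams[5])

    n_st = config.n_stations
    lats = np.linspace(50.0, -45.0, n_st)
    lons = np.linspace(-20.0, -25.0, n_st) + 8.0 * np.sin(np.linspace(0, 3, n_st))
    provinces = [_province(lat) for lat in lats]
    surface = np.broadcast_to(
        np.asarray(config.surface_poc_by_station, dtype=float), (n_st,)
    )
    station_factor = np.exp(
        rng_field.normal(0.0, config.station_poc_lognormal_sd, size=n_st)
    )

    # Per-run true calibration lines.
    run_ids = np.arange(1, config.n_runs + 1)
    run_slope = config.instrument_slope * np.exp(
        rng_cal.normal(0.0, config.run_slope_jitter_sd, size=config.n_runs)
    )
    run_intercept = config.instrument_intercept + rng_cal.normal(
        0.0, config.run_intercept_jitter_sd, size=config.n_runs
    )
    unstable = np.isin(run_ids, config.unstable_run_ids)
    run_noise = np.where(
        unstable,
        config.response_noise_sd * config.unstable_noise_factor,
        config.response_noise_sd,
    )
    # Run-level capsule residual carbon.
    run_cap_mean = config.capsule_mass_mean + rng_blank.normal(
        0.0, config.capsule_between_run_sd, size=config.n_runs
    )
    run_cap_mean = np.clip(run_cap_mean, 0.0, None)

    station_to_run = {}
    for k, chunk in enumerate(np.array_split(np.arange(n_st), config.n_runs)):
        for s in chunk:
            station_to_run[s] = int(run_ids[k])

    def response(mass: float, k_idx: int, rng, slope_factor: float = 1.0) -> float:
        m = run_slope[k_idx] * slope_factor
        x = (mass - run_intercept[k_idx]) / m
        return x + rng.normal(0.0, run_noise[k_idx])

    # --- standards -------------------------------------------------------
    lo, hi = config.standard_mass_range
    cal_masses = np.linspace(lo, hi, config.calibration_standards_per_run)
    stab_masses = np.linspace(lo, hi, config.stability_standards_per_run + 2)[1:-1]
    std_rows = []
    for k_idx, k in enumerate(run_ids):
        for mass in cal_masses:
            std_rows.append(
                dict(run=k, set="calibration", known_mass_ug=float(mass),
                     response=response(float(mass), k_idx, rng_cal))
            )
        slope_factor = config.unstable_slope_factor if unstable[k_idx] else 1.0
        for mass in stab_masses:
            std_rows.append(
                dict(run=k, set="stability", known_mass_ug=float(mass),
                     response=response(float(mass), k_idx, rng_cal, slope_factor))
            )
    standards = pd.DataFrame(std_rows)

    # --- capsules and filter blanks -------------------------------------
    def capsule_mass(k_idx: int) -> float:
        return float(
            np.clip(run_cap_mean[k_idx] + rng_blank.normal(0.0, config.capsule_mass_sd),
                    0.0, None)
        )

    def filter_extra() -> float:
        return float(
            np.clip(
                config.clean_filter_extra_mass_mean
                + rng_blank.normal(0.0, config.clean_filter_extra_mass_sd),
                0.0, None,
            )
        )

    def contamination() -> float:
        return float(
            np.clip(
                config.acidification_contamination_mean
                + rng_blank.normal(0.0, config.acidification_contamination_sd),
                0.0, None,
            )
        )

    cap_rows, nac_rows, ac_rows = [], [], []
    desiccators: dict[int, list[str]] = {}
    for k_idx, k in enumerate(run_ids):
        for i in range(config.capsules_per_run):
            mass = capsule_mass(k_idx)
            cap_rows.append(
                dict(run=k, item=f"CAP{k:02d}-{i + 1}",
                     response=response(mass, k_idx, rng_blank))
            )
        desiccators[k] = [
            f"R{k:02d}D{j + 1}" for j in range(config.n_desiccators_per_run)
        ]
        for dess in desiccators[k]:
            for i in range(config.blanks_per_desiccator):
                mass = capsule_mass(k_idx) + filter_extra()
                nac_rows.append(
                    dict(run=k, desiccator=dess, item=f"NAC-{dess}-{i + 1}",
                         response=response(mass, k_idx, rng_blank))
                )
                mass = capsule_mass(k_idx) + filter_extra() + contamination()
                ac_rows.append(
                    dict(run=k, desiccator=dess, item=f"AC-{dess}-{i + 1}",
                         response=response(mass, k_idx, rng_blank))
                )
    capsules = pd.DataFrame(cap_rows)
    nonacidified = pd.DataFrame(nac_rows)
    acidified = pd.DataFrame(ac_rows)

    # --- station samples -------------------------------------------------
    prov_factor = dict(config.province_poc_factor)
    sigma_r_zone = {
        "productive": config.sigma_r_true_productive,
        "mesopelagic": config.sigma_r_true_mesopelagic,
    }

    def true_profile(depth: float, st: int) -> float:
        base = (
            surface[st]
            * prov_factor.get(provinces[st], 1.0)
            * math.exp(-depth / config.poc_decay_scale)
            + config.deep_poc_floor
        )
        return station_factor[st] * base

    def expected_profile(depth: float, st: int) -> float:
        # climatological expectation used to choose the volume (no station
        # factor: the operator does not know it)
        return (
            surface[st]
            * prov_factor.get(provinces[st], 1.0)
            * math.exp(-depth / config.poc_decay_scale)
            + config.deep_poc_floor
        )

    upoc_rows, adoc_rows, truth_rows = [], [], []
    dup_upoc_rows, dup_adoc_rows = [], []
    start = pd.Timestamp("2014-09-26 04:00:00")

    def make_sample(sample_id, st, depth, k, k_idx, dess, volume, n_bottles,
                    when, duplicate):
        zone = _zone(depth, config.zone_boundary_m)
        c_field = true_profile(depth, st)
        eps = rng_filters.normal(0.0, sigma_r_zone[zone])
        v_true = volume + rng_vol.normal(
            0.0, config.volume_noise_sd_per_bottle_l * math.sqrt(n_bottles)
        )
        v_true = max(v_true, 0.05)
        poc_mass = c_field * max(1.0 + eps, 0.05) * v_true
        adoc_mass = config.adoc_baseline_mass + config.adoc_poc_fraction * poc_mass
        slope_factor = 1.0
        if unstable[k_idx]:
            slope_factor = 0.5 * (1.0 + config.unstable_slope_factor)
        upoc_total = poc_mass + adoc_mass + capsule_mass(k_idx) + filter_extra() \
            + contamination()
        adoc_total = adoc_mass + capsule_mass(k_idx) + filter_extra() \
            + contamination()
        meta = dict(
            sample_id=sample_id, station=st + 1, depth_m=depth, run=k,
            desiccator=dess, volume_l=volume, n_bottles=n_bottles,
            latitude=round(float(lats[st]), 4), longitude=round(float(lons[st]), 4),
            datetime=when.isoformat(), province=provinces[st],
        )
        u = dict(meta, response=response(upoc_total, k_idx, rng_filters, slope_factor))
        a = dict(
            sample_id=sample_id, station=st + 1, depth_m=depth, run=k,
            desiccator=dess,
            response=response(adoc_total, k_idx, rng_filters, slope_factor),
        )
        (dup_upoc_rows if duplicate else upoc_rows).append(u)
        (dup_adoc_rows if duplicate else adoc_rows).append(a)
        truth_rows.append(
            dict(sample_id=sample_id, station=st + 1, depth_m=depth, zone=zone,
                 true_poc_mass_ug=poc_mass, true_adoc_mass_ug=adoc_mass,
                 true_volume_l=v_true, true_concentration=poc_mass / v_true)
        )

    for st in range(n_st):
        k = station_to_run[st]
        k_idx = int(k - 1)
        dess_list = desiccators[k]
        when = start + pd.Timedelta(hours=12 * st)
        dup_depth_idx = int(rng_dup.integers(0, len(config.depths_per_station)))
        for zi, depth in enumerate(config.depths_per_station):
            volume, n_bottles = choose_volume(
                expected_profile(depth, st),
                config.target_filter_mass_ug,
                config.volume_range_l,
                config.bottle_volume_l,
            )
            dess = dess_list[zi % len(dess_list)]
            sample_id = f"ST{st + 1:03d}Z{zi + 1}"
            make_sample(sample_id, st, depth, k, k_idx, dess, volume, n_bottles,
                        when, duplicate=False)
            if zi == dup_depth_idx:
                # duplicate drawn from the same bottle, acidified in a
                # different desiccator
                other = dess_list[(zi + 1) % len(dess_list)]
                make_sample(f"{sample_id}-DUP", st, depth, k, k_idx, other,
                            volume, n_bottles, when, duplicate=True)

    dataset = CruiseDataset(
        standards=standards,
        capsules=capsules,
        nonacidified=nonacidified,
        acidified=acidified,
        upoc=pd.DataFrame(upoc_rows),
        adoc=pd.DataFrame(adoc_rows),
        dup_upoc=pd.DataFrame(dup_upoc_rows),
        dup_adoc=pd.DataFrame(dup_adoc_rows),
    )
    truth = GroundTruth(
        samples=pd.DataFrame(truth_rows),
        runs=pd.DataFrame(
            dict(run=run_ids, slope=run_slope, intercept=run_intercept,
                 unstable=unstable)
        ),
        sigma_r=dict(sigma_r_zone),
    )
    return dataset, truth


def simulate_duplicate_pairs(
    n_pairs: int,
    sigma_r: float,
    rng: np.random.Generator,
    median_concentration: float = 10.0,
    spread: float = 0.6,
    zone: str = "productive",
) -> pd.DataFrame:
    """Draw duplicate concentration pairs with known relative noise.

    Each pair shares a true concentration drawn lognormally around
    ``median_concentration``; both members receive independent multiplicative
    noise ``(1 + eps)``, ``eps ~ N(0, sigma_r)``.  Used for fast Monte-Carlo
    validation of the duplicate-based uncertainty estimator.
    """
    c_true = median_concentration * np.exp(rng.normal(0.0, spread, size=n_pairs))
    d1 = c_true * (1.0 + rng.normal(0.0, sigma_r, size=n_pairs))
    d2 = c_true * (1.0 + rng.normal(0.0, sigma_r, size=n_pairs))
    return pd.DataFrame(
        dict(d1=d1, d2=d2, zone=zone, excluded=False, true_concentration=c_true)
    )
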