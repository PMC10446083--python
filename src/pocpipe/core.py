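"""Blank corrections, POC masses/concentrations and IUPAC detection limits.

The blank-corrected masses subtract the run's mean tin-capsule carbon and the
acidification increment (acidified minus non-acidified filter-blank means):

    M*_uPOC = M_uPOC - Mbar_cap - (Mbar_ac - Mbar_nac)
    M*_aDOC = M_aDOC - Mbar_cap - (Mbar_ac - Mbar_nac)

Because paired filters share the desiccator and CHN run, the POC mass
reduces identically to ``M = M_uPOC - M_aDOC`` — the implementation computes
M that way, so the identity holds to the last bit.  Concentrations are
``C = M / V`` in ug/L, numerically equal to mg/m3.  Detection limits follow
the IUPAC/ISO blank approach: ``L_C = x0bar + s0 t`` and
``L_D = x0bar + 2 s0 t`` with a one-tailed Student-t quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "BlankSet",
    "DetectionLimits",
    "blank_correct",
    "concentration",
    "detection_limits",
]


@dataclass
class BlankSet:
    """Blank carbon masses shared by one run/desiccator group.

    Capsules and non-acidified filter blanks belong to the CHN run; the
    acidified blanks belong to the desiccator in which the samples were
    acid-fumed.  ``sigma_eta`` is the standard error of the mean of the
    acidified masses, the contamination uncertainty per filter.
    """

    run_id: int | str
    desiccator_id: str
    capsule_masses: np.ndarray
    acidified_masses: np.ndarray
    nonacidified_masses: np.ndarray

    def __post_init__(self) -> None:
        for name in ("capsule_masses", "acidified_masses",
                     "nonacidified_masses"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size < 2:
                raise ValueError(f"{name} needs >= 2 entries")
            object.__setattr__(self, name, arr)

    @property
    def mean_cap(self) -> float:
        return float(np.mean(self.capsule_masses))

    @property
    def mean_ac(self) -> float:
        return float(np.mean(self.acidified_masses))

    @property
    def mean_nac(self) -> float:
        return float(np.mean(self.nonacidified_masses))

    @property
    def sigma_eta(self) -> float:
        return float(np.std(self.acidified_masses, ddof=1)
                     / math.sqrt(self.acidified_masses.size))


@dataclass
class DetectionLimits:
    """IUPAC critical value and detection limit from blank statistics."""

    x0_mean: float  # mean blank mass, ug
    s0: float  # SD of blank masses, ug
    df: int
    t_value: float
    l_c: float  # critical value, ug
    l_d: float  # detection limit, ug


def blank_correct(upoc_mass, adoc_mass, blanks: BlankSet,
                  run_id=None, desiccator_id=None):
    """Blank-corrected masses and the POC mass (all ug).

    Returns ``(M*_uPOC, M*_aDOC, M)``.  When ``run_id``/``desiccator_id``
    are given they must match the blank set — the bias cancellation argument
    only holds for filters processed with these very blanks.  ``M`` is
    computed directly as ``M_uPOC - M_aDOC`` (exact identity).
    """
    if run_id is not None and run_id != blanks.run_id:
        raise ValueError(f"run mismatch: sample {run_id} vs blanks {blanks.run_id}")
    if desiccator_id is not None and desiccator_id != blanks.desiccator_id:
        raise ValueError(
            f"desiccator mismatch: sample {desiccator_id} vs blanks "
            f"{blanks.desiccator_id}")
    upoc = np.asarray(upoc_mass, dtype=float)
    adoc = np.asarray(adoc_mass, dtype=float)
    correction = blanks.mean_cap + (blanks.mean_ac - blanks.mean_nac)
    m_star_u = upoc - correction
    m_star_a = adoc - correction
    m = upoc - adoc
    if m.ndim == 0:
        return float(m_star_u), float(m_star_a), float(m)
    return m_star_u, m_star_a, m


def concentration(mass, volume):
    """POC concentration ``C = M / V`` (ug/L == mg/m3).

    Negative masses (aDOC exceeding uPOC) propagate to negative
    concentrations — preserved, never clipped, so that medians stay
    unbiased.  ``volume`` must be positive.
    """
    volume = np.asarray(volume, dtype=float)
    if np.any(volume <= 0):
        raise ValueError("volume must be > 0")
    out = np.asarray(mass, dtype=float) / volume
    return float(out) if out.ndim == 0 else out


def detection_limits(blank_masses, quantile: float = 0.95) -> DetectionLimits:
    """Critical value L_C and detection limit L_D from blank masses.

    Uses the ordinary (non-robust) mean and SD of the pooled blank material
    (tin capsules), df = n - 1, and the one-tailed Student-t quantile.
    """
    arr = np.asarray(blank_masses, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("need >= 2 blank masses")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    x0 = float(np.mean(arr))
    s0 = float(np.std(arr, ddof=1))
    df = arr.size - 1
    t_value = float(stats.t.ppf(quantile, df))
    return DetectionLimits(x0_mean=x0, s0=s0, df=df, t_value=t_value,
                           l_c=x0 + s0 * t_value, l_d=x0 + 2.0 * s0 * t_value)
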