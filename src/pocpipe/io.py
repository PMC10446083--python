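"""Read/write the ten-file cruise CSV layout and assemble a linked dataset.

The on-disk layout mirrors the deposited accession: ``Standards.csv``,
``Capsules.csv``, ``NonAcidifiedFilters.csv``, ``AcidifiedFilters.csv``,
``uPOCFilters.csv``, ``aDOCFilters.csv``, ``DuplicateuPOC.csv``,
``DuplicateaDOC.csv`` (plus ``README.txt`` and a pipeline-written
``POC.csv``).  Column headers are resolved through a schema map so that both
the synthetic layout (the default) and the accession layout can be read
without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "CruiseDataset",
    "DEFAULT_SCHEMA",
    "read_cruise",
    "write_cruise",
    "assign_zone",
]

#: file name on disk for each dataset attribute
FILE_NAMES = {
    "standards": "Standards.csv",
    "capsules": "Capsules.csv",
    "nonacidified": "NonAcidifiedFilters.csv",
    "acidified": "AcidifiedFilters.csv",
    "upoc": "uPOCFilters.csv",
    "adoc": "aDOCFilters.csv",
    "dup_upoc": "DuplicateuPOC.csv",
    "dup_adoc": "DuplicateaDOC.csv",
}

#: canonical -> on-disk column names per table; override entries to adapt to
#: a different deposited header row (e.g. via the YAML config's `schema:` key)
DEFAULT_SCHEMA: dict[str, dict[str, str]] = {
    "standards": {c: c for c in ("run", "set", "known_mass_ug", "response")},
    "capsules": {c: c for c in ("run", "item", "response")},
    "nonacidified": {c: c for c in ("run", "desiccator", "item", "response")},
    "acidified": {c: c for c in ("run", "desiccator", "item", "response")},
    "upoc": {
        c: c
        for c in (
            "sample_id", "station", "depth_m", "run", "desiccator", "response",
            "volume_l", "n_bottles", "latitude", "longitude", "datetime",
            "province",
        )
    },
    "adoc": {
        c: c
        for c in ("sample_id", "station", "depth_m", "run", "desiccator",
                  "response")
    },
}
DEFAULT_SCHEMA["dup_upoc"] = dict(DEFAULT_SCHEMA["upoc"])
DEFAULT_SCHEMA["dup_adoc"] = dict(DEFAULT_SCHEMA["adoc"])

_NUMERIC = {
    "standards": ("known_mass_ug", "response"),
    "capsules": ("response",),
    "nonacidified": ("response",),
    "acidified": ("response",),
    "upoc": ("depth_m", "response", "volume_l", "n_bottles", "latitude",
             "longitude"),
    "adoc": ("depth_m", "response"),
}
_NUMERIC["dup_upoc"] = _NUMERIC["upoc"]
_NUMERIC["dup_adoc"] = _NUMERIC["adoc"]

_README = """Synthetic cruise dataset (generated by pocpipe).

Standards.csv            calibration + stability standards per CHN run
Capsules.csv             empty tin capsules per CHN run
NonAcidifiedFilters.csv  clean GF/F filter blanks (per run and desiccator)
AcidifiedFilters.csv     acid-fumed GF/F filter blanks (per run and desiccator)
uPOCFilters.csv          upper (particle) filters with station metadata
aDOCFilters.csv          lower (adsorbed-DOC blank) filters, paired by sample_id
DuplicateuPOC.csv        duplicate upper filters (partner = same station+depth)
DuplicateaDOC.csv        duplicate lower filters
ground_truth.csv         true per-sample masses/volumes/concentrations
ground_truth_runs.csv    true per-run calibration lines and unstable flags
POC.csv                  written by `pocpipe process` (final concentrations)

Units: masses ug C, volumes L, depths m, concentrations mg/m3 (== ug/L).
Instrument responses are in arbitrary response units.
"""


@dataclass
class CruiseDataset:
    """In-memory cruise dataset: one DataFrame per deposited table."""

    standards: pd.DataFrame
    capsules: pd.DataFrame
    nonacidified: pd.DataFrame
    acidified: pd.DataFrame
    upoc: pd.DataFrame
    adoc: pd.DataFrame
    dup_upoc: pd.DataFrame
    dup_adoc: pd.DataFrame

    def samples(self) -> pd.DataFrame:
        """Paired uPOC/aDOC wide table (duplicates included and flagged).

        Raises ``ValueError`` listing offending sample ids if any uPOC
        record cannot be paired with exactly one aDOC record from the same
        run and desiccator.
        """
        frames = []
        for u_df, a_df, dup in ((self.upoc, self.adoc, False),
                                (self.dup_upoc, self.dup_adoc, True)):
            if u_df.empty and a_df.empty:
                continue
            u = u_df.rename(columns={"response": "upoc_response"})
            a = a_df.rename(columns={"response": "adoc_response"})[
                ["sample_id", "run", "desiccator", "adoc_response"]
            ]
            merged = u.merge(a, on="sample_id", how="outer",
                             suffixes=("", "_adoc"), indicator=True)
            bad = merged.loc[merged["_merge"] != "both", "sample_id"].tolist()
            dup_ids = a_df["sample_id"][a_df["sample_id"].duplicated()].tolist()
            dup_ids += u_df["sample_id"][u_df["sample_id"].duplicated()].tolist()
            if bad or dup_ids:
                raise ValueError(
                    "unpairable uPOC/aDOC records: "
                    + ", ".join(sorted(set(map(str, bad + dup_ids))))
                )
            mismatch = merged[
                (merged["run"] != merged["run_adoc"])
                | (merged["desiccator"] != merged["desiccator_adoc"])
            ]["sample_id"].tolist()
            if mismatch:
                raise ValueError(
                    "paired filters from different run/desiccator: "
                    + ", ".join(map(str, mismatch))
                )
            merged = merged.drop(columns=["_merge", "run_adoc",
                                          "desiccator_adoc"])
            merged["is_duplicate"] = dup
            frames.append(merged)
        out = pd.concat(frames, ignore_index=True)
        return out


def assign_zone(depth: float, boundary: float = 200.0) -> str:
    """Zone label for a sampling depth: ``mesopelagic`` at/below the boundary
    (default 200 m), ``productive`` above it.  Exhaustive and exclusive."""
    import numpy as np

    d = float(depth)
    if not np.isfinite(d) or d < 0:
        raise ValueError(f"depth must be finite and >= 0, got {depth}")
    return "mesopelagic" if d >= boundary else "productive"


def _apply_schema(df: pd.DataFrame, key: str, schema: Mapping[str, Mapping[str, str]],
                  filename: str) -> pd.DataFrame:
    colmap = dict(DEFAULT_SCHEMA[key])
    colmap.update(schema.get(key, {}))
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise ValueError(f"{filename}: missing columns {missing}")
    df = df.rename(columns={src: canon for canon, src in colmap.items()})
    for col in _NUMERIC[key]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{filename}: non-numeric values in column {col!r} at rows "
                f"{list(bad[:10])}"
            )
        df[col] = coerced if col == "n_bottles" else coerced.astype(float)
    return df[list(colmap)]


def read_cruise(path: str | Path,
                schema: Mapping[str, Mapping[str, str]] | None = None
                ) -> CruiseDataset:
    """Load the eight measurement tables from ``path`` into a linked dataset.

    ``schema`` optionally remaps canonical column names to the on-disk
    headers (per table).  A missing file is a fatal error naming the file;
    unpairable uPOC/aDOC records are reported when :meth:`CruiseDataset.samples`
    is built (called here for validation).
    """
    path = Path(path)
    schema = schema or {}
    tables = {}
    for key, fname in FILE_NAMES.items():
        fpath = path / fname
        if not fpath.exists():
            raise FileNotFoundError(f"required cruise file missing: {fname}")
        tables[key] = _apply_schema(pd.read_csv(fpath), key, schema, fname)
    ds = CruiseDataset(**tables)
    ds.samples()  # validate pairing eagerly
    return ds


def write_cruise(dataset: CruiseDataset, path: str | Path,
                 float_format: str = "%.10g") -> None:
    """Write the dataset tables as RFC-4180 CSV (plus a README.txt)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for f in fields(CruiseDataset):
        df = getattr(dataset, f.name)
        df.to_csv(path / FILE_NAMES[f.name], index=False,
                  float_format=float_format)
    (path / "README.txt").write_text(_README)


def write_ground_truth(truth, path: str | Path,
                       float_format: str = "%.10g") -> None:
    """Write ground-truth tables next to the cruise CSVs."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    truth.samples.to_csv(path / "ground_truth.csv", index=False,
                         float_format=float_format)
    truth.runs.to_csv(path / "ground_truth_runs.csv", index=False,
                      float_format=float_format)
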