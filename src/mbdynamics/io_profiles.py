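"""Reading, filtering and renormalizing merged taxonomic/pathway profiles.

Handles MetaPhlAn4-style merged relative-abundance tables (rows are
pipe-delimited clade lineages, columns are samples, optional ``#`` comment
header lines) and HUMAnN3-style pathway tables, plus the per-sample
metadata and per-patient survival tables used downstream.

The prevalence filter retains features present in at least 20% of baseline
samples and at least 10% of post-baseline samples (both thresholds
inclusive); "present" means a strictly positive relative abundance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "METADATA_FIELDS",
    "read_merged_profile",
    "read_metadata",
    "read_survival",
    "prevalence_filter",
    "renormalize",
    "write_results",
]

#: metadata columns required before modeling
METADATA_FIELDS = [
    "sample_id",
    "patient_id",
    "visit",
    "days_since_first_infusion",
    "pfs12",
    "therapy",
    "colitis",
    "other_irae",
    "ppi",
    "antibiotics",
    "prior_targeted",
    "center",
    "age",
    "sex",
    "bmi",
]


@dataclass
class AbundanceTable:
    """Features x samples relative-abundance matrix.

    ``df`` is indexed by feature ID (clade or pathway string) with one
    column per sample; values are per-sample proportions.
    """

    df: pd.DataFrame
    level: str = "SGB"

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            dups = self.df.index[self.df.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature IDs: {dups[:5]}")
        if self.df.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        if (self.df.values < 0).any():
            raise ValueError("negative abundance values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.df.copy(), self.level)


def _is_sgb_row(clade: str) -> bool:
    last = clade.split("|")[-1]
    return last.startswith("t__")


def read_merged_profile(path, level: str = "SGB") -> AbundanceTable:
    """Read a merged MetaPhlAn4/HUMAnN3 abundance TSV.

    The first non-comment line is the header (first column holds clade or
    pathway names).  For ``level='SGB'`` only rows whose lineage terminates
    in a ``t__`` label are kept (MetaPhlAn's terminal SGB rank, including
    unclassified SGB groups).  Percent-scaled tables are rescaled to
    proportions.
    """
    if level not in ("SGB", "pathway"):
        raise ValueError(f"unknown level: {level!r}")
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
    else:
        raise ValueError(f"{path}: no header line found (all lines are comments)")
    header = lines[body_start].rstrip("\n").split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: malformed header at line {body_start + 1}: need >=2 columns")
    df = pd.read_csv(
        io.StringIO("".join(lines[body_start:])), sep="\t", index_col=0, float_precision="round_trip"
    )
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric abundance value ({exc})") from exc
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative abundance values")
    if level == "SGB":
        df = df.loc[[f for f in df.index if _is_sgb_row(str(f))]]
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated feature row {dup!r}")
    # percent-scaled tables (columns summing near 100) -> proportions
    col_sums = df.sum(axis=0)
    if len(col_sums) and col_sums.max() > 1.5:
        df = df / 100.0
    return AbundanceTable(df, level=level)


def read_metadata(path) -> pd.DataFrame:
    """Read the per-sample metadata TSV and check the required fields."""
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_FIELDS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample_id rows")
    bad = set(meta["visit"].unique()) - {0, 1, 2, 3}
    if bad:
        raise ValueError(f"{path}: visit values outside 0-3: {sorted(bad)}")
    return meta


def read_survival(path) -> pd.DataFrame:
    surv = pd.read_csv(path, sep="\t")
    for col in ("patient_id", "time", "event"):
        if col not in surv.columns:
            raise ValueError(f"{path}: missing survival column {col!r}")
    if (surv["time"] <= 0).any():
        raise ValueError(f"{path}: non-positive survival times")
    return surv


def prevalence_filter(
    tab: AbundanceTable,
    meta: pd.DataFrame,
    baseline_min: float = 0.20,
    longitudinal_min: float = 0.10,
) -> AbundanceTable:
    """Keep features present (>0) in >= ``baseline_min`` of visit-0 samples
    and >= ``longitudinal_min`` of visit>0 samples (inclusive thresholds)."""
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    samples = [s for s in tab.sample_ids if s in meta.index]
    base = [s for s in samples if meta.loc[s, "visit"] == 0]
    longi = [s for s in samples if meta.loc[s, "visit"] > 0]
    if not base:
        raise ValueError("no baseline (visit 0) samples for prevalence filtering")
    if not longi:
        raise ValueError("no longitudinal (visit > 0) samples for prevalence filtering")
    prev_base = (tab.df[base] > 0).mean(axis=1)
    prev_longi = (tab.df[longi] > 0).mean(axis=1)
    # nudge for float-representation of thresholds like 0.2 (inclusive rule)
    keep = (prev_base >= baseline_min - 1e-12) & (prev_longi >= longitudinal_min - 1e-12)
    return AbundanceTable(tab.df.loc[keep].copy(), tab.level)


def renormalize(tab: AbundanceTable) -> AbundanceTable:
    """Re-close each sample so its column sums to 1."""
    sums = tab.df.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample columns: {list(zero.index)}")
    return AbundanceTable(tab.df / sums, tab.level)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a tabular result as TSV with full float precision."""
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")
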