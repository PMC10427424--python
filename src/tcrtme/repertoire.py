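"""TCR-beta clonotype tables: VDJtools-style I/O, productive-CDR3 QC, richness and clonality.

A repertoire sample is a table of clonotypes (CDR3 amino-acid sequence plus V/D/J
segment calls) with observed template counts.  Diversity is summarised by

* richness  -- the number of unique productive clonotypes, and
* clonality -- ``1 - H / ln(R)`` where ``H`` is the Shannon entropy of the clone
  frequency distribution and ``R`` the richness.  Clonality 0 means every template
  carries a distinct clonotype (maximally diverse); 1 means a monoclonal repertoire.

A CDR3 amino-acid sequence is *productive* when it contains no stop (``*``) or
frameshift (``_``) symbol, is at least 5 residues long, starts with ``C`` and ends
with ``F`` or ``W``; everything else is excluded from clonotype analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, UndefinedValueError, UsageError

#: canonical column order of the on-disk tab-separated format
VDJTOOLS_COLUMNS = ["count", "freq", "cdr3nt", "cdr3aa", "v", "d", "j"]

#: accepted header spellings, lower-cased (VDJtools and common vendor exports)
_COLUMN_ALIASES: Mapping[str, str] = {
    "count": "count",
    "#count": "count",
    "clonecount": "count",
    "templates": "count",
    "freq": "freq",
    "frequency": "freq",
    "clonefraction": "freq",
    "cdr3nt": "cdr3nt",
    "nseqcdr3": "cdr3nt",
    "cdr3aa": "cdr3aa",
    "aaseqcdr3": "cdr3aa",
    "v": "v",
    "vgene": "v",
    "allvhitswithscore": "v",
    "d": "d",
    "dgene": "d",
    "j": "j",
    "jgene": "j",
}

#: clonotype identity keys -> the columns that define them
KEY_FIELDS: Mapping[str, tuple[str, ...]] = {
    "aa_vj": ("cdr3aa", "v", "j"),
    "aa": ("cdr3aa",),
    "nt_vj": ("cdr3nt", "v", "j"),
}

COMPARTMENTS = ("tumor", "blood")
TIMEPOINTS = ("baseline", "W3", "W6", "post_surgery")


def is_productive(cdr3aa: str) -> bool:
    """Apply the productive-CDR3 rule to a single amino-acid sequence."""
    if not isinstance(cdr3aa, str) or len(cdr3aa) < 5:
        return False
    if "*" in cdr3aa or "_" in cdr3aa:
        return False
    return cdr3aa.startswith("C") and cdr3aa[-1] in "FW"


@dataclass
class ClonotypeTable:
    """One sample's clonotype repertoire plus its sample metadata.

    Parameters
    ----------
    df : DataFrame with (at least) the canonical VDJtools columns.
    patient, compartment, timepoint : sample annotations; compartment must be
        ``tumor`` or ``blood`` when given, timepoint one of ``baseline``, ``W3``,
        ``W6``, ``post_surgery``.
    key : clonotype identity definition (``aa_vj`` by default).
    """

    df: pd.DataFrame
    patient: str | None = None
    compartment: str | None = None
    timepoint: str | None = None
    key: str = "aa_vj"

    def __post_init__(self) -> None:
        if self.key not in KEY_FIELDS:
            raise UsageError(f"unknown clonotype key {self.key!r}; choose from {sorted(KEY_FIELDS)}")
        if self.compartment is not None and self.compartment not in COMPARTMENTS:
            raise UsageError(f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}")
        if self.timepoint is not None and self.timepoint not in TIMEPOINTS:
            raise UsageError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")
        df = self.df.copy()
        for col in ("cdr3nt", "v", "d", "j"):
            if col not in df.columns:
                df[col] = "."
        missing = [c for c in ("count", "cdr3aa") if c not in df.columns]
        if missing:
            raise FormatError(f"clonotype table is missing required column(s): {', '.join(missing)}")
        counts = df["count"]
        if len(df) and not np.allclose(counts, np.round(counts)):
            raise FormatError("column 'count' must contain integer template counts")
        df["count"] = counts.astype(np.int64)
        if len(df) and (df["count"] < 0).any():
            raise DataError("negative clonotype counts")
        total = int(df["count"].sum())
        df["freq"] = df["count"] / total if total > 0 else 0.0
        self.df = df.reset_index(drop=True)[
            VDJTOOLS_COLUMNS + [c for c in df.columns if c not in VDJTOOLS_COLUMNS]
        ]

    # -- basic accessors -------------------------------------------------
    @property
    def depth(self) -> int:
        """Total number of templates in the table."""
        return int(self.df["count"].sum())

    def keys(self) -> pd.Index:
        """Clonotype identity keys as an index of tuples (or strings for 1-field keys)."""
        fields = KEY_FIELDS[self.key]
        if len(fields) == 1:
            return pd.Index(self.df[fields[0]])
        return pd.MultiIndex.from_frame(self.df[list(fields)]).to_flat_index()

    def key_set(self) -> set:
        return set(self.keys())

    def merged(self) -> "ClonotypeTable":
        """Collapse duplicate clonotype keys, summing counts (first row wins elsewhere)."""
        fields = list(KEY_FIELDS[self.key])
        df = self.df
        if df.duplicated(fields).any():
            agg = {c: "first" for c in df.columns if c not in fields + ["count", "freq"]}
            agg["count"] = "sum"
            df = df.groupby(fields, as_index=False, sort=False).agg(agg)
        return replace(self, df=df.copy())

    def frequencies(self) -> pd.Series:
        """Clone frequencies indexed by clonotype key (duplicates merged)."""
        merged = self.merged()
        return pd.Series(merged.df["freq"].to_numpy(), index=merged.keys())

    def __len__(self) -> int:
        return len(self.df)


def read_clonotype_table(
    path,
    patient: str | None = None,
    compartment: str | None = None,
    timepoint: str | None = None,
    key: str = "aa_vj",
) -> ClonotypeTable:
    """Read a VDJtools-style tab-separated clonotype table.

    The header must provide a count and a CDR3aa column (common alias spellings are
    accepted); frequencies are always recomputed from counts.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    renames = {}
    for col in raw.columns:
        canon = _COLUMN_ALIASES.get(col.strip().lower())
        if canon is not None and canon not in renames.values():
            renames[col] = canon
    df = raw.rename(columns=renames)
    for required in ("count", "cdr3aa"):
        if required not in df.columns:
            raise FormatError(
                f"{path}: missing required column '{required}' "
                f"(found: {', '.join(raw.columns)})"
            )
    try:
        df["count"] = pd.to_numeric(df["count"])
    except ValueError as exc:
        raise FormatError(f"{path}: column 'count' is not numeric: {exc}") from exc
    if not np.allclose(df["count"], np.round(df["count"])):
        raise FormatError(f"{path}: column 'count' must contain integer template counts")
    return ClonotypeTable(df, patient=patient, compartment=compartment, timepoint=timepoint, key=key)


def write_clonotype_table(table: ClonotypeTable, path) -> None:
    """Write the canonical tab-separated representation (round-trips with the reader)."""
    table.df[VDJTOOLS_COLUMNS].to_csv(path, sep="\t", index=False)


def filter_productive(table: ClonotypeTable) -> ClonotypeTable:
    """Retain productive CDR3aa records only and renormalise frequencies.

    Emits a warning (not an error) when nothing survives the filter.
    """
    mask = table.df["cdr3aa"].map(is_productive)
    kept = table.df[mask].reset_index(drop=True)
    if len(kept) == 0 and len(table.df) > 0:
        warnings.warn("productive filter removed every clonotype", stacklevel=2)
    return replace(table, df=kept)


def richness(table: ClonotypeTable) -> int:
    """Number of unique clonotype keys (duplicate rows merged first)."""
    return len(table.merged())


def clonality(table: ClonotypeTable) -> float:
    """``1 - H/ln(R)`` on the merged clone frequency distribution.

    Returns 1.0 for a monoclonal table (richness 1), by the documented convention
    that a single clone is the limit of a maximally dominated repertoire.
    """
    merged = table.merged()
    if len(merged) == 0 or merged.depth == 0:
        raise UndefinedValueError("clonality is undefined on an empty repertoire")
    r = len(merged)
    if r == 1:
        return 1.0
    f = merged.df["freq"].to_numpy(dtype=float)
    f = f[f > 0]
    entropy = float(-(f * np.log(f)).sum())
    value = 1.0 - entropy / math.log(r)
    # entropy of a uniform table equals ln(R) only up to rounding
    return min(1.0, max(0.0, value))
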