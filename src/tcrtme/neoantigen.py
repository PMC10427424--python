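"""Neoantigen persistence classes, binding-filter cascade, TCR linkage and TMB.

Neoantigens are classified by the persistence of their source somatic mutation
across treatment: *clearance* (pre-treatment only — eliminated by the immune
system), *novel* (post-treatment only) and *persistent* (both timepoints).
Candidate neoantigens are kept when their predicted MHC affinity is strictly
below 500 nM; TCR-neoantigen pairs are kept when their predicted binding
percentile rank is within the top 2% (boundary inclusive, smaller rank =
stronger predicted binding).  Tumour mutation burden (TMB) is the nonsynonymous
mutation count per megabase of the 33.86 Mb exome panel.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, UndefinedValueError, UsageError

NEOANTIGEN_CLASSES = ("clearance", "novel", "persistent")
PANEL_MB = 33.86


def classify_neoantigens(mutations: pd.DataFrame) -> pd.Series:
    """Class per mutation from its pre/post presence flags.

    ``mutations`` needs boolean ``pre`` and ``post`` columns (indexed or keyed by
    ``mutation_key``); a row with neither flag set is a data error.
    """
    for col in ("pre", "post"):
        if col not in mutations.columns:
            raise UsageError(f"mutation table lacks boolean column {col!r}")
    pre = mutations["pre"].astype(bool)
    post = mutations["post"].astype(bool)
    if (~pre & ~post).any():
        raise DataError("mutation present at neither timepoint")
    cls = np.where(pre & post, "persistent", np.where(pre, "clearance", "novel"))
    index = mutations["mutation_key"] if "mutation_key" in mutations.columns else mutations.index
    return pd.Series(cls, index=index, name="class")


def annotate_classes(neoantigens: pd.DataFrame, mutations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attach the persistence class to each neoantigen via its source mutation.

    When ``mutations`` is omitted the neoantigen table itself must carry the
    pre/post flags.
    """
    df = neoantigens.copy()
    if mutations is not None:
        classes = classify_neoantigens(mutations)
        df["class"] = df["mutation_key"].map(classes)
        if df["class"].isna().any():
            missing = df.loc[df["class"].isna(), "mutation_key"].head().tolist()
            raise DataError(f"neoantigens reference unknown mutations: {missing}")
    else:
        df["class"] = classify_neoantigens(df).to_numpy()
    return df


def filter_binders(neoantigens: pd.DataFrame, threshold_nm: float = 500.0) -> pd.DataFrame:
    """Retain neoantigens with predicted MHC affinity strictly below the threshold."""
    if "affinity_nm" not in neoantigens.columns:
        raise UsageError("neoantigen table lacks column 'affinity_nm'")
    if len(neoantigens) and (neoantigens["affinity_nm"] <= 0).any():
        raise DataError("affinities must be positive (nM)")
    return neoantigens[neoantigens["affinity_nm"] < threshold_nm].reset_index(drop=True)


def filter_tcr_pairs(
    pairs: pd.DataFrame, top_percent: float = 2.0, inclusive: bool = True
) -> pd.DataFrame:
    """Retain TCR-neoantigen pairs within the top percentile-rank band.

    The boundary is inclusive by default (rank == top_percent is retained);
    idempotent under repeated application.
    """
    if "percentile_rank" not in pairs.columns:
        raise UsageError("pair table lacks column 'percentile_rank'")
    ranks = pairs["percentile_rank"]
    if len(pairs) and ((ranks <= 0) | (ranks > 100)).any():
        raise DataError("percentile ranks must lie in (0, 100]")
    mask = ranks <= top_percent if inclusive else ranks < top_percent
    return pairs[mask].reset_index(drop=True)


def count_high_affinity_itcs(
    pairs: pd.DataFrame,
    itcs: Mapping[str, Iterable] | Iterable | None = None,
    neoantigen_classes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-patient count of distinct high-affinity ITC clonotypes (filters already applied).

    ``itcs`` optionally restricts clonotypes to each patient's ITC set (a mapping
    patient -> keys, or one global set).  ``neoantigen_classes`` (patient, peptide,
    class) adds a per-class breakdown of the recognised neoantigens.
    """
    if not {"patient", "clonotype", "peptide"} <= set(pairs.columns):
        raise UsageError("pair table needs patient, clonotype and peptide columns")
    df = pairs.copy()
    if itcs is not None:
        if isinstance(itcs, Mapping):
            keep = [row.clonotype in set(itcs.get(row.patient, ())) for row in df.itertuples()]
        else:
            allowed = set(itcs)
            keep = df["clonotype"].isin(allowed)
        df = df[np.asarray(keep, dtype=bool)]
    if neoantigen_classes is not None:
        df = df.merge(neoantigen_classes[["patient", "peptide", "class"]], on=["patient", "peptide"], how="left")
    rows = []
    for patient, group in df.groupby("patient", sort=True):
        row = {"patient": patient, "n_itcs": group["clonotype"].nunique()}
        if "class" in group.columns:
            for cls in NEOANTIGEN_CLASSES:
                row[f"n_neo_{cls}"] = group.loc[group["class"] == cls, "peptide"].nunique()
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_with_response(values, residual_tumor_percent) -> tuple[float, float]:
    """Two-sided Pearson correlation between a per-patient quantity and the
    pathological response (percent residual viable tumour)."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(residual_tumor_percent, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise UsageError("need matched samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def tmb(n_nonsynonymous: int, panel_mb: float = PANEL_MB) -> float:
    """Tumour mutation burden: nonsynonymous mutations per megabase of panel."""
    if n_nonsynonymous < 0:
        raise DataError("mutation count must be non-negative")
    if panel_mb <= 0:
        raise DataError("panel size must be positive")
    return n_nonsynonymous / panel_mb
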