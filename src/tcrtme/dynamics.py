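"""Clonotype tracking across paired tumours and longitudinal blood.

Intratumoral T cell clonotypes (ITCs) are the clonotypes shared between the
pre-treatment and post-treatment tumour of a patient.  Each ITC is classified as
expanded / contracted / unchanged by its frequency direction, and flagged as
*differentially* expanded or contracted when a two-sided Fisher exact test on the
2x2 template-count table ``[[count_pre, total_pre - count_pre],
[count_post, total_post - count_post]]`` gives p below the significance level
(0.05, unadjusted, with Benjamini-Hochberg adjustment available behind a flag).
Clones present on only one side are tracked as ``new`` / ``lost`` and excluded
from the Fisher classification.

Clonal space of a clone set is its summed frequency relative to the whole
repertoire; clonotype fraction is its share of the repertoire's richness.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ConsistencyError, DataError, UsageError
from .repertoire import ClonotypeTable, richness

CATEGORIES = ("expanded", "contracted", "unchanged", "new", "lost")
ITC_CATEGORIES = ("expanded", "contracted", "unchanged")

#: relative tolerance for pmf ties in the two-sided Fisher test (documented rule:
#: the two-sided p-value sums all hypergeometric outcomes whose probability does
#: not exceed the observed one, up to this relative slack)
_FISHER_TIE_REL = 1e-7


def fisher_exact_two_sided(
    count_pre: int, total_pre: int, count_post: int, total_post: int
) -> float:
    """Two-sided Fisher exact p for the 2x2 table of clone vs other templates.

    Computed as the sum of hypergeometric probabilities over the (small) support of
    the clone's combined count, which keeps the test exact but fast even at
    repertoire depths of 1e5.
    """
    a, b = int(count_pre), int(count_post)
    n1, n2 = int(total_pre), int(total_post)
    if min(a, b, n1 - a, n2 - b) < 0:
        raise DataError("negative cell in 2x2 contingency table")
    n = a + b
    big_n = n1 + n2
    kmin = max(0, n - n2)
    kmax = min(n, n1)
    support = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(support, big_n, n1, n)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_TIE_REL)].sum())
    return min(1.0, p)


def identify_itcs(pre_tumor: ClonotypeTable, post_tumor: ClonotypeTable) -> set:
    """Clonotype keys shared between the pre- and post-treatment tumour of a patient."""
    if pre_tumor.patient != post_tumor.patient:
        raise UsageError(
            f"pre/post tables belong to different patients "
            f"({pre_tumor.patient!r} vs {post_tumor.patient!r})"
        )
    if pre_tumor.key != post_tumor.key:
        raise UsageError("pre and post tables must use the same clonotype key definition")
    return pre_tumor.key_set() & post_tumor.key_set()


def clonal_space(keys: Iterable, table: ClonotypeTable) -> float:
    """Summed frequency of the member clones relative to the whole repertoire."""
    keys = set(keys)
    freqs = table.frequencies()
    return float(freqs[freqs.index.isin(keys)].sum())


def clonotype_fraction(keys: Iterable, table: ClonotypeTable) -> float:
    """Share of the repertoire's unique clonotypes that belong to the key set."""
    r = richness(table)
    if r == 0:
        return 0.0
    keys = set(keys)
    return sum(1 for k in table.merged().keys() if k in keys) / r


def make_clone_pairs(pre_tumor: ClonotypeTable, post_tumor: ClonotypeTable) -> pd.DataFrame:
    """Per-clonotype count table across the pair (outer join on clonotype keys)."""
    identify_itcs(pre_tumor, post_tumor)  # validates patient/key agreement
    pre = pre_tumor.merged()
    post = post_tumor.merged()
    pre_counts = pd.Series(pre.df["count"].to_numpy(), index=pre.keys())
    post_counts = pd.Series(post.df["count"].to_numpy(), index=post.keys())
    df = pd.DataFrame({"count_pre": pre_counts, "count_post": post_counts}).fillna(0).astype(int)
    df.index.name = "clonotype"
    df["total_pre"] = pre.depth
    df["total_post"] = post.depth
    df["freq_pre"] = df["count_pre"] / df["total_pre"]
    df["freq_post"] = df["count_post"] / df["total_post"]
    return df.reset_index()


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        adj[order[rank]] = running
    return adj


def classify_dynamics(pairs: pd.DataFrame, alpha: float = 0.05, adjust: bool = False) -> pd.DataFrame:
    """Classify each clone pair and flag differential expansion/contraction.

    Returns the input with ``category`` (expanded / contracted / unchanged / new /
    lost), ``p_value`` (Fisher exact, NaN for new/lost clones) and ``differential``
    columns.  ``adjust=True`` applies Benjamini-Hochberg across the tested clones.
    """
    required = {"count_pre", "total_pre", "count_post", "total_post"}
    missing = required - set(pairs.columns)
    if missing:
        raise UsageError(f"pairs table is missing columns: {sorted(missing)}")
    df = pairs.copy()
    for col in required:
        if (df[col] < 0).any():
            raise DataError(f"negative values in {col}")
    df["freq_pre"] = df["count_pre"] / df["total_pre"]
    df["freq_post"] = df["count_post"] / df["total_post"]

    category = np.where(
        df["count_pre"] == 0,
        "new",
        np.where(
            df["count_post"] == 0,
            "lost",
            np.where(
                df["freq_post"] > df["freq_pre"],
                "expanded",
                np.where(df["freq_post"] < df["freq_pre"], "contracted", "unchanged"),
            ),
        ),
    )
    df["category"] = category

    tested = (df["count_pre"] > 0) & (df["count_post"] > 0)
    pvals = np.full(len(df), np.nan)
    rows = df.loc[tested, ["count_pre", "total_pre", "count_post", "total_post"]].to_numpy()
    pvals[tested.to_numpy()] = [fisher_exact_two_sided(*row) for row in rows]
    df["p_value"] = pvals
    if adjust and tested.any():
        adj = np.full(len(df), np.nan)
        adj[tested.to_numpy()] = _benjamini_hochberg(pvals[tested.to_numpy()])
        df["p_adjusted"] = adj
        df["differential"] = (adj < alpha) & np.isin(category, ITC_CATEGORIES[:2])
    else:
        df["differential"] = (pvals < alpha) & np.isin(category, ITC_CATEGORIES[:2])
    return df


def frequency_rank_bins(table: ClonotypeTable) -> dict[int, int]:
    """Decade frequency bins ``10^0 .. 10^-6``: clone with frequency f falls in the
    bin labelled ``10^floor(log10 f)``.  Returns {exponent: clone count}."""
    freqs = table.frequencies().to_numpy()
    if len(freqs) and ((freqs <= 0) | (freqs > 1)).any():
        raise DataError("frequencies must lie in (0, 1]")
    exponents = np.floor(np.log10(freqs)).astype(int)
    bins: dict[int, int] = {}
    for e in exponents:
        bins[int(e)] = bins.get(int(e), 0) + 1
    return bins


def circulating_itcs(itcs: Iterable, blood_series: Sequence[ClonotypeTable]) -> pd.DataFrame:
    """Per-timepoint richness and clonal space of ITC clones detected in blood."""
    if not blood_series:
        raise UsageError("blood series is empty")
    itcs = set(itcs)
    rows = []
    for table in blood_series:
        present = itcs & table.key_set()
        rows.append(
            {
                "timepoint": table.timepoint,
                "n_circulating": len(present),
                "clonal_space": clonal_space(present, table),
            }
        )
    return pd.DataFrame(rows)


def summarize_circulating(per_patient: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Cohort summary: mean and s.e.m. of circulating-ITC clonal space per timepoint."""
    if not per_patient:
        raise UsageError("no patients to summarise")
    stacked = pd.concat(per_patient, names=["patient"]).reset_index(level=0)
    grouped = stacked.groupby("timepoint", sort=False)

    def sem(x):
        x = np.asarray(x, dtype=float)
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    return grouped.agg(
        mean_space=("clonal_space", "mean"),
        sem_space=("clonal_space", sem),
        mean_n=("n_circulating", "mean"),
        sem_n=("n_circulating", sem),
    ).reset_index()


def subset_circulating(
    classified: pd.DataFrame, blood_series: Sequence[ClonotypeTable]
) -> dict[str, pd.DataFrame]:
    """Circulating expanded / contracted / new subsets per timepoint.

    ``classified`` is the output of :func:`classify_dynamics` with a ``clonotype``
    column; each dynamic category is intersected with the blood-detected keys.
    """
    out = {}
    for cat in ("expanded", "contracted", "new"):
        keys = set(classified.loc[classified["category"] == cat, "clonotype"])
        out[cat] = circulating_itcs(keys, blood_series)
    return out


def flow_summary(
    post_tumor: ClonotypeTable,
    classified: pd.DataFrame,
    blood_series: Sequence[ClonotypeTable] | None = None,
) -> pd.DataFrame:
    """Origin of the post-treatment repertoire.

    For each category (expanded / contracted / unchanged ITCs and new clones):
    the fraction of post-treatment clonotypes, the fraction of post-treatment
    clonal space, and (when blood tables are given) the fraction of the category's
    clonotypes also detected in peripheral blood.  Clonotype/space fractions sum
    to 1 across categories.
    """
    post_keys = post_tumor.merged().key_set()
    cat_of = dict(zip(classified["clonotype"], classified["category"]))
    uncovered = [k for k in post_keys if k not in cat_of or cat_of[k] == "lost"]
    if uncovered:
        raise ConsistencyError(
            f"{len(uncovered)} post-treatment clonotypes are not covered by the classification"
        )
    blood_keys = set()
    if blood_series:
        for table in blood_series:
            blood_keys |= table.key_set()
    freqs = post_tumor.frequencies()
    rows = []
    for cat in ("expanded", "contracted", "unchanged", "new"):
        keys = {k for k in post_keys if cat_of[k] == cat}
        in_blood = len(keys & blood_keys) / len(keys) if keys else np.nan
        rows.append(
            {
                "category": cat,
                "clonotype_fraction": len(keys) / len(post_keys) if post_keys else 0.0,
                "clonal_space": float(freqs[freqs.index.isin(keys)].sum()),
                "blood_detected_fraction": in_blood if blood_series else np.nan,
            }
        )
    return pd.DataFrame(rows)
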