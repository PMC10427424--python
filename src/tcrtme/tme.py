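"""Tumour-microenvironment subtyping from hallmark ssGSEA scores.

Samples are clustered on row-scaled hallmark scores by Ward hierarchical
clustering on Euclidean distances (the ``ward.D2`` semantics: merge cost
minimises the increase of within-cluster sum of squares) and the tree is cut at
k = 3.  Clusters are then labelled by marker hallmark groups:

* immune-enriched (IE): interferon-alpha/gamma and inflammatory response,
* tumor_proliferation: E2F targets, MYC targets, DNA repair, mTORC1 signalling,
* fibroblast_enriched: EMT, TGF-beta, KRAS signalling, angiogenesis,

each cluster taking the label of the group with the highest mean scaled score
within the cluster (ties broken by the fixed priority IE > tumor_proliferation >
fibroblast_enriched, with a warning).  New samples are assigned to the nearest
fitted centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_samples

from .errors import ConfigurationError, UsageError
from .synthetic import HALLMARK_GROUPS

SUBTYPE_PRIORITY = ("IE", "tumor_proliferation", "fibroblast_enriched")


def _row_scale(scores: pd.DataFrame) -> pd.DataFrame:
    sd = scores.std(axis=1, ddof=1).replace(0.0, 1.0)
    return scores.sub(scores.mean(axis=1), axis=0).div(sd, axis=0)


def cluster_tme(scores: pd.DataFrame, k: int = 3) -> pd.Series:
    """Ward clustering of samples on row-scaled hallmark scores; returns cluster ids.

    Deterministic (agglomerative, no random initialisation) and invariant to sample
    order up to cluster renumbering.
    """
    if scores.shape[1] < k:
        raise UsageError(f"need at least k={k} samples, got {scores.shape[1]}")
    scaled = _row_scale(scores)
    z = linkage(scaled.to_numpy().T, method="ward")
    ids = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(ids, index=scores.columns, name="cluster")


def label_clusters(
    clusters: pd.Series,
    scores: pd.DataFrame,
    hallmark_groups: Mapping[str, Sequence[str]] = HALLMARK_GROUPS,
) -> pd.DataFrame:
    """Assign a subtype label to every cluster by its dominant marker group.

    Greedy assignment of (cluster, group) pairs in decreasing order of the cluster's
    mean scaled score over the group's hallmarks; no two clusters share a label, so
    a cluster beaten to its best label falls back to its best remaining one.
    Requires the number of clusters not to exceed the number of groups.
    """
    for group, members in hallmark_groups.items():
        missing = [h for h in members if h not in scores.index]
        if missing:
            raise ConfigurationError(f"hallmark group {group!r} members absent from matrix: {missing}")
    cluster_ids = sorted(clusters.unique())
    groups = [g for g in SUBTYPE_PRIORITY if g in hallmark_groups] + [
        g for g in hallmark_groups if g not in SUBTYPE_PRIORITY
    ]
    if len(cluster_ids) > len(groups):
        raise UsageError(f"{len(cluster_ids)} clusters but only {len(groups)} subtype groups")
    scaled = _row_scale(scores)
    means = pd.DataFrame(index=cluster_ids, columns=groups, dtype=float)
    for cid in cluster_ids:
        cols = clusters.index[clusters == cid]
        for g in groups:
            means.loc[cid, g] = scaled.loc[list(hallmark_groups[g]), cols].to_numpy().mean()

    label_of: dict[int, str] = {}
    taken: set[str] = set()
    flat = means.stack()
    if flat.nunique() < len(flat):
        warnings.warn("tied cluster/group means; labels break ties by subtype priority", stacklevel=2)
    # iterate cells by (descending mean, group priority) for a deterministic greedy match
    order = sorted(
        ((cid, g) for cid in cluster_ids for g in groups),
        key=lambda cg: (-means.loc[cg[0], cg[1]], groups.index(cg[1])),
    )
    for cid, g in order:
        if cid in label_of or g in taken:
            continue
        label_of[cid] = g
        taken.add(g)

    n_clusters = len(cluster_ids)
    if n_clusters >= 2 and scores.shape[1] > n_clusters:
        sil = silhouette_samples(scaled.to_numpy().T, clusters.to_numpy())
    else:
        sil = np.full(scores.shape[1], np.nan)
    out = pd.DataFrame(
        {
            "sample": clusters.index,
            "cluster": clusters.to_numpy(),
            "subtype": [label_of[c] for c in clusters],
            "silhouette": sil,
        }
    )
    sizes = out.groupby("cluster").size()
    if (sizes < 2).any() or (np.nanmean(sil) if np.isfinite(sil).any() else 1.0) < 0.05:
        warnings.warn("degenerate clustering: tiny clusters or near-zero silhouette", stacklevel=2)
    return out


@dataclass
class TmeSubtypeResult:
    """Fitted subtyping: per-sample assignments and per-subtype centroids (scaled scores)."""

    assignments: pd.DataFrame
    centroids: pd.DataFrame  # subtypes x hallmarks
    scale_mean: pd.Series
    scale_sd: pd.Series

    def assign(self, sample_scores: pd.Series) -> str:
        """Nearest-centroid subtype for a new sample (scored on the same hallmarks).

        Equidistant samples resolve by subtype priority (a warning marks the tie).
        """
        if not set(self.centroids.columns) <= set(sample_scores.index):
            missing = [h for h in self.centroids.columns if h not in sample_scores.index]
            raise UsageError(f"sample lacks hallmark scores: {missing}")
        z = (sample_scores[self.centroids.columns] - self.scale_mean) / self.scale_sd
        dists = ((self.centroids - z) ** 2).sum(axis=1)
        best = dists.min()
        winners = [s for s in SUBTYPE_PRIORITY if s in dists.index and dists[s] <= best + 1e-12]
        if len(winners) > 1:
            warnings.warn(f"equidistant centroids {winners}; resolved by priority", stacklevel=2)
        return winners[0]


def fit_tme_subtypes(
    scores: pd.DataFrame,
    k: int = 3,
    hallmark_groups: Mapping[str, Sequence[str]] = HALLMARK_GROUPS,
) -> TmeSubtypeResult:
    """Cluster, label and summarise: the one-call TME subtyping fit."""
    clusters = cluster_tme(scores, k=k)
    assignments = label_clusters(clusters, scores, hallmark_groups)
    scaled = _row_scale(scores)
    centroids = {}
    for subtype in assignments["subtype"].unique():
        cols = assignments.loc[assignments["subtype"] == subtype, "sample"]
        centroids[subtype] = scaled[list(cols)].mean(axis=1)
    return TmeSubtypeResult(
        assignments=assignments,
        centroids=pd.DataFrame(centroids).T,
        scale_mean=scores.mean(axis=1),
        scale_sd=scores.std(axis=1, ddof=1).replace(0.0, 1.0),
    )


def assign_new_sample(sample_scores: pd.Series, result: TmeSubtypeResult) -> str:
    """Convenience wrapper over :meth:`TmeSubtypeResult.assign`."""
    return result.assign(sample_scores)
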