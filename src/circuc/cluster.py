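"""Hierarchical clustering of samples and correlation-based feature clusters.

Two views are provided: (1) unsupervised clustering of sample columns
(Euclidean distance, complete linkage) with a two-group cut compared to
the case/control labels, and (2) extraction of tightly co-expressed
biomarker clusters, defined as feature subgroups whose *minimum* pairwise
Pearson correlation exceeds a threshold (default 0.6), pooled over cases
and controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from circuc.datatypes import ExprMatrix, GenomicLocus, SampleTable, ValidationError

logger = logging.getLogger("circuc")


@dataclass
class SampleClustering:
    linkage_matrix: np.ndarray
    two_group_labels: pd.Series   # sample_id -> 1/2
    misclassified: int | None     # against case/control labels, best matching


@dataclass
class CorrClusterSet:
    correlation_matrix: pd.DataFrame
    clusters: list[list[str]]
    stats: pd.DataFrame           # per cluster: size, min/mean pairwise r, max p
    unassigned: list[str]


def hier_cluster_samples(m: ExprMatrix, meta: SampleTable | None = None) -> SampleClustering:
    """Complete-linkage Euclidean clustering of sample columns.

    The dendrogram is cut into two groups; when metadata is given, the
    misclassification count is the number of samples on the wrong side
    under the best assignment of groups to labels.
    """
    if m.shape[1] < 2:
        raise ValidationError("sample clustering needs >= 2 samples")
    X = m.values.T  # samples x features
    Z = linkage(X, method="complete", metric="euclidean")
    labels = fcluster(Z, t=2, criterion="maxclust")
    series = pd.Series(labels, index=m.sample_ids)
    mis = None
    if meta is not None:
        truth = meta.groups_for(m.sample_ids)  # case mask
        in_1 = labels == 1
        # best of the two ways to map {1,2} onto {case,control}
        mis_a = int(np.sum(in_1 != truth))
        mis = min(mis_a, len(truth) - mis_a)
    return SampleClustering(linkage_matrix=Z, two_group_labels=series, misclassified=mis)


def pearson_matrix(m: ExprMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation of feature rows over all samples."""
    corr = np.corrcoef(m.values)
    return pd.DataFrame(corr, index=m.feature_ids, columns=m.feature_ids)


def pairwise_r_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via the t transform with n-2 df."""
    if n < 3:
        raise ValidationError("p-value for r needs n >= 3")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * t_dist.sf(abs(t), df=n - 2))


def _is_valid(members: list[str], corr: pd.DataFrame, r_threshold: float) -> bool:
    sub = corr.loc[members, members].to_numpy()
    off = sub[~np.eye(len(members), dtype=bool)]
    return bool(off.min() > r_threshold)


def _trim_cluster(members: list[str], corr: pd.DataFrame, r_threshold: float) -> list[str]:
    """Drop the weakest member until min pairwise r exceeds the threshold.

    Weakness is the mean correlation to the other members, which separates
    genuine cluster members from hangers-on more reliably than the minimum.
    """
    members = list(members)
    while len(members) >= 2:
        if _is_valid(members, corr, r_threshold):
            return members
        sub = corr.loc[members, members].to_numpy()
        np.fill_diagonal(sub, np.nan)
        mean_to_others = np.nanmean(sub, axis=1)
        members.pop(int(np.argmin(mean_to_others)))
    return []


def correlation_clusters(m: ExprMatrix, features: list[str] | None = None,
                         r_threshold: float = 0.6) -> CorrClusterSet:
    """Extract feature clusters whose minimum pairwise Pearson r exceeds
    ``r_threshold``.

    Features are clustered hierarchically on distance 1 - r (complete
    linkage); the dendrogram is cut at height 1 - r_threshold and each
    candidate cluster is verified against the min-pairwise-r criterion,
    iteratively dropping its weakest member if needed.  Constant (zero
    variance) features cannot carry a correlation and land in
    ``unassigned``.
    """
    if m.shape[1] < 3:
        raise ValidationError("correlation clustering needs >= 3 samples")
    sub = m if features is None else m.subset_features(list(features))
    values = sub.values
    sds = values.std(axis=1)
    constant = sds == 0
    unassigned = [f for f, c in zip(sub.feature_ids, constant) if c]
    if unassigned:
        logger.warning("constant features moved to unassigned: %s", unassigned)
    usable = [f for f, c in zip(sub.feature_ids, constant) if not c]
    corr = pearson_matrix(sub.subset_features(usable)) if len(usable) >= 1 else \
        pd.DataFrame(index=[], columns=[])

    clusters: list[list[str]] = []
    if len(usable) >= 2:
        dist = 1.0 - corr.to_numpy()
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        Z = linkage(squareform(dist, checks=False), method="complete")
        # candidate clusters are the subtrees of the dendrogram, largest
        # first: subtrees already satisfying the min-pairwise-r criterion
        # are accepted whole; leftover features are then claimed by trimming
        # the remaining candidates
        n_leaves = len(usable)
        members_of: list[list[int]] = [[i] for i in range(n_leaves)]
        for left, right, _, _ in Z:
            members_of.append(members_of[int(left)] + members_of[int(right)])
        candidates = sorted(range(n_leaves, len(members_of)),
                            key=lambda nd: -len(members_of[nd]))
        claimed: set[int] = set()
        for node in candidates:
            idx = members_of[node]
            if len(idx) < 2 or any(i in claimed for i in idx):
                continue
            names = [usable[i] for i in idx]
            if _is_valid(names, corr, r_threshold):
                clusters.append(sorted(names))
                claimed.update(idx)
        for node in candidates:
            free = [i for i in members_of[node] if i not in claimed]
            if len(free) < 2:
                continue
            kept = _trim_cluster([usable[i] for i in free], corr, r_threshold)
            if len(kept) >= 2:
                clusters.append(sorted(kept))
                claimed.update(usable.index(f) for f in kept)
        unassigned.extend(usable[i] for i in range(n_leaves) if i not in claimed)
    else:
        unassigned.extend(usable)

    clusters.sort(key=lambda c: (-len(c), c))
    n = m.shape[1]
    rows = []
    for i, members in enumerate(clusters):
        sub_r = corr.loc[members, members].to_numpy()
        off = sub_r[~np.eye(len(members), dtype=bool)]
        rows.append({
            "cluster": i + 1,
            "size": len(members),
            "min_pairwise_r": float(off.min()),
            "mean_pairwise_r": float(off.mean()),
            "max_pairwise_p": max(pairwise_r_pvalue(r, n) for r in off),
        })
    stats = pd.DataFrame(rows, columns=["cluster", "size", "min_pairwise_r",
                                        "mean_pairwise_r", "max_pairwise_p"])
    full_corr = pearson_matrix(sub.subset_features(usable)) if usable else corr
    return CorrClusterSet(correlation_matrix=full_corr, clusters=clusters,
                          stats=stats, unassigned=sorted(unassigned))


def colocalize(loci: list[GenomicLocus], max_gap_bp: int) -> pd.DataFrame:
    """Unordered same-chromosome feature pairs with interval gap <= max_gap_bp.

    The gap is 0 for overlapping or abutting intervals, otherwise the
    distance between the closer ends.
    """
    rows = []
    for a, b in combinations(loci, 2):
        if a.chrom != b.chrom:
            continue
        gap = max(a.start, b.start) - min(a.end, b.end)
        gap = max(gap, 0)
        if gap <= max_gap_bp:
            rows.append({
                "feature_a": a.feature_id, "feature_b": b.feature_id,
                "chrom": a.chrom, "gap_bp": gap,
            })
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "chrom", "gap_bp"])
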