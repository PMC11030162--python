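"""Healthy/rotten sample classification from metagenomic TPM profiles.

Samples are compared by Euclidean distance, ordinated by PCA and clustered
with the Ward.D2 criterion; cluster stability is assessed by resampling
gene columns with replacement.  The putative field status is retained,
reassigned from the k=2 cluster, or rescued from the metatranscriptome for
samples with an intermediate metagenomic focal share.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .quantify import TpmMatrix
from .taxonomy import Lineage, focal_share

HEALTHY = "healthy"
ROTTEN = "rotten"


@dataclass(frozen=True)
class StatusThresholds:
    """Tunable decision thresholds; the defaults generalize the case-by-case
    narrative rules into a single procedure."""

    mg_low: float = 0.01
    mg_high: float = 0.50
    mt_rescue: float = 0.10
    min_reads: int = 3500


@dataclass
class SampleStatusReport:
    """Per-sample classification with its supporting evidence."""

    report: pd.DataFrame
    distances: pd.DataFrame
    explained_variance: tuple[float, ...]


def distance_matrix(tpm: TpmMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between sample TPM rows."""
    data = getattr(tpm, "data", tpm)
    if len(data.index) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    x = data.to_numpy(dtype=float)
    sq = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=2)
    d = np.sqrt(np.maximum(sq, 0.0))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=data.index, columns=data.index)


def pca(tpm: TpmMatrix | pd.DataFrame, n_components: int = 2):
    """Column-centered SVD ordination.

    Component signs are fixed so each loading vector's largest-magnitude
    entry is positive.  Returns (scores frame, explained-variance
    fractions).
    """
    data = getattr(tpm, "data", tpm)
    if len(data.index) < 2:
        raise ValueError("need at least 2 samples for PCA")
    x = data.to_numpy(dtype=float)
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    var = s**2
    total = var.sum()
    explained = var / total if total > 0 else np.zeros_like(var)
    k = min(n_components, scores.shape[1])
    frame = pd.DataFrame(
        scores[:, :k], index=data.index, columns=[f"PC{i+1}" for i in range(k)]
    )
    return frame, tuple(float(e) for e in explained[:k])


def ward_cluster(dist: pd.DataFrame, k: int = 2):
    """Ward.D2 agglomeration on unsquared Euclidean distances.

    Returns (scipy linkage matrix, flat cluster labels at ``k`` as a
    Series).  Merge heights are non-decreasing (Ward monotonicity).
    """
    condensed = squareform(dist.to_numpy(), checks=False)
    linkage = hierarchy.linkage(condensed, method="ward")
    flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return linkage, pd.Series(flat, index=dist.index, name="cluster")


def _internal_leaf_sets(linkage: np.ndarray, n: int) -> list[frozenset[int]]:
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    out = []
    for row_idx, (a, b, _h, _c) in enumerate(linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + row_idx] = merged
        out.append(merged)
    return out


def bootstrap_support(
    tpm: TpmMatrix | pd.DataFrame,
    iterations: int = 1000,
    seed: int = 0,
) -> dict[frozenset[str], float]:
    """Support of every internal cluster under gene-column resampling.

    Each iteration resamples gene columns with replacement, recomputes the
    distance matrix and Ward.D2 dendrogram, and scores an original internal
    cluster 1 when its exact leaf set reappears.  Columns are sorted by
    gene id before resampling so the result is invariant to input column
    order for a fixed seed.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    data = getattr(tpm, "data", tpm)
    data = data[sorted(data.columns)]
    x = data.to_numpy(dtype=float)
    n, g = x.shape
    samples = list(data.index)

    base_link, _ = ward_cluster(distance_matrix(data))
    original = _internal_leaf_sets(base_link, n)
    hits = {leaf_set: 0 for leaf_set in original}

    rng = np.random.default_rng(seed)
    for _ in range(iterations):
        idx = rng.integers(0, g, size=g)
        xb = x[:, idx]
        sq = np.sum((xb[:, None, :] - xb[None, :, :]) ** 2, axis=2)
        condensed = squareform(np.sqrt(np.maximum(sq, 0.0)), checks=False)
        link = hierarchy.linkage(condensed, method="ward")
        boot_sets = set(_internal_leaf_sets(link, n))
        for leaf_set in original:
            if leaf_set in boot_sets:
                hits[leaf_set] += 1
    return {
        frozenset(samples[i] for i in leaf_set): count / iterations
        for leaf_set, count in hits.items()
    }


def classify_samples(
    mg_tpm: TpmMatrix | pd.DataFrame,
    mt_tpm: TpmMatrix | pd.DataFrame | None,
    lineages: Mapping[str, Lineage],
    focal_taxon: str,
    putative: Mapping[str, str],
    mt_read_counts: Mapping[str, int] | None = None,
    thresholds: StatusThresholds = StatusThresholds(),
    iterations: int = 1000,
    seed: int = 0,
) -> SampleStatusReport:
    """Confirm or reassign each sample's healthy/rotten label.

    Final status defaults to the majority putative label of the sample's
    k=2 Ward.D2 cluster (ties broken towards the cluster with the higher
    mean metagenomic focal share).  Samples whose metagenomic focal share
    lies in ``[mg_low, mg_high)`` are instead decided by the
    metatranscriptome: healthy iff the MT focal share is at least
    ``mt_rescue``.  Samples with fewer than ``min_reads`` MT reads are
    excluded from the MT analysis and fall back to the cluster label.
    """
    mg_data = getattr(mg_tpm, "data", mg_tpm)
    samples = list(mg_data.index)

    mg_share = focal_share(mg_data, lineages, focal_taxon)
    dist = distance_matrix(mg_data)
    scores, explained = pca(mg_data)
    _, clusters = ward_cluster(dist, k=2)
    support = bootstrap_support(mg_data, iterations=iterations, seed=seed)

    mt_data = getattr(mt_tpm, "data", mt_tpm) if mt_tpm is not None else None
    mt_share = (
        focal_share(mt_data, lineages, focal_taxon) if mt_data is not None else None
    )

    excluded = set()
    if mt_read_counts is not None:
        excluded = {s for s in samples if mt_read_counts.get(s, 0) < thresholds.min_reads}
    if mt_data is None:
        excluded = set(samples)

    cluster_label = _majority_labels(clusters, putative, mg_share)
    cluster_sets = {
        cid: frozenset(clusters.index[clusters == cid]) for cid in clusters.unique()
    }

    rows = []
    for s in samples:
        cid = clusters[s]
        clabel = cluster_label[cid]
        share = float(mg_share[s])
        mts = float(mt_share[s]) if (mt_share is not None and s not in excluded) else np.nan
        intermediate = thresholds.mg_low <= share < thresholds.mg_high
        if intermediate and s not in excluded:
            final = HEALTHY if mts >= thresholds.mt_rescue else ROTTEN
            if final == HEALTHY:
                rationale = "rescued_by_MT"
            else:
                rationale = "retained" if final == putative[s] else "reassigned_by_cluster"
        elif intermediate and s in excluded:
            final = clabel
            rationale = "excluded_low_reads"
        else:
            final = clabel
            rationale = "retained" if final == putative[s] else "reassigned_by_cluster"
        rows.append(
            {
                "sample": s,
                "putative_status": putative[s],
                "mg_focal_share": share,
                "mt_focal_share": mts,
                "mt_excluded": s in excluded,
                "cluster": int(cid),
                "cluster_support": support.get(cluster_sets[cid], 1.0),
                "PC1": float(scores.loc[s, "PC1"]),
                "PC2": float(scores.loc[s, "PC2"]) if "PC2" in scores else 0.0,
                "final_status": final,
                "rationale": rationale,
            }
        )
    report = pd.DataFrame(rows).set_index("sample")
    return SampleStatusReport(report=report, distances=dist, explained_variance=explained)


def _majority_labels(
    clusters: pd.Series,
    putative: Mapping[str, str],
    mg_share: pd.Series,
) -> dict[int, str]:
    """Majority putative label per cluster; ties resolved by assigning
    healthy to the cluster with the higher mean metagenomic focal share."""
    labels: dict[int, str] = {}
    tied: list[int] = []
    means = {}
    for cid in clusters.unique():
        members = clusters.index[clusters == cid]
        n_healthy = sum(putative[s] == HEALTHY for s in members)
        n_rotten = len(members) - n_healthy
        means[cid] = float(mg_share[members].mean())
        if n_healthy > n_rotten:
            labels[cid] = HEALTHY
        elif n_rotten > n_healthy:
            labels[cid] = ROTTEN
        else:
            tied.append(cid)
    if tied:
        ordered = sorted(clusters.unique(), key=lambda c: -means[c])
        for cid in tied:
            labels[cid] = HEALTHY if cid == ordered[0] else ROTTEN
    return labels
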