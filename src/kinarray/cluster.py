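"""Unsupervised sample stratification.

Peptides are filtered by relative variance (sigma / sigma_max), log-scaled
and z-scored, then samples are clustered by average-linkage (UPGMA)
agglomeration on Euclidean distances.  The number of clusters is estimated
with the gap statistic: within-cluster dispersion of the observed data is
compared against B reference datasets drawn uniformly over each feature's
observed range, and the smallest k satisfying the one-standard-error rule
is selected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .datatypes import ClusterResult, PeptideMatrix, ValidationError

log = logging.getLogger(__name__)

DEFAULT_VARIANCE_THRESHOLD = 0.15
DEFAULT_K_MAX = 6
DEFAULT_B = 100


def variance_filter(
    m: PeptideMatrix, threshold: float = DEFAULT_VARIANCE_THRESHOLD
) -> PeptideMatrix:
    """Retain peptides whose sd is at least ``threshold`` times the largest sd.

    The ratio is on standard deviations (sigma / sigma_max), computed across
    samples per peptide.  The peptide attaining sigma_max is always retained
    for any threshold <= 1.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("variance threshold must lie in [0, 1]")
    sd = m.data.std(axis=1, ddof=1)
    sd_max = sd.max()
    if sd_max == 0.0:
        raise ValidationError("all-constant matrix: sigma_max is zero")
    keep = sd / sd_max >= threshold
    log.info("variance filter retained %d/%d peptides", int(keep.sum()), len(keep))
    return m.advance("filtered", m.data.loc[keep])


def scale_features(m: PeptideMatrix, log_transform: bool = True) -> PeptideMatrix:
    """Optional log2(1 + x), then per-peptide z-score across samples.

    Peptides with zero variance after the transform carry no clustering
    information and are dropped with a warning.
    """
    df = m.data
    if log_transform:
        df = np.log2(1.0 + df)
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    degenerate = sd == 0.0
    if degenerate.any():
        log.warning("dropping %d zero-variance peptides before scaling", int(degenerate.sum()))
        df, mean, sd = df.loc[~degenerate], mean[~degenerate], sd[~degenerate]
    scaled = df.sub(mean, axis=0).div(sd, axis=0)
    return m.advance("scaled", scaled, log_applied=m.log_applied or log_transform, scaled=True)


def _as_sample_array(m: PeptideMatrix | np.ndarray | pd.DataFrame) -> np.ndarray:
    """Samples-by-features array from a PeptideMatrix (features x samples) or array."""
    if isinstance(m, PeptideMatrix):
        return m.data.to_numpy(float).T
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(float)
    return np.asarray(m, dtype=float)


def hierarchical_cluster(m: PeptideMatrix | np.ndarray) -> np.ndarray:
    """UPGMA (average-linkage) agglomeration on Euclidean sample distances.

    Returns the scipy linkage matrix: each row (i, j, height, size) merges
    the pair of clusters at the smallest mean inter-cluster distance.
    """
    x = _as_sample_array(m)
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 samples to cluster")
    return linkage(x, method="average", metric="euclidean")


def cut_tree(tree: np.ndarray, k: int) -> np.ndarray:
    """Labels for the k-group partition from the top k-1 splits.

    Cluster ids are 1..k, numbered by order of each cluster's first member
    sample; at k = 2 the groups are reported as cluster-1 / cluster-2.
    """
    n = tree.shape[0] + 1
    if not 1 <= k <= n:
        raise ValidationError(f"k = {k} out of range 1..{n}")
    raw = fcluster(tree, t=k, criterion="maxclust")
    # relabel by first occurrence so numbering is deterministic
    relabel: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, c in enumerate(raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        out[i] = relabel[c]
    return out


def within_dispersion(m: PeptideMatrix | np.ndarray, labels: np.ndarray) -> float:
    """Pooled within-cluster dispersion W = sum_r D_r / (2 n_r).

    D_r is the sum of all pairwise squared Euclidean distances within
    cluster r; the quantity equals the within-cluster sum of squared
    distances to centroids.
    """
    x = _as_sample_array(m)
    labels = np.asarray(labels)
    w = 0.0
    for c in np.unique(labels):
        pts = x[labels == c]
        centroid = pts.mean(axis=0)
        w += float(((pts - centroid) ** 2).sum())
    return w


def gap_statistic(
    m: PeptideMatrix | np.ndarray,
    k_max: int = DEFAULT_K_MAX,
    B: int = DEFAULT_B,
    seed: int | np.random.Generator = 0,
) -> tuple[int, np.ndarray, np.ndarray, np.ndarray]:
    """Gap-statistic estimate of the number of clusters.

    For each k in 1..k_max the observed data is clustered (UPGMA + cut) and
    log W_k recorded; B reference datasets drawn uniformly over each
    feature's observed range are clustered identically.  Gap(k) is the mean
    reference log W minus the observed log W, s_k the reference sd inflated
    by sqrt(1 + 1/B), and k-hat the smallest k with
    Gap(k) >= Gap(k+1) - s_{k+1} (falling back to k_max).

    Returns ``(k_hat, gap, s, log_w)`` with curves indexed k = 1..k_max.
    """
    x = _as_sample_array(m)
    n = x.shape[0]
    if n < 3:
        raise ValidationError("gap statistic needs at least 3 samples")
    if k_max >= n:
        raise ValidationError("k_max must be smaller than the number of samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def log_w_curve(data: np.ndarray) -> np.ndarray:
        tree = linkage(data, method="average", metric="euclidean")
        return np.array(
            [np.log(within_dispersion(data, cut_tree(tree, k))) for k in range(1, k_max + 1)]
        )

    log_w = log_w_curve(x)
    lo, hi = x.min(axis=0), x.max(axis=0)
    ref = np.empty((B, k_max))
    for b in range(B):
        ref[b] = log_w_curve(rng.uniform(lo, hi, size=x.shape))
    gap = ref.mean(axis=0) - log_w
    s = ref.std(axis=0) * np.sqrt(1.0 + 1.0 / B)

    k_hat = k_max
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - s[k]:
            k_hat = k
            break
    return k_hat, gap, s, log_w


def run_clustering(
    m: PeptideMatrix,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    log_transform: bool = True,
    k_max: int = DEFAULT_K_MAX,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> ClusterResult:
    """Variance filter -> scale -> gap statistic -> labels at k-hat."""
    filtered = variance_filter(m, threshold=variance_threshold)
    scaled = scale_features(filtered, log_transform=log_transform)
    tree = hierarchical_cluster(scaled)
    k_hat, gap, s, log_w = gap_statistic(scaled, k_max=k_max, B=B, seed=seed)
    labels = {k: cut_tree(tree, k) for k in range(1, k_max + 1)}
    log.info("gap statistic selected k = %d (cluster sizes %s)",
             k_hat, np.bincount(labels[k_hat])[1:].tolist())
    return ClusterResult(
        samples=scaled.samples,
        linkage=tree,
        labels=labels,
        w=np.exp(log_w),
        gap=gap,
        s=s,
        k_hat=k_hat,
        kept_peptides=list(scaled.data.index),
    )
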