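"""Clustering coupled with bootstrap stability sampling (CT-BS).

Rows of a segment are clustered with k-means; each cluster's stability is
the mean maximal Jaccard coefficient between the cluster and the clusters
found on bootstrap resamples of the rows.  The least stable clusters are
pruned, and every surviving cluster is resampled with replacement to a
fixed size so downstream feature extraction sees equal-sized blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "ClusterPartition",
    "StabilityReport",
    "CTBSResult",
    "jaccard",
    "cluster_points",
    "bootstrap_stability",
    "reduce_clusters",
    "sample_cluster",
    "run_ctbs",
]


@dataclass
class ClusterPartition:
    k: int
    assignments: np.ndarray  # row index -> cluster id in [0, k)
    centroids: np.ndarray  # k x d
    seed: int

    def members(self, cluster_id: int) -> np.ndarray:
        """Row indices of a cluster."""
        if not 0 <= cluster_id < self.k:
            raise KeyError(f"unknown cluster id {cluster_id}")
        return np.flatnonzero(self.assignments == cluster_id)


@dataclass
class StabilityReport:
    """Per-cluster bootstrap-Jaccard stability.

    ``tau_sequence[c]`` holds one entry per replicate (0 where the induced
    cluster was empty); ``tau_mean[c]`` averages the non-empty replicates,
    of which there were ``b_star[c]``.
    """

    b: int
    tau_mean: np.ndarray
    b_star: np.ndarray
    tau_sequence: np.ndarray  # k x b

    def to_dict(self) -> dict:
        return {
            int(c): {"tau_mean": float(self.tau_mean[c]), "b_star": int(self.b_star[c])}
            for c in range(len(self.tau_mean))
        }


@dataclass
class CTBSResult:
    """Everything downstream feature extraction needs from one segment."""

    partition: ClusterPartition
    report: StabilityReport
    kept_ids: list
    clusters: dict  # kept cluster id -> (cluster_size x d) resampled rows


def jaccard(C, D) -> float:
    """|C ∩ D| / |C ∪ D| for two index sets; undefined when both are empty."""
    C, D = set(C), set(D)
    union = C | D
    if not union:
        raise ValueError("Jaccard coefficient undefined for two empty sets")
    return len(C & D) / len(union)


def cluster_points(points: np.ndarray, k: int, seed: int) -> ClusterPartition:
    """Lloyd k-means with k-means++ seeding; centroids are cluster means.

    Cluster ids are canonical: clusters are relabelled in ascending order of
    centroid norm (stable on ties), so id j means comparable things across
    independently clustered segments — required for downstream features of
    different instances to share columns.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < k:
        raise ValueError(f"cannot form k={k} clusters from n={n} points")
    km = KMeans(n_clusters=k, init="k-means++", n_init=4, random_state=seed)
    labels = km.fit_predict(points)
    # guard the no-empty-cluster invariant (KMeans re-seeds empties itself)
    assert len(np.unique(labels)) == k
    order = np.argsort(np.linalg.norm(km.cluster_centers_, axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return ClusterPartition(
        k=k,
        assignments=relabel[labels],
        centroids=km.cluster_centers_[order],
        seed=seed,
    )


def bootstrap_stability(
    points: np.ndarray,
    partition: ClusterPartition,
    b: int,
    seed: int,
    indices: np.ndarray | None = None,
) -> StabilityReport:
    """Mean maximal Jaccard stability of each original cluster.

    Per replicate: draw n rows with replacement, recluster the sample with
    the same k and method, and score each original cluster C by the maximum
    Jaccard similarity between C restricted to the sampled rows and the
    clusters of the resample (restricted likewise).  ``indices`` may supply
    the b x n resample index matrix explicitly (reproducibility hooks/tests).
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    rng = np.random.default_rng(seed)
    if indices is None:
        indices = rng.integers(0, n, size=(b, n))
    else:
        indices = np.asarray(indices)
        if indices.shape != (b, n):
            raise ValueError(f"indices must have shape {(b, n)}")

    k = partition.k
    tau_seq = np.zeros((k, b))
    b_star = np.zeros(k, dtype=int)
    originals = [set(map(int, partition.members(c))) for c in range(k)]
    for i in range(b):
        idx = indices[i]
        sample_rows = set(map(int, np.unique(idx)))
        sub = cluster_points(points[idx], k, seed=int(rng.integers(2**31)))
        # new clustering restricted to original rows present in the sample
        induced_new = [set() for _ in range(k)]
        for pos, cid in enumerate(sub.assignments):
            induced_new[cid].add(int(idx[pos]))
        for c in range(k):
            c_star = originals[c] & sample_rows
            if not c_star:
                continue
            b_star[c] += 1
            tau_seq[c, i] = max(
                (jaccard(c_star, D) for D in induced_new if D), default=0.0
            )
    with np.errstate(invalid="ignore"):
        tau_mean = np.where(b_star > 0, tau_seq.sum(axis=1) / np.maximum(b_star, 1), 0.0)
    return StabilityReport(b=b, tau_mean=tau_mean, b_star=b_star, tau_sequence=tau_seq)


def reduce_clusters(
    partition: ClusterPartition, report: StabilityReport, target_k: int
) -> list:
    """Keep the ``target_k`` most stable clusters (ties: lower id); sorted by id."""
    if target_k < 1:
        raise ValueError("target_k must be >= 1")
    if target_k > partition.k:
        raise ValueError(f"target_k={target_k} exceeds k={partition.k}")
    order = sorted(range(partition.k), key=lambda c: (-report.tau_mean[c], c))
    return sorted(order[:target_k])


def sample_cluster(
    points: np.ndarray,
    partition: ClusterPartition,
    cluster_id: int,
    size: int,
    seed: int,
    indices: np.ndarray | None = None,
) -> np.ndarray:
    """Resample a cluster's rows with replacement to a fixed size."""
    members = partition.members(cluster_id)
    if members.size == 0:
        raise ValueError(f"cluster {cluster_id} is empty")
    if indices is None:
        rng = np.random.default_rng(seed)
        indices = rng.integers(0, members.size, size=size)
    else:
        indices = np.asarray(indices)
        if indices.shape != (size,):
            raise ValueError(f"indices must have shape ({size},)")
    return np.asarray(points, dtype=float)[members[indices]]


def run_ctbs(
    segment: np.ndarray,
    k: int,
    target_k: int,
    cluster_size: int,
    b: int,
    seed: int,
) -> CTBSResult:
    """Full CT-BS pass over one segment: cluster, score, prune, resample."""
    ss = np.random.SeedSequence(seed)
    s_cluster, s_boot, s_sample = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    partition = cluster_points(segment, k, seed=s_cluster)
    report = bootstrap_stability(segment, partition, b=b, seed=s_boot)
    kept = reduce_clusters(partition, report, target_k)
    rng = np.random.default_rng(s_sample)
    clusters = {
        c: sample_cluster(segment, partition, c, cluster_size, seed=int(rng.integers(2**31)))
        for c in kept
    }
    return CTBSResult(partition=partition, report=report, kept_ids=kept, clusters=clusters)
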