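"""Covariance eigen-spectrum features.

Each fixed-size cluster of segment rows is split into 4 consecutive
sub-clusters; each sub-cluster's sample covariance (observations = rows,
variables = trial columns) is eigendecomposed and the sorted spectrum is
summarised by ten descriptive statistics, giving a 40-entry vector per
cluster and a 40 x k matrix per segment (k kept clusters, default 30).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import ctbs, signal_io

__all__ = [
    "STAT_NAMES",
    "StatVector",
    "SegmentFeatures",
    "FeatureTable",
    "covariance_matrix",
    "eigen_spectrum",
    "stat_features",
    "extract_cluster_features",
    "extract_segment_features",
    "build_feature_table",
]

#: fixed order of the ten spectrum statistics
STAT_NAMES = (
    "mean",
    "median",
    "maximum",
    "minimum",
    "mode",
    "range",
    "standard_deviation",
    "variance",
    "skewness",
    "kurtosis",
)

N_SUBCLUSTERS = 4


@dataclass
class StatVector:
    mean: float
    median: float
    maximum: float
    minimum: float
    mode: float
    range: float
    standard_deviation: float
    variance: float
    skewness: float
    kurtosis: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STAT_NAMES])


@dataclass
class SegmentFeatures:
    values: np.ndarray  # 40 x k
    feature_names: list  # 40 labels: sub{j}_{stat}
    cluster_ids: list  # k kept-cluster labels

    def __post_init__(self) -> None:
        if self.values.shape != (N_SUBCLUSTERS * len(STAT_NAMES), len(self.cluster_ids)):
            raise ValueError(f"bad SegmentFeatures shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


@dataclass
class FeatureTable:
    """Instances x features with labels and (subject, segment) provenance."""

    values: pd.DataFrame
    labels: list  # per instance, in {control, alcoholic}
    provenance: list  # per instance (subject_id, segment_index)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.values):
            raise ValueError("one label per instance required")
        bad = set(self.labels) - set(signal_io.LABELS)
        if bad:
            raise ValueError(f"unknown labels {bad}")
        if self.values.isna().any().any():
            raise ValueError("missing values in feature table")

    @property
    def feature_names(self) -> list:
        return list(self.values.columns)

    def class_values(self, label: str, columns) -> np.ndarray:
        mask = np.array([l == label for l in self.labels])
        return self.values.loc[mask, columns].to_numpy().ravel()

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, sep="\t", index=False)


def covariance_matrix(X: np.ndarray) -> np.ndarray:
    """Sample covariance of rows-as-observations with the W-1 divisor."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 observation rows")
    return np.cov(X, rowvar=False, ddof=1)


def eigen_spectrum(M: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Descending real eigenvalues of a symmetric PSD-within-tolerance matrix."""
    M = np.asarray(M, dtype=float)
    scale = np.linalg.norm(M)
    if not np.allclose(M, M.T, atol=tol * max(scale, 1.0)):
        raise ValueError("matrix is not symmetric within tolerance")
    vals = np.linalg.eigvalsh(M)[::-1]
    if scale > 0 and vals.min() < -tol * scale:
        raise ValueError(f"matrix has significantly negative eigenvalue {vals.min():g}")
    return np.clip(vals, 0.0, None)


def _round_sig(x: float, sig: int = 12) -> float:
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def _mode(v: np.ndarray) -> float:
    # smallest most-frequent value, grouping by 12 significant digits;
    # returns the minimum on all-distinct samples.  The returned value is an
    # actual sample value (not its rounding) so min <= mode <= max holds.
    groups: dict[float, list[float]] = {}
    for x in v:
        groups.setdefault(_round_sig(float(x)), []).append(float(x))
    best = max(groups.values(), key=lambda g: (len(g), -min(g)))
    return min(best)


def stat_features(v: np.ndarray) -> StatVector:
    """Ten descriptive statistics of a spectrum (or any real vector).

    Variance/SD use the n-1 divisor; skewness and kurtosis are the
    standardized third and fourth central moments (kurtosis of a normal
    sample ≈ 3, not 0); a zero-variance sample gets skew = kurt = 0.
    """
    v = np.asarray(v, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite entries")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    if sd > 0:
        skew = float(sstats.skew(v, bias=True))
        kurt = float(sstats.kurtosis(v, fisher=False, bias=True))
    else:
        skew = kurt = 0.0
    return StatVector(
        mean=float(np.mean(v)),
        median=float(np.median(v)),
        maximum=float(np.max(v)),
        minimum=float(np.min(v)),
        mode=_mode(v),
        range=float(np.max(v) - np.min(v)),
        standard_deviation=sd,
        variance=sd**2,
        skewness=skew,
        kurtosis=kurt,
    )


def extract_cluster_features(cluster: np.ndarray) -> np.ndarray:
    """40 features from one fixed-size cluster: 4 consecutive row blocks,
    each summarised by the ten statistics of its covariance eigen-spectrum."""
    cluster = np.asarray(cluster, dtype=float)
    n = cluster.shape[0]
    if n % N_SUBCLUSTERS:
        raise ValueError(f"cluster rows ({n}) must be divisible by {N_SUBCLUSTERS}")
    block = n // N_SUBCLUSTERS
    out = []
    for j in range(N_SUBCLUSTERS):
        sub = cluster[j * block : (j + 1) * block]
        spectrum = eigen_spectrum(covariance_matrix(sub))
        out.append(stat_features(spectrum).as_array())
    return np.concatenate(out)


def subcluster_feature_names() -> list:
    return [f"sub{j}_{s}" for j in range(N_SUBCLUSTERS) for s in STAT_NAMES]


def extract_segment_features(ctbs_result: ctbs.CTBSResult) -> SegmentFeatures:
    """Column j = the 40 features of kept cluster j (kept-id order)."""
    cols = [extract_cluster_features(ctbs_result.clusters[c]) for c in ctbs_result.kept_ids]
    return SegmentFeatures(
        values=np.column_stack(cols),
        feature_names=subcluster_feature_names(),
        cluster_ids=list(ctbs_result.kept_ids),
    )


def flatten_segment_features(sf: SegmentFeatures) -> tuple[np.ndarray, list]:
    """Cluster-major flattening to a length 40*k vector with stable names."""
    names = [
        f"c{pos:02d}_{fn}"
        for pos in range(len(sf.cluster_ids))
        for fn in sf.feature_names
    ]
    return sf.values.ravel(order="F"), names


def build_feature_table(
    recordings,
    n_segments: int = 4,
    k: int = 32,
    target_k: int = 30,
    cluster_size: int = 120,
    bootstrap_b: int = 100,
    seed: int = 0,
) -> FeatureTable:
    """One instance per (recording, segment): stack, segment, CT-BS, features.

    Deterministic given ``seed``; the per-(recording, segment) CT-BS seeds are
    spawned from it.
    """
    recordings = list(recordings)
    if not recordings:
        raise ValueError("no recordings")
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.spawn(len(recordings) * n_segments))
    rows, labels, prov = [], [], []
    names = None
    for rec in recordings:
        segset = signal_io.segment_signal(signal_io.stack_channels(rec), n_segments)
        for si, seg in enumerate(segset.segments):
            sub_seed = int(next(seeds).generate_state(1)[0] % 2**31)
            res = ctbs.run_ctbs(
                seg, k=k, target_k=target_k, cluster_size=cluster_size, b=bootstrap_b,
                seed=sub_seed,
            )
            vec, names = flatten_segment_features(extract_segment_features(res))
            rows.append(vec)
            labels.append(rec.label)
            prov.append((rec.subject_id, si))
    df = pd.DataFrame(np.vstack(rows), columns=names)
    return FeatureTable(values=df, labels=labels, provenance=prov)
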