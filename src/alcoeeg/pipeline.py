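"""End-to-end orchestration: features -> KS screening -> FOA-tuned F-SVM -> CV.

Evaluation is stratified k-fold cross-validation over (recording, segment)
instances.  Within every training fold, the KS screen is fitted on a
stratified half-split of that fold (never on the test fold) and the SVM
hyperparameters (Z, gamma) are tuned by FOA against an inner cross-validated
accuracy — so no information from a fold's test instances reaches feature
selection or tuning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler

from . import coveig, foa, fsvm, ks_selection, metrics as metrics_mod, signal_io

__all__ = ["PipelineConfig", "EvaluationReport", "cross_validate", "run_pipeline",
           "channel_ranking"]

logger = logging.getLogger(__name__)

_LABEL_TO_SIGN = {"control": -1, "alcoholic": 1}
_SIGN_TO_LABEL = {-1: "control", 1: "alcoholic"}


@dataclass
class PipelineConfig:
    """Knobs of the full detection pipeline (worked-example defaults)."""

    n_segments: int = 4
    k: int = 32
    target_k: int = 30
    cluster_size: int = 120
    bootstrap_b: int = 100
    alpha: float = 0.05
    folds: int = 5
    inner_folds: int = 3
    seed: int = 0
    tune: bool = True
    fsvm: fsvm.FSVMConfig = field(default_factory=fsvm.FSVMConfig)
    foa: foa.FOAConfig = field(default_factory=foa.FOAConfig)

    def __post_init__(self) -> None:
        if self.cluster_size % coveig.N_SUBCLUSTERS:
            raise ValueError("cluster_size must be divisible by 4")
        if self.target_k > self.k:
            raise ValueError("target_k must not exceed k")


@dataclass
class EvaluationReport:
    counts: metrics_mod.ConfusionCounts
    metrics: dict
    folds: list  # per fold: {fold, Z, gamma, accuracy, n_test}
    config: dict
    seed: int


class _SegmentScaler:
    """Per-segment column z-scoring plus 1/sqrt(dim) shrinkage.

    Segments cover different channel blocks, whose power differs by orders
    of magnitude; z-scoring each segment group separately (with training
    statistics) removes that nuisance scale while keeping the class signal.
    The final 1/sqrt(n_features) factor makes squared pairwise distances
    O(1), so the RBF width search operates on a scale-free space.  Segment
    index is instance metadata known at prediction time.
    """

    def fit(self, X, segments):
        self.norm_ = np.sqrt(X.shape[1])
        self.global_ = StandardScaler().fit(X)
        self.per_segment_ = {}
        for g in np.unique(segments):
            rows = X[segments == g]
            if len(rows) >= 2:
                self.per_segment_[g] = StandardScaler().fit(rows)
        return self

    def transform(self, X, segments):
        out = np.empty_like(X, dtype=float)
        for g in np.unique(segments):
            mask = segments == g
            sc = self.per_segment_.get(g, self.global_)
            out[mask] = sc.transform(X[mask])
        return out / self.norm_


def _fit_fold(X_tr, y_tr, seg_tr, config: PipelineConfig, fold_seed: int):
    """Tune (Z, gamma) by FOA on the training part only, then fit."""
    scaler = _SegmentScaler().fit(X_tr, seg_tr)
    X_tr = scaler.transform(X_tr, seg_tr)
    base = config.fsvm

    def fitness(Z: float, gamma: float) -> float:
        cfg = replace(base, Z=Z, gamma=gamma)
        inner = StratifiedKFold(
            n_splits=config.inner_folds, shuffle=True, random_state=fold_seed % 2**31
        )
        correct = 0
        for tr_idx, te_idx in inner.split(X_tr, y_tr):
            if len(np.unique(y_tr[tr_idx])) < 2:
                return -np.inf
            model = fsvm.fit_fsvm(X_tr[tr_idx], y_tr[tr_idx], cfg)
            correct += int(np.sum(fsvm.predict(model, X_tr[te_idx]) == y_tr[te_idx]))
        return correct / len(y_tr)

    if config.tune:
        foa_cfg = replace(config.foa, seed=fold_seed % 2**31)
        result = foa.optimize(fitness, foa_cfg)
        Z, gamma = result.best_params
    else:
        Z, gamma = base.Z, base.gamma
    model = fsvm.fit_fsvm(X_tr, y_tr, replace(base, Z=Z, gamma=gamma))
    return model, scaler, Z, gamma


def cross_validate(
    table: coveig.FeatureTable,
    config: PipelineConfig | None = None,
    folds: int | None = None,
    seed: int | None = None,
) -> EvaluationReport:
    """Stratified k-fold CV with per-fold KS screening and FOA tuning."""
    config = config or PipelineConfig()
    folds = folds if folds is not None else config.folds
    seed = seed if seed is not None else config.seed
    labels = np.array(table.labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % 2**31)
    y_true_all, y_pred_all, fold_rows = [], [], []
    idx_all = np.arange(len(labels))
    for fold_no, (tr_idx, te_idx) in enumerate(skf.split(idx_all, labels)):
        fold_seed = seed + 1000003 * (fold_no + 1)
        # KS screening on a stratified half-split of the training fold only
        half_a, half_b = train_test_split(
            tr_idx, test_size=0.5, stratify=labels[tr_idx],
            random_state=fold_seed % 2**31,
        )
        sub_train = _subset(table, half_a)
        sub_test = _subset(table, half_b)
        try:
            report = ks_selection.select_features(sub_train, sub_test, config.alpha)
            masked = ks_selection.apply_mask(_subset(table, idx_all), report)
        except ValueError as exc:
            logger.warning("fold %d: KS screen kept nothing (%s); using all features",
                           fold_no, exc)
            masked = table
        X = masked.values.to_numpy()
        y = np.array([_LABEL_TO_SIGN[l] for l in labels])
        segments = np.array([p[1] for p in table.provenance])
        model, scaler, Z, gamma = _fit_fold(
            X[tr_idx], y[tr_idx], segments[tr_idx], config, fold_seed
        )
        pred_sign = fsvm.predict(model, scaler.transform(X[te_idx], segments[te_idx]))
        preds = [_SIGN_TO_LABEL[int(s)] for s in pred_sign]
        truth = list(labels[te_idx])
        y_pred_all += preds
        y_true_all += truth
        acc = float(np.mean([p == t for p, t in zip(preds, truth)]))
        fold_rows.append(
            {"fold": fold_no, "Z": float(Z), "gamma": float(gamma),
             "accuracy": acc, "n_test": len(te_idx)}
        )
    counts = metrics_mod.confusion_counts(y_true_all, y_pred_all)
    return EvaluationReport(
        counts=counts,
        metrics=metrics_mod.metrics(counts),
        folds=fold_rows,
        config=asdict(config),
        seed=seed,
    )


def _subset(table: coveig.FeatureTable, idx) -> coveig.FeatureTable:
    idx = np.asarray(idx)
    return coveig.FeatureTable(
        values=table.values.iloc[idx].reset_index(drop=True),
        labels=[table.labels[i] for i in idx],
        provenance=[table.provenance[i] for i in idx],
    )


def run_pipeline(recordings, config: PipelineConfig | None = None) -> EvaluationReport:
    """segment -> CT-BS -> cov-eig features -> KS screen -> FOA-F-SVM -> CV."""
    config = config or PipelineConfig()
    recordings = list(recordings)
    per_class = {}
    for r in recordings:
        per_class[r.label] = per_class.get(r.label, 0) + 1
    if len(per_class) < 2 or min(per_class.values()) < 2:
        raise ValueError(f"need >= 2 recordings per class, got {per_class}")
    table = coveig.build_feature_table(
        recordings,
        n_segments=config.n_segments,
        k=config.k,
        target_k=config.target_k,
        cluster_size=config.cluster_size,
        bootstrap_b=config.bootstrap_b,
        seed=config.seed,
    )
    return cross_validate(table, config)


def channel_ranking(recordings, config: PipelineConfig | None = None) -> list:
    """Per-channel pipeline accuracy, ranked descending (ties: channel order)."""
    config = config or PipelineConfig()
    recordings = list(recordings)
    n_channels = recordings[0].n_channels
    if n_channels < 2:
        raise ValueError("channel ranking needs >= 2 channels")
    rows = []
    for c in range(n_channels):
        restricted = [r.select_channels([c]) for r in recordings]
        rep = run_pipeline(restricted, config)
        rows.append((recordings[0].channel_names[c], rep.metrics["accuracy"]))
    order = sorted(range(len(rows)), key=lambda i: (-rows[i][1], i))
    return [rows[i] for i in order]
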