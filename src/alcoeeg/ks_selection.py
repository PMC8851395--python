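"""Two-sample Kolmogorov–Smirnov screening of the ten statistic types.

For each statistic type, all features of that type are pooled across
sub-clusters and clusters, and the control and alcoholic pools are compared
with the two-sample KS test — once within a training table and once within
a testing table.  A type is *accepted* only if both p-values fall at or
below the significance level (0.05, inclusive); the acceptance rate is the
percentage of the ten types accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .coveig import STAT_NAMES, FeatureTable

__all__ = [
    "SelectionReport",
    "ks_two_sample",
    "decide_feature",
    "select_features",
    "apply_mask",
    "acceptance_rate_from_pvalues",
]

ACCEPTED = "accepted"
REJECTED = "rejected"

#: exact p-value computation up to this smaller-sample size, asymptotic above
EXACT_N_MAX = 25


@dataclass
class SelectionReport:
    alpha: float
    p_train: dict  # statistic type -> p-value within the training table
    p_test: dict
    decisions: dict  # statistic type -> "accepted" | "rejected"

    @property
    def acceptance_rate(self) -> float:
        """Percent of the ten statistic types accepted."""
        n = sum(1 for d in self.decisions.values() if d == ACCEPTED)
        return 100.0 * n / len(self.decisions)

    @property
    def accepted_types(self) -> list:
        return [s for s in STAT_NAMES if self.decisions.get(s) == ACCEPTED]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "acceptance_rate": self.acceptance_rate,
            "types": {
                s: {
                    "p_test": self.p_test[s],
                    "p_train": self.p_train[s],
                    "decision": self.decisions[s],
                }
                for s in self.decisions
            },
        }


def ks_two_sample(a, b) -> tuple[float, float]:
    """D statistic and p-value of the two-sample KS test.

    D is the supremum gap between the empirical CDFs.  The p-value uses the
    exact null distribution when ``min(n_a, n_b) <= 25`` and the asymptotic
    Kolmogorov distribution with effective n = n_a n_b/(n_a + n_b) otherwise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if min(a.size, b.size) <= EXACT_N_MAX else "asymp"
    res = sstats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def decide_feature(p_test: float, p_train: float, alpha: float = 0.05) -> str:
    """Accept a statistic type iff both p-values are <= alpha (inclusive)."""
    for p in (p_test, p_train):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return ACCEPTED if (p_test <= alpha and p_train <= alpha) else REJECTED


def _type_columns(table: FeatureTable, stat: str) -> list:
    return [c for c in table.feature_names if c.endswith("_" + stat)]


def select_features(
    train: FeatureTable, test: FeatureTable, alpha: float = 0.05
) -> SelectionReport:
    """Screen the ten statistic types between classes in train and test tables."""
    if train.feature_names != test.feature_names:
        raise ValueError("train and test tables must share feature naming")
    for tbl, name in ((train, "train"), (test, "test")):
        present = set(tbl.labels)
        if present != {"control", "alcoholic"}:
            raise ValueError(f"{name} table must contain both classes, has {present}")
    p_train, p_test, decisions = {}, {}, {}
    for stat in STAT_NAMES:
        cols = _type_columns(train, stat)
        if not cols:
            raise ValueError(f"no features of type {stat!r} in table")
        _, p_tr = ks_two_sample(
            train.class_values("control", cols), train.class_values("alcoholic", cols)
        )
        _, p_te = ks_two_sample(
            test.class_values("control", cols), test.class_values("alcoholic", cols)
        )
        p_train[stat], p_test[stat] = p_tr, p_te
        decisions[stat] = decide_feature(p_te, p_tr, alpha)
    return SelectionReport(alpha=alpha, p_train=p_train, p_test=p_test, decisions=decisions)


def apply_mask(table: FeatureTable, report: SelectionReport) -> FeatureTable:
    """Retain exactly the features of accepted types, preserving column order."""
    accepted = set(report.accepted_types)
    if not accepted:
        raise ValueError(
            "no statistic types accepted; review alpha or the screening tables"
        )
    keep = [
        c for c in table.feature_names
        if any(c.endswith("_" + s) for s in accepted)
    ]
    return FeatureTable(
        values=table.values[keep].copy(),
        labels=list(table.labels),
        provenance=list(table.provenance),
    )


def acceptance_rate_from_pvalues(pvalues: dict, alpha: float = 0.05) -> float:
    """Replay the decision rule over ``{stat: (p_test, p_train)}`` pairs.

    Returns the acceptance rate in percent; used to reproduce the published
    channel-subset screening outcomes from their printed p-values.
    """
    decisions = [decide_feature(pt, ptr, alpha) for pt, ptr in pvalues.values()]
    return 100.0 * sum(d == ACCEPTED for d in decisions) / len(decisions)
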