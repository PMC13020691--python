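"""Evaluation statistics: ARI, DBI, Cramér's V, tree accuracy, AUROC.

Conventions for degenerate inputs keep batch reports total rather than
crashing: a constant label vector gives Cramér's V = 0 and ARI = 0
against any partition; a single nonempty cluster gives DBI = NaN.
Missing labels (NaN or negative sentinels) are dropped pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import contingency
from sklearn.metrics import (
    adjusted_rand_score,
    davies_bouldin_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "adjusted_rand_index",
    "davies_bouldin",
    "cramers_v",
    "interpretability_accuracy",
    "outcome_association",
    "concordance_matrix",
    "EvaluationReport",
]


def _clean_pair(labels_a, labels_b):
    """Drop positions where either side is missing (NaN or < 0)."""
    a = np.asarray(labels_a, dtype=float).ravel()
    b = np.asarray(labels_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b) & (a >= 0) & (b >= 0)
    return a[ok].astype(int), b[ok].astype(int)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions.

    1 for identical partitions up to relabeling; 0 in expectation for
    independent partitions under the permutation model. NaN when no
    jointly observed positions remain.
    """
    a, b = _clean_pair(labels_a, labels_b)
    if a.size == 0:
        return float("nan")
    return float(adjusted_rand_score(a, b))


def davies_bouldin(points: np.ndarray, labels) -> float:
    """Davies–Bouldin index: mean over clusters of the worst
    (S_i + S_j) / M_ij ratio; lower means tighter, better-separated
    clusters.  S_i is the mean Euclidean distance to the cluster
    centroid and M_ij the distance between centroids.

    NaN for fewer than two nonempty clusters or coincident centroids.
    """
    X = np.asarray(points, dtype=float)
    lab = np.asarray(labels)
    if not np.isfinite(X).all():
        raise ValueError("points must be finite")
    uniq = np.unique(lab)
    if uniq.size < 2:
        return float("nan")
    cents = np.vstack([X[lab == c].mean(axis=0) for c in uniq])
    d = np.linalg.norm(cents[:, None] - cents[None, :], axis=-1)
    if np.any(d[~np.eye(len(uniq), dtype=bool)] == 0):
        return float("nan")  # coincident centroids: ratio undefined
    if uniq.size == X.shape[0]:
        return 0.0  # all clusters singletons: every scatter S_i is zero
    return float(davies_bouldin_score(X, lab))


def cramers_v(labels_a, labels_b) -> float:
    """Cramér's V association between two categorical vectors.

    sqrt((chi2/n) / min(r-1, c-1)), no bias correction; invariant to
    relabeling either side, hence usable to compare clusterings with
    unmatched labels or different cluster counts.  0 by convention when
    either side is constant.
    """
    a, b = _clean_pair(labels_a, labels_b)
    if a.size == 0:
        return float("nan")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        return 0.0
    table = contingency.crosstab(a, b).count
    return float(contingency.association(table, method="cramer", correction=False))


def interpretability_accuracy(
    features: np.ndarray,
    labels,
    *,
    n_folds: int = 10,
    max_depth: int | None = None,
    seed: int = 0,
) -> float:
    """Cross-validated accuracy (%) of a classification tree predicting
    cluster membership from the features.

    High accuracy means the clusters can be "unpacked" into a compact,
    transparent rule over the original features; chance level for K
    balanced clusters is 100/K %.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    ok = np.isfinite(np.asarray(y, dtype=float)) & (np.asarray(y, dtype=float) >= 0)
    X, y = X[ok], y[ok].astype(int)
    if np.unique(y).size < 2:
        return float("nan")
    n_folds = min(n_folds, int(np.bincount(y)[np.bincount(y) > 0].min()))
    if n_folds < 2:
        return float("nan")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    correct = 0
    for train, test in skf.split(X, y):
        tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
        tree.fit(X[train], y[train])
        correct += int((tree.predict(X[test]) == y[test]).sum())
    return 100.0 * correct / len(y)


def outcome_association(labels, outcome_binary) -> float:
    """AUROC of a logistic model using cluster membership as the only
    (categorical) predictor.

    With a single saturated categorical predictor the fitted
    probability of each observation is its cluster's event rate, so the
    AUROC is computed from those rates directly; this closed form is
    the logistic MLE and is immune to perfect-separation issues.
    NaN for a constant outcome.
    """
    lab, y = _clean_pair(labels, outcome_binary)
    if lab.size == 0:
        return float("nan")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    if np.unique(y).size < 2:
        return float("nan")
    rates = {c: y[lab == c].mean() for c in np.unique(lab)}
    fitted = np.array([rates[c] for c in lab])
    return float(roc_auc_score(y, fitted))


def concordance_matrix(assignments: dict) -> pd.DataFrame:
    """Pairwise Cramér's V between named cluster assignments.

    ``assignments`` maps a name (e.g. pipeline id) to a label vector
    over the same observations.  Symmetric with unit diagonal; NaN
    rows/columns for assignments that are entirely missing.
    """
    names = list(assignments)
    lengths = {len(np.asarray(v).ravel()) for v in assignments.values()}
    if len(lengths) > 1:
        raise ValueError("all assignments must cover the same observations")
    M = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        va = np.asarray(assignments[a], dtype=float)
        if not (np.isfinite(va) & (va >= 0)).any():
            M.loc[a, :] = np.nan
            M.loc[:, a] = np.nan
            continue
        for b in names[i + 1 :]:
            v = cramers_v(assignments[a], assignments[b])
            M.loc[a, b] = v
            M.loc[b, a] = v
    return M


@dataclass
class EvaluationReport:
    """Summary of one pipeline's performance on one dataset."""

    robustness_ari: float = float("nan")
    interpretability_accuracy: float = float("nan")
    ground_truth_v: float = float("nan")
    outcome_auroc: dict = field(default_factory=dict)
    n_clusters_detected: int | None = None
    failure_flag: str = ""

    def to_row(self) -> dict:
        row = {
            "robustness_ari": self.robustness_ari,
            "interpretability_accuracy": self.interpretability_accuracy,
            "ground_truth_v": self.ground_truth_v,
            "n_clusters_detected": self.n_clusters_detected,
            "failure_flag": self.failure_flag,
        }
        for name, auc in self.outcome_auroc.items():
            row[f"auroc_{name}"] = auc
        return row
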