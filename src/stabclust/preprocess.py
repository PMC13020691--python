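"""Feature-table preprocessing: mean imputation, correlation pruning, z-scoring.

Fit-on-train / apply-on-test semantics: all statistics (imputation
means, surviving columns, scaling parameters) are estimated once on the
training table and reapplied verbatim to any later table, so folds and
bootstrap resamples see a consistent feature space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["PreprocessModel", "fit_preprocess", "apply_preprocess"]


@dataclass(frozen=True)
class PreprocessModel:
    """Frozen preprocessing state.

    Parameters estimated at fit time: per-column imputation means
    (over observed entries), indices of columns surviving the
    zero-variance and correlation filters (original order), and the
    mean/SD used for z-scoring the kept columns.
    """

    column_means: np.ndarray  # imputation value per original column
    kept_columns: np.ndarray  # sorted original indices that survive
    scale_means: np.ndarray  # per kept column
    scale_sds: np.ndarray  # per kept column, all > 0
    corr_threshold: float

    @property
    def n_features_in(self) -> int:
        return len(self.column_means)

    @property
    def n_features_out(self) -> int:
        return len(self.kept_columns)

    def transform(self, features: np.ndarray) -> np.ndarray:
        return apply_preprocess(self, features)

    def to_json(self) -> str:
        return json.dumps(
            {
                "column_means": self.column_means.tolist(),
                "kept_columns": self.kept_columns.tolist(),
                "scale_means": self.scale_means.tolist(),
                "scale_sds": self.scale_sds.tolist(),
                "corr_threshold": self.corr_threshold,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PreprocessModel":
        d = json.loads(text)
        return cls(
            column_means=np.asarray(d["column_means"], float),
            kept_columns=np.asarray(d["kept_columns"], int),
            scale_means=np.asarray(d["scale_means"], float),
            scale_sds=np.asarray(d["scale_sds"], float),
            corr_threshold=float(d["corr_threshold"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PreprocessModel":
        return cls.from_json(Path(path).read_text())


def fit_preprocess(
    features: np.ndarray, corr_threshold: float = 0.95
) -> PreprocessModel:
    """Fit imputation, correlation-filter and scaling parameters.

    Missing entries are imputed with the column mean of observed
    values.  On the imputed table, zero-variance columns are dropped,
    then for every pair with absolute Pearson correlation above
    ``corr_threshold`` the later column (original order) is dropped.
    Kept columns are finally z-scored.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need a 2-D table with >= 2 observations and >= 1 feature")
    if not 0 < corr_threshold <= 1:
        raise ValueError("corr_threshold must be in (0, 1]")

    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        bad = np.flatnonzero(all_missing)
        raise ValueError(f"column(s) {bad.tolist()} are entirely missing")
    column_means = np.nanmean(X, axis=0)
    Xi = np.where(np.isnan(X), column_means, X)

    sds = Xi.std(axis=0, ddof=0)
    candidates = [j for j in range(X.shape[1]) if sds[j] > 0]

    # greedy pruning in original column order: a column is dropped if it
    # correlates above threshold with any earlier kept column
    kept: list[int] = []
    if candidates:
        R = np.abs(np.corrcoef(Xi[:, candidates], rowvar=False))
        R = np.atleast_2d(R)
        pos = {j: a for a, j in enumerate(candidates)}
        for j in candidates:
            if not any(R[pos[i], pos[j]] > corr_threshold for i in kept):
                kept.append(j)
    if not kept:
        raise ValueError("no columns survive the variance/correlation filters")

    kept_arr = np.asarray(kept, int)
    return PreprocessModel(
        column_means=column_means,
        kept_columns=kept_arr,
        scale_means=Xi[:, kept_arr].mean(axis=0),
        scale_sds=Xi[:, kept_arr].std(axis=0, ddof=0),
        corr_threshold=float(corr_threshold),
    )


def apply_preprocess(model: PreprocessModel, features: np.ndarray) -> np.ndarray:
    """Impute, subset and z-score a table with fitted parameters."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != model.n_features_in:
        raise ValueError(
            f"expected {model.n_features_in} features, got {X.shape[1]}"
        )
    Xi = np.where(np.isnan(X), model.column_means, X)
    Z = Xi[:, model.kept_columns]
    return (Z - model.scale_means) / model.scale_sds
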