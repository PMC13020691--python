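"""Bootstrap-stability hyperparameter search for clustering chains.

The search statistic: for one hyperparameter combination, the chain is
refitted on ``n_bootstrap`` resamples (a fraction of the data drawn
with replacement); each refitted model assigns cluster labels to the
*full* dataset through the chain's out-of-sample path, and the mean
adjusted Rand index over the B-1 consecutive pairs of those full-data
partitions measures how reproducible the clustering is under resampling.
Compactness is tracked alongside as the mean Davies–Bouldin index of
each bootstrap's full-data partition in that bootstrap's reduced space.

Selection is two-stage: keep the ``top_k_ari`` combinations by mean
ARI (stability first), then pick the lowest mean DBI among them.  ARI
alone favours trivially few clusters — the most stable partition is
often the coarsest — and the DBI stage counterbalances that.

Final cluster membership is produced by k-fold cross-validation: each
observation is labelled by a model that never saw it, and fold models
are aligned to a reference full-data fit by maximum-overlap (Hungarian)
matching so the concatenated labels share one labelling scheme.

``StabilitySearch`` / ``StabilitySearchResults`` wrap the procedure as
model/results objects; the module-level functions expose each step.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.model_selection import KFold

from .metrics import (
    EvaluationReport,
    adjusted_rand_index,
    cramers_v,
    davies_bouldin,
    interpretability_accuracy,
    outcome_association,
)
from .pipelines import (
    KERNELS,
    PIPELINE_STAGES,
    PipelineSpec,
    fit_pipeline,
)

__all__ = [
    "SearchConfig",
    "StabilityRecord",
    "ClusterAssignment",
    "bootstrap_indices",
    "score_combo",
    "grid_search",
    "select_combo",
    "cv_membership",
    "default_grid",
    "StabilitySearch",
    "StabilitySearchResults",
]


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the bootstrap search and the CV membership step."""

    n_bootstrap: int = 100
    bootstrap_fraction: float = 0.9
    sample_with_replacement: bool = True
    n_folds: int = 10
    top_k_ari: int = 5
    seed: int = 0
    knn_k: int = 5  # spectral surrogate neighbourhood
    n_restarts: int = 10  # K-means restarts
    spectral_gamma: float | None = None  # RBF affinity bandwidth; None -> 1/n_features

    def __post_init__(self) -> None:
        if self.n_bootstrap < 2:
            raise ValueError("n_bootstrap must be >= 2")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must be in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.top_k_ari < 1:
            raise ValueError("top_k_ari must be >= 1")


@dataclass(frozen=True)
class StabilityRecord:
    """Stability and compactness of one hyperparameter combination."""

    pipeline_id: str
    combo: dict
    mean_ari: float
    mean_dbi: float
    n_valid_pairs: int
    failure_flag: str = ""
    grid_index: int = 0

    def __post_init__(self) -> None:
        if np.isnan(self.mean_ari) and not self.failure_flag:
            raise ValueError("an NA mean_ari requires a nonempty failure_flag")
        if not np.isnan(self.mean_ari) and self.n_valid_pairs < 1:
            raise ValueError("a present mean_ari requires n_valid_pairs >= 1")

    @property
    def is_valid(self) -> bool:
        return not np.isnan(self.mean_ari)

    def to_row(self) -> dict:
        return {
            "pipeline_id": self.pipeline_id,
            "combo": json.dumps(self.combo, sort_keys=True),
            "mean_ari": self.mean_ari,
            "mean_dbi": self.mean_dbi,
            "n_valid_pairs": self.n_valid_pairs,
            "failure_flag": self.failure_flag,
        }


@dataclass
class ClusterAssignment:
    """Cross-validated cluster membership for every observation."""

    labels: np.ndarray  # -1 marks observations from failed folds
    fold_of: np.ndarray
    combo: dict
    pipeline_id: str
    failed_folds: tuple = ()

    @property
    def n_clusters_detected(self) -> int:
        ok = self.labels >= 0
        return int(np.unique(self.labels[ok]).size) if ok.any() else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "obs_id": np.arange(1, len(self.labels) + 1),
                "fold": self.fold_of,
                "cluster": self.labels,
            }
        )


#: Grid values used when the caller does not supply a grid; the method
#: itself does not prescribe the values, only the search over them.
DEFAULT_GRID_VALUES = {
    "n_clusters": [2, 3, 4, 5, 6],
    "kernel": list(KERNELS),
    "pca_components": [2, 5, 10, 20],
    "nmf_components": [2, 5, 10, 20],
    "perplexity": [5, 15, 30, 50],
}

_PARAM_FOR_STAGE = {
    "kernel_pca": ("kernel", "pca_components"),
    "nmf": ("nmf_components",),
    "tsne": ("perplexity",),
}


def default_grid(pipeline_id: str) -> dict:
    """Default hyperparameter grid restricted to a pipeline's stages."""
    kinds = PIPELINE_STAGES[pipeline_id]
    grid: dict[str, list] = {}
    for kind in kinds[:-1]:
        for name in _PARAM_FOR_STAGE[kind]:
            grid[name] = list(DEFAULT_GRID_VALUES[name])
    grid["n_clusters"] = list(DEFAULT_GRID_VALUES["n_clusters"])
    return grid


def bootstrap_indices(n: int, cfg: SearchConfig) -> list[np.ndarray]:
    """Resample index vectors: ``n_bootstrap`` draws of size
    ``round(bootstrap_fraction * n)``, with or without replacement."""
    if n < 2:
        raise ValueError("need at least 2 observations")
    m = int(round(cfg.bootstrap_fraction * n))
    if m < 2:
        raise ValueError("bootstrap sample size below 2; raise bootstrap_fraction")
    rng = np.random.default_rng(cfg.seed)
    out = []
    for _ in range(cfg.n_bootstrap):
        if cfg.sample_with_replacement:
            out.append(rng.integers(0, n, size=m))
        else:
            out.append(rng.permutation(n)[:m])
    return out


def _combo_seed(seed: int, grid_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), int(grid_index)])


def score_combo(
    data: np.ndarray,
    pipeline_id: str,
    combo: dict,
    cfg: SearchConfig,
    *,
    grid_index: int = 0,
) -> StabilityRecord:
    """Score one hyperparameter combination by bootstrap stability.

    Each bootstrap fits the chain on its resample and labels the full
    dataset out-of-sample; mean_ari averages the ARI of consecutive
    full-data partitions, mean_dbi the per-bootstrap DBI of the
    full-data partition in that bootstrap's reduced space.  Degenerate
    bootstraps (single nonempty cluster, non-finite embedding, fit
    failure) are excluded and recorded in ``failure_flag``.
    """
    spec = PipelineSpec.from_id(pipeline_id, combo)  # validate before fitting
    X = np.asarray(data, dtype=float)
    n = X.shape[0]

    ss = _combo_seed(cfg.seed, grid_index)
    boot_seed, *fit_seeds = (int(s) for s in ss.generate_state(cfg.n_bootstrap + 1) % (2**31))
    idx_list = bootstrap_indices(n, replace(cfg, seed=boot_seed))

    label_runs: list[np.ndarray] = []
    dbis: list[float] = []
    failures: list[str] = []
    for b, idx in enumerate(idx_list):
        try:
            fp = fit_pipeline(
                spec,
                X[idx],
                fit_seeds[b],
                knn_k=cfg.knn_k,
                n_restarts=cfg.n_restarts,
                spectral_gamma=cfg.spectral_gamma,
            )
            labels, rep = fp.assign(X, return_representation=True)
        except ValueError as exc:
            failures.append(f"b{b}:{exc}")
            if b == 0:
                break  # deterministic infeasibility (e.g. components > width)
            continue
        if not np.isfinite(rep).all():
            failures.append(f"b{b}:non_finite_embedding")
            continue
        if np.unique(labels).size < 2:
            failures.append(f"b{b}:single_cluster")
            continue
        label_runs.append(labels)
        dbi = davies_bouldin(rep, labels)
        if np.isfinite(dbi):
            dbis.append(dbi)

    if len(label_runs) >= 2:
        aris = [
            adjusted_rand_index(label_runs[i], label_runs[i + 1])
            for i in range(len(label_runs) - 1)
        ]
        mean_ari = float(np.mean(aris))
        n_valid_pairs = len(aris)
        flag = ";".join(failures[:5])
    else:
        mean_ari = float("nan")
        n_valid_pairs = 0
        flag = ";".join(failures[:5]) or "fewer_than_2_valid_bootstraps"

    mean_dbi = float(np.mean(dbis)) if dbis else float("nan")
    return StabilityRecord(
        pipeline_id=pipeline_id,
        combo=dict(combo),
        mean_ari=mean_ari,
        mean_dbi=mean_dbi,
        n_valid_pairs=n_valid_pairs,
        failure_flag=flag,
        grid_index=grid_index,
    )


def grid_search(
    data: np.ndarray,
    pipeline_id: str,
    grid: dict,
    cfg: SearchConfig,
) -> list[StabilityRecord]:
    """Score the full Cartesian product of a hyperparameter grid.

    Combination order is the lexicographic product over the grid's
    definition order; each combination gets an independent seed derived
    from ``(cfg.seed, combination index)`` so the grid is reproducible
    and order-independent.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    names = list(grid)
    records = []
    for gi, values in enumerate(itertools.product(*(grid[n] for n in names))):
        combo = dict(zip(names, values))
        records.append(score_combo(data, pipeline_id, combo, cfg, grid_index=gi))
    return records


def select_combo(records: list[StabilityRecord], cfg: SearchConfig) -> StabilityRecord:
    """Two-stage selection: top-``top_k_ari`` by mean ARI, then lowest
    mean DBI among them.  Ties at either stage resolve by lower DBI,
    then grid order; NA-DBI records rank last within the shortlist."""
    valid = [r for r in records if r.is_valid]
    if not valid:
        raise ValueError("no stable combination: every record has NA mean_ari")

    def dbi_key(r: StabilityRecord) -> float:
        return r.mean_dbi if np.isfinite(r.mean_dbi) else np.inf

    shortlist = sorted(valid, key=lambda r: (-r.mean_ari, dbi_key(r), r.grid_index))
    shortlist = shortlist[: cfg.top_k_ari]
    return min(shortlist, key=lambda r: (dbi_key(r), r.grid_index))


def _align_labels(
    fold_labels: np.ndarray, ref_labels: np.ndarray
) -> dict[int, int]:
    """Maximum-overlap (Hungarian) map from fold labels to reference labels."""
    f_uniq = np.unique(fold_labels)
    r_uniq = np.unique(ref_labels)
    overlap = np.zeros((f_uniq.size, r_uniq.size))
    for i, fl in enumerate(f_uniq):
        for j, rl in enumerate(r_uniq):
            overlap[i, j] = np.sum((fold_labels == fl) & (ref_labels == rl))
    rows, cols = linear_sum_assignment(-overlap)
    mapping = {int(f_uniq[i]): int(r_uniq[j]) for i, j in zip(rows, cols)}
    # fold clusters beyond the reference count keep distinct new ids
    next_id = int(r_uniq.max()) + 1
    for fl in f_uniq:
        if int(fl) not in mapping:
            mapping[int(fl)] = next_id
            next_id += 1
    return mapping


def cv_membership(
    data: np.ndarray,
    pipeline_id: str,
    combo: dict,
    cfg: SearchConfig,
) -> ClusterAssignment:
    """Cluster membership from mutually exclusive CV test folds.

    The chain is refitted on each fold's complement and the held-out
    observations are labelled out-of-sample; every fold model's labels
    are aligned to a reference fit on all data by maximum-overlap
    matching over the fold's training observations.  Observations of a
    fold whose fit fails carry label -1.
    """
    spec = PipelineSpec.from_id(pipeline_id, combo)
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    ss = np.random.SeedSequence([int(cfg.seed), 7919])
    ref_seed, split_seed, *fold_seeds = (
        int(s) for s in ss.generate_state(cfg.n_folds + 2) % (2**31)
    )

    ref_fp = fit_pipeline(
        spec, X, ref_seed, knn_k=cfg.knn_k, n_restarts=cfg.n_restarts,
        spectral_gamma=cfg.spectral_gamma,
    )
    ref_labels = ref_fp.train_labels

    labels = np.full(n, -1, dtype=int)
    fold_of = np.full(n, -1, dtype=int)
    failed = []
    kf = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=split_seed % (2**31))
    for f, (tr, te) in enumerate(kf.split(X)):
        fold_of[te] = f
        try:
            fp = fit_pipeline(
                spec, X[tr], fold_seeds[f], knn_k=cfg.knn_k,
                n_restarts=cfg.n_restarts, spectral_gamma=cfg.spectral_gamma,
            )
            te_labels = fp.assign(X[te])
        except ValueError:
            failed.append(f)
            continue
        mapping = _align_labels(fp.train_labels, ref_labels[tr])
        labels[te] = [mapping[int(l)] for l in te_labels]
    return ClusterAssignment(
        labels=labels,
        fold_of=fold_of,
        combo=dict(combo),
        pipeline_id=pipeline_id,
        failed_folds=tuple(failed),
    )


# ---------------------------------------------------------------------------
# model / results objects


class StabilitySearch:
    """Bootstrap-stability hyperparameter search for one pipeline.

    Parameters
    ----------
    data : array-like, shape (n_obs, n_features)
        Preprocessed feature matrix (finite, no missing values).
    pipeline : str
        Pipeline id, one of M1..M10.
    grid : dict, optional
        Hyperparameter name -> list of values; defaults to
        :func:`default_grid` for the pipeline.
    config : SearchConfig, optional
    ground_truth : array-like, optional
        Known labels used only for evaluation, never for fitting.

    Examples
    --------
    >>> search = StabilitySearch(X, pipeline="M4",
    ...                          config=SearchConfig(n_bootstrap=20, seed=1))
    >>> res = search.fit()
    >>> res.selected.combo, res.selected.mean_ari
    """

    def __init__(
        self,
        data,
        pipeline: str = "M4",
        grid: dict | None = None,
        config: SearchConfig | None = None,
        ground_truth=None,
    ):
        self.data = np.asarray(data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D matrix")
        if pipeline not in PIPELINE_STAGES:
            raise ValueError(f"unknown pipeline id {pipeline!r}")
        self.pipeline = pipeline
        self.grid = dict(grid) if grid is not None else default_grid(pipeline)
        self.config = config or SearchConfig()
        self.ground_truth = (
            None if ground_truth is None else np.asarray(ground_truth)
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        pipeline: str = "M4",
        feature_columns: list[str] | None = None,
        ground_truth_column: str | None = None,
        **kwargs,
    ) -> "StabilitySearch":
        if feature_columns is None:
            drop = {"obs_id", ground_truth_column}
            feature_columns = [c for c in df.columns if c not in drop]
        gt = df[ground_truth_column].to_numpy() if ground_truth_column else None
        return cls(
            df[feature_columns].to_numpy(float),
            pipeline=pipeline,
            ground_truth=gt,
            **kwargs,
        )

    def fit(self, compute_membership: bool = True) -> "StabilitySearchResults":
        """Run the grid search, select a combination, and (optionally)
        produce the cross-validated membership."""
        records = grid_search(self.data, self.pipeline, self.grid, self.config)
        selected = select_combo(records, self.config)
        membership = None
        if compute_membership:
            membership = cv_membership(
                self.data, self.pipeline, selected.combo, self.config
            )
        return StabilitySearchResults(self, records, selected, membership)


class StabilitySearchResults:
    """Results of a bootstrap-stability search.

    Attributes
    ----------
    records : list of StabilityRecord
    selected : StabilityRecord
        The combination chosen by the top-k-ARI / min-DBI rule.
    membership : ClusterAssignment or None
        Cross-validated cluster membership under the selected combo.
    """

    def __init__(self, model, records, selected, membership):
        self.model = model
        self.records = records
        self.selected = selected
        self.membership = membership

    @property
    def records_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.to_row() for r in self.records])
        df["selected"] = [
            int(r.grid_index == self.selected.grid_index) for r in self.records
        ]
        return df

    @property
    def labels(self) -> np.ndarray | None:
        return None if self.membership is None else self.membership.labels

    @property
    def n_clusters_detected(self) -> int | None:
        return None if self.membership is None else self.membership.n_clusters_detected

    def ground_truth_v(self) -> float:
        """Cramér's V between the CV membership and the known labels."""
        gt = self.model.ground_truth
        if gt is None or self.membership is None:
            return float("nan")
        return cramers_v(self.membership.labels, gt)

    def evaluate(self, outcomes: pd.DataFrame | None = None) -> EvaluationReport:
        """Robustness, interpretability and (optional) outcome AUROCs."""
        rep = EvaluationReport(
            robustness_ari=self.selected.mean_ari,
            failure_flag=self.selected.failure_flag,
        )
        if self.membership is not None:
            rep.n_clusters_detected = self.membership.n_clusters_detected
            rep.interpretability_accuracy = interpretability_accuracy(
                self.model.data,
                self.membership.labels,
                seed=self.model.config.seed,
            )
            if self.model.ground_truth is not None:
                rep.ground_truth_v = self.ground_truth_v()
            if outcomes is not None:
                for col in outcomes.columns:
                    rep.outcome_auroc[col] = outcome_association(
                        self.membership.labels, outcomes[col].to_numpy()
                    )
        return rep

    def summary(self) -> str:
        """Plain-text summary of the search, statsmodels-style."""
        cfg = self.model.config
        lines = [
            "Bootstrap stability search results",
            "=" * 54,
            f"Pipeline:            {self.model.pipeline} "
            f"({' -> '.join(PIPELINE_STAGES[self.model.pipeline])})",
            f"Observations:        {self.model.data.shape[0]}",
            f"Features:            {self.model.data.shape[1]}",
            f"Bootstraps:          {cfg.n_bootstrap} "
            f"(fraction {cfg.bootstrap_fraction}, "
            f"{'with' if cfg.sample_with_replacement else 'without'} replacement)",
            f"Combinations tried:  {len(self.records)}",
            f"Selected combo:      {json.dumps(self.selected.combo, sort_keys=True)}",
            f"  mean ARI:          {self.selected.mean_ari:.4f}",
            f"  mean DBI:          {self.selected.mean_dbi:.4f}",
        ]
        if self.membership is not None:
            lines.append(f"Clusters detected:   {self.n_clusters_detected}")
        if self.model.ground_truth is not None and self.membership is not None:
            lines.append(f"Ground-truth V:      {self.ground_truth_v():.4f}")
        lines.append("-" * 54)
        top = self.records_frame.sort_values(
            "mean_ari", ascending=False
        ).head(self.model.config.top_k_ari)
        lines.append("Top combinations by mean ARI:")
        lines.append(
            top[["combo", "mean_ari", "mean_dbi", "selected"]].to_string(index=False)
        )
        return "\n".join(lines)
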