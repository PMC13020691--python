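"""The ten dimensionality-reduction -> clustering chains (M1..M10).

Each pipeline is an ordered chain of zero or more reduction stages
(kernel PCA, NMF, t-SNE) ending in one clustering stage (K-means or
spectral).  Fitted chains support a uniform out-of-sample assignment
path, which is what makes bootstrap stability scoring and fold-based
cross-validation of an unsupervised model possible at all:

* K-means endings assign new points to the nearest centroid;
* spectral endings — which retain no out-of-sample map — use a k
  nearest-neighbour surrogate that "records" the training partition
  and votes among the k closest training points in the reduced space;
* t-SNE stages retain no transform either, so chains containing t-SNE
  re-embed the union of training and new points jointly.  This is the
  faithful treatment of an embedding with no parametric map, and its
  run-to-run inconsistency is a property of the method, not a defect
  of the implementation.

NMF requires nonnegative input while upstream z-scoring produces
negatives, so NMF stages min-max rescale their input to [0, 1]
column-wise (parameters learned on the training sample; new data is
clipped into the box).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans, SpectralClustering
from sklearn.decomposition import NMF, KernelPCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.manifold import TSNE

__all__ = [
    "StageSpec",
    "PipelineSpec",
    "FittedPipeline",
    "PIPELINE_STAGES",
    "PIPELINE_IDS",
    "KERNELS",
    "fit_pipeline",
    "assign_out_of_sample",
    "reduced_representation",
]

#: Admissible kernels for the kernel-PCA stage.
KERNELS = ("sigmoid", "rbf", "linear", "cosine", "polynomial")

#: Hyperparameter names admissible per stage kind.
STAGE_PARAMS = {
    "kernel_pca": frozenset({"kernel", "n_components"}),
    "nmf": frozenset({"n_components"}),
    "tsne": frozenset({"perplexity"}),
    "kmeans": frozenset({"n_clusters"}),
    "spectral": frozenset({"n_clusters"}),
}
CLUSTER_KINDS = frozenset({"kmeans", "spectral"})

#: Stage sequences of the ten pipelines.
PIPELINE_STAGES = {
    "M1": ("kmeans",),
    "M2": ("kernel_pca", "kmeans"),
    "M3": ("nmf", "kernel_pca", "kmeans"),
    "M4": ("nmf", "kmeans"),
    "M5": ("spectral",),
    "M6": ("kernel_pca", "spectral"),
    "M7": ("nmf", "kernel_pca", "spectral"),
    "M8": ("nmf", "spectral"),
    "M9": ("tsne", "kernel_pca", "kmeans"),
    "M10": ("tsne", "kmeans"),
}
PIPELINE_IDS = tuple(PIPELINE_STAGES)

#: Flat hyperparameter names used in grids/combos, mapped to
#: (stage kind, stage-level parameter name).
COMBO_PARAMS = {
    "n_clusters": (None, "n_clusters"),  # terminal clusterer, either kind
    "kernel": ("kernel_pca", "kernel"),
    "pca_components": ("kernel_pca", "n_components"),
    "nmf_components": ("nmf", "n_components"),
    "perplexity": ("tsne", "perplexity"),
}


@dataclass(frozen=True)
class StageSpec:
    """One stage of a chain: its kind and hyperparameters."""

    kind: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in STAGE_PARAMS:
            raise ValueError(f"unknown stage kind {self.kind!r}")
        extra = set(self.hyperparams) - STAGE_PARAMS[self.kind]
        if extra:
            raise ValueError(
                f"hyperparameters {sorted(extra)} not valid for {self.kind!r}"
            )
        if self.kind == "kernel_pca":
            kern = self.hyperparams.get("kernel", "linear")
            if kern not in KERNELS:
                raise ValueError(f"unknown kernel {kern!r}")


@dataclass(frozen=True)
class PipelineSpec:
    """An ordered chain of stages, identified as one of M1..M10."""

    pipeline_id: str
    stages: tuple

    def __post_init__(self) -> None:
        if self.pipeline_id not in PIPELINE_STAGES:
            raise ValueError(f"unknown pipeline id {self.pipeline_id!r}")
        kinds = tuple(s.kind for s in self.stages)
        if kinds != PIPELINE_STAGES[self.pipeline_id]:
            raise ValueError(
                f"{self.pipeline_id} requires stages {PIPELINE_STAGES[self.pipeline_id]}, "
                f"got {kinds}"
            )
        for s in self.stages[:-1]:
            if s.kind in CLUSTER_KINDS:
                raise ValueError("clustering stages may only appear last")
        if self.stages[-1].kind not in CLUSTER_KINDS:
            raise ValueError("final stage must be a clustering stage")

    @classmethod
    def from_id(cls, pipeline_id: str, combo: dict | None = None) -> "PipelineSpec":
        """Build a concrete spec from a flat hyperparameter combo.

        ``combo`` uses flat names (``n_clusters``, ``kernel``,
        ``pca_components``, ``nmf_components``, ``perplexity``); names
        irrelevant to the pipeline's stages are rejected.
        """
        combo = dict(combo or {})
        kinds = PIPELINE_STAGES.get(pipeline_id)
        if kinds is None:
            raise ValueError(f"unknown pipeline id {pipeline_id!r}")
        per_stage: dict[str, dict] = {k: {} for k in kinds}
        for name, value in combo.items():
            if name not in COMBO_PARAMS:
                raise ValueError(f"unknown hyperparameter {name!r}")
            kind, param = COMBO_PARAMS[name]
            if kind is None:  # terminal clusterer
                kind = kinds[-1]
            if kind not in per_stage:
                raise ValueError(
                    f"hyperparameter {name!r} does not apply to {pipeline_id}"
                )
            per_stage[kind][param] = value
        stages = tuple(StageSpec(k, per_stage[k]) for k in kinds)
        return cls(pipeline_id=pipeline_id, stages=stages)

    @property
    def uses_tsne(self) -> bool:
        return any(s.kind == "tsne" for s in self.stages)

    @property
    def terminal_kind(self) -> str:
        return self.stages[-1].kind


# ---------------------------------------------------------------------------
# fitted stage wrappers


class _KPCAStage:
    def __init__(self, spec: StageSpec, X: np.ndarray, seed: int):
        n_components = int(spec.hyperparams.get("n_components", 2))
        if n_components > X.shape[1]:
            raise ValueError(
                f"kernel_pca n_components={n_components} exceeds input width {X.shape[1]}"
            )
        self.model = KernelPCA(
            n_components=n_components,
            kernel=spec.hyperparams.get("kernel", "linear"),
            random_state=seed,
        )
        self.train_output = self.model.fit_transform(X)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.model.transform(X)


class _NMFStage:
    def __init__(self, spec: StageSpec, X: np.ndarray, seed: int):
        n_components = int(spec.hyperparams.get("n_components", 2))
        if n_components > X.shape[1]:
            raise ValueError(
                f"nmf n_components={n_components} exceeds input width {X.shape[1]}"
            )
        self.col_min = X.min(axis=0)
        rng = X.max(axis=0) - self.col_min
        rng[rng == 0] = 1.0
        self.col_range = rng
        self.converged = True
        self.model = NMF(
            n_components=n_components,
            init="nndsvda",
            max_iter=400,
            random_state=seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            self.train_output = self.model.fit_transform(self._rescale(X))
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                self.converged = False

    def _rescale(self, X: np.ndarray) -> np.ndarray:
        return np.clip((X - self.col_min) / self.col_range, 0.0, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            return self.model.transform(self._rescale(X))


class _TSNEStage:
    """t-SNE keeps no parametric map: store inputs, re-embed jointly."""

    def __init__(self, spec: StageSpec, X: np.ndarray, seed: int):
        self.perplexity = float(spec.hyperparams.get("perplexity", 30.0))
        self.seed = seed
        self.input_train = X
        self.train_output = self._embed(X)

    def _embed(self, X: np.ndarray) -> np.ndarray:
        tsne = TSNE(
            n_components=2,
            perplexity=min(self.perplexity, (X.shape[0] - 1) / 3.0),
            random_state=self.seed,
            init="pca",
        )
        return tsne.fit_transform(X)

    def joint_embed(self, new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Re-embed training and new points together; return both parts."""
        union = np.vstack([self.input_train, new])
        emb = self._embed(union)
        n_train = self.input_train.shape[0]
        return emb[:n_train], emb[n_train:]

    def transform(self, X: np.ndarray) -> np.ndarray:
        raise RuntimeError(
            "t-SNE retains no out-of-sample transform; use joint re-embedding"
        )


_STAGE_CLASSES = {"kernel_pca": _KPCAStage, "nmf": _NMFStage, "tsne": _TSNEStage}


@dataclass
class FittedPipeline:
    """A fitted chain: reduction transforms plus clustering state."""

    spec: PipelineSpec
    dr_stages: list
    reduced_train: np.ndarray
    train_labels: np.ndarray
    train_matrix: np.ndarray
    knn_k: int
    centroids: np.ndarray | None  # K-means endings
    seed: int
    warnings: tuple = ()

    @property
    def n_clusters_found(self) -> int:
        return len(np.unique(self.train_labels))

    def assign(self, new_matrix: np.ndarray, return_representation: bool = False):
        return assign_out_of_sample(
            self, new_matrix, return_representation=return_representation
        )


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def fit_pipeline(
    spec: PipelineSpec,
    train_matrix: np.ndarray,
    seed: int,
    *,
    knn_k: int = 5,
    n_restarts: int = 10,
    spectral_gamma: float | None = None,
) -> FittedPipeline:
    """Fit reduction stages sequentially, then the terminal clusterer.

    Deterministic for a fixed seed; sub-seeds for each stochastic stage
    are derived from ``seed``.  ``spectral_gamma`` sets the RBF affinity
    bandwidth of spectral endings; the default 1/n_features keeps the
    affinity graph non-degenerate regardless of dimensionality.
    """
    X = np.asarray(train_matrix, dtype=float)
    if np.isnan(X).any() or not np.isfinite(X).all():
        raise ValueError("training matrix must be finite with no missing values")
    seeds = _derive_seeds(seed, len(spec.stages) + 1)
    flags: list[str] = []

    cur = X
    dr_stages = []
    for i, stage in enumerate(spec.stages[:-1]):
        fitted = _STAGE_CLASSES[stage.kind](stage, cur, int(seeds[i]))
        if getattr(fitted, "converged", True) is False:
            flags.append(f"nmf_not_converged(stage={i})")
        dr_stages.append(fitted)
        cur = fitted.train_output

    terminal = spec.stages[-1]
    n_clusters = int(terminal.hyperparams.get("n_clusters", 3))
    clust_seed = int(seeds[-1])
    if terminal.kind == "kmeans":
        km = KMeans(n_clusters=n_clusters, n_init=n_restarts, random_state=clust_seed)
        labels = km.fit_predict(cur)
        centroids = km.cluster_centers_
    else:
        gamma = 1.0 / cur.shape[1] if spectral_gamma is None else spectral_gamma
        sc = SpectralClustering(
            n_clusters=n_clusters,
            affinity="rbf",
            gamma=gamma,
            random_state=clust_seed,
            n_init=n_restarts,
        )
        labels = sc.fit_predict(cur)
        centroids = None

    return FittedPipeline(
        spec=spec,
        dr_stages=dr_stages,
        reduced_train=cur,
        train_labels=np.asarray(labels),
        train_matrix=X,
        knn_k=knn_k,
        centroids=centroids,
        seed=seed,
        warnings=tuple(flags),
    )


def reduced_representation(fp: FittedPipeline, matrix: np.ndarray) -> np.ndarray:
    """Push data through the stored reduction stages only.

    For chains without reduction stages this is the identity.  t-SNE
    chains have no stored transform: the training matrix itself maps to
    the stored embedding, anything else is an error (joint re-embedding
    lives in :func:`assign_out_of_sample`).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != fp.train_matrix.shape[1]:
        raise ValueError(
            f"expected {fp.train_matrix.shape[1]} features, got {X.shape[1]}"
        )
    if fp.spec.uses_tsne:
        if X.shape == fp.train_matrix.shape and np.array_equal(X, fp.train_matrix):
            return fp.reduced_train
        raise ValueError(
            "t-SNE chains retain no out-of-sample transform; "
            "only the training matrix has a stored representation"
        )
    cur = X
    for stage in fp.dr_stages:
        cur = stage.transform(cur)
    return cur


def _nearest_centroid(rep: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # argmin takes the first minimum, so exact ties go to the smaller label
    d = cdist(rep, centroids, metric="sqeuclidean")
    return d.argmin(axis=1)


def _knn_vote(
    rep: np.ndarray, train_rep: np.ndarray, train_labels: np.ndarray, k: int
) -> np.ndarray:
    d = cdist(rep, train_rep)
    k = min(k, train_rep.shape[0])
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    out = np.empty(rep.shape[0], dtype=int)
    for i, row in enumerate(order):
        votes = np.bincount(train_labels[row])
        out[i] = votes.argmax()  # first max -> smallest label on ties
    return out


def assign_out_of_sample(
    fp: FittedPipeline,
    new_matrix: np.ndarray,
    *,
    return_representation: bool = False,
):
    """Assign cluster labels to new observations.

    K-means endings use the nearest stored centroid (ties to the
    smaller label); spectral endings a majority vote among the ``k``
    nearest training points in the reduced space (ties to the smaller
    label).  Chains with a t-SNE stage re-embed training and new points
    jointly, push both through the remaining stored stages and assign
    against cluster statistics recomputed from the training partition.
    """
    X = np.asarray(new_matrix, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[0] == 0:
        empty = np.empty(0, dtype=int)
        return (empty, np.empty((0, fp.reduced_train.shape[1]))) if return_representation else empty
    if X.shape[1] != fp.train_matrix.shape[1]:
        raise ValueError(
            f"expected {fp.train_matrix.shape[1]} features, got {X.shape[1]}"
        )

    if fp.spec.uses_tsne:
        # joint re-embedding: t-SNE is always the first stage
        tsne = fp.dr_stages[0]
        train_rep, new_rep = tsne.joint_embed(X)
        for stage in fp.dr_stages[1:]:
            train_rep = stage.transform(train_rep)
            new_rep = stage.transform(new_rep)
        if fp.spec.terminal_kind == "kmeans":
            # centroids recomputed in the fresh embedding from the stored partition
            present = np.unique(fp.train_labels)
            cents = np.vstack(
                [train_rep[fp.train_labels == c].mean(axis=0) for c in present]
            )
            labels = present[_nearest_centroid(new_rep, cents)]
        else:
            labels = _knn_vote(new_rep, train_rep, fp.train_labels, fp.knn_k)
        return (labels, new_rep) if return_representation else labels

    rep = reduced_representation(fp, X)
    if fp.spec.terminal_kind == "kmeans":
        labels = _nearest_centroid(rep, fp.centroids)
    else:
        labels = _knn_vote(rep, fp.reduced_train, fp.train_labels, fp.knn_k)
    return (labels, rep) if return_representation else labels
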