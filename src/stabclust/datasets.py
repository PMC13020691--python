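"""Benchmark data simulation: effect-size-controlled Gaussian mixtures.

Synthetic datasets are mixtures of K = 3 multivariate normals whose
parameters are derived from Fisher's Iris measurements (150 flowers,
3 species, 4 features), the classical reference for a known 3-cluster
structure.  Cluster separation is controlled by shrinking the class
means toward the grand mean: with per-class sample means ``mu_k`` and
grand mean ``mu_bar``, the component means are

    mu_k(s) = mu_bar + s * (mu_k - mu_bar)

and the scale ``s`` is chosen so that the mean absolute pairwise
class-mean difference, relative to the per-feature grand mean and
averaged over the four features, hits a target relative separation of
10% (small), 20% (medium) or 50% (large).  Per-class covariances are
the Iris sample covariances, unscaled.  Any number of pure-noise
covariates (i.i.d. standard normal, independent of class) can be
appended to emulate high-dimensional feature tables where only a few
columns carry cluster signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceData",
    "MixtureParams",
    "SimulationConfig",
    "SimulatedDataset",
    "load_iris_reference",
    "derive_mixture_params",
    "relative_separation",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
    "EFFECT_TARGETS",
    "NOISE_GRID",
]

#: Target mean relative separations for the three effect levels.
EFFECT_TARGETS = {"small": 0.10, "medium": 0.20, "large": 0.50}

#: Noise-covariate counts used in the benchmark factorial.
NOISE_GRID = (0, 4, 20, 40, 60, 80, 140, 200)


@dataclass(frozen=True)
class ReferenceData:
    """A labelled reference table used to derive mixture parameters."""

    features: np.ndarray  # (n, p) continuous features
    class_labels: np.ndarray  # integer labels, one per row

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.class_labels)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("features and class_labels must have matching rows")
        if np.isnan(X).any():
            raise ValueError("reference data must not contain missing values")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "class_labels", y)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.class_labels)


@dataclass(frozen=True)
class MixtureParams:
    """Ground-truth parameters of a K-component Gaussian mixture."""

    component_means: np.ndarray  # (K, p)
    component_covariances: np.ndarray  # (K, p, p)
    mixing_proportions: np.ndarray  # (K,)
    effect_scale: float  # the mean-shrinkage factor s

    def __post_init__(self) -> None:
        means = np.asarray(self.component_means, dtype=float)
        covs = np.asarray(self.component_covariances, dtype=float)
        props = np.asarray(self.mixing_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("mixing proportions must sum to 1")
        if (props < 0).any():
            raise ValueError("mixing proportions must be nonnegative")
        for k, cov in enumerate(covs):
            if not np.allclose(cov, cov.T):
                raise ValueError(f"covariance of component {k} is not symmetric")
            w = np.linalg.eigvalsh(cov)
            if w.min() < -1e-8 * max(1.0, w.max()):
                raise ValueError(f"covariance of component {k} is not PSD")
        object.__setattr__(self, "component_means", means)
        object.__setattr__(self, "component_covariances", covs)
        object.__setattr__(self, "mixing_proportions", props)

    @property
    def n_components(self) -> int:
        return self.component_means.shape[0]

    @property
    def n_features(self) -> int:
        return self.component_means.shape[1]

    def to_dict(self) -> dict:
        return {
            "component_means": self.component_means.tolist(),
            "component_covariances": self.component_covariances.tolist(),
            "mixing_proportions": self.mixing_proportions.tolist(),
            "effect_scale": float(self.effect_scale),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureParams":
        return cls(
            component_means=np.asarray(d["component_means"]),
            component_covariances=np.asarray(d["component_covariances"]),
            mixing_proportions=np.asarray(d["mixing_proportions"]),
            effect_scale=float(d["effect_scale"]),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Size, noise dimensionality and seed of one simulated dataset."""

    effect_level: str
    n_obs: int = 1000
    n_noise: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_level not in EFFECT_TARGETS:
            raise ValueError(
                f"effect_level must be one of {sorted(EFFECT_TARGETS)}, "
                f"got {self.effect_level!r}"
            )
        if self.n_obs < 3:
            raise ValueError("n_obs must be at least the number of components")
        if self.n_noise < 0:
            raise ValueError("n_noise must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "effect_level": self.effect_level,
            "n_obs": int(self.n_obs),
            "n_noise": int(self.n_noise),
            "seed": int(self.seed),
        }


@dataclass(frozen=True)
class SimulatedDataset:
    """A simulated feature table with its ground-truth labels."""

    features: np.ndarray  # (n_obs, p + n_noise)
    ground_truth: np.ndarray  # integer labels in 1..K
    config: SimulationConfig
    params: MixtureParams | None = field(default=None, compare=False)

    @property
    def n_informative(self) -> int:
        return self.features.shape[1] - self.config.n_noise

    def to_frame(self) -> pd.DataFrame:
        p = self.n_informative
        cols = [f"f{i + 1}" for i in range(p)] + [
            f"noise{i + 1}" for i in range(self.config.n_noise)
        ]
        df = pd.DataFrame(self.features, columns=cols)
        df.insert(0, "obs_id", np.arange(1, len(df) + 1))
        df["ground_truth"] = self.ground_truth
        return df


def load_iris_reference() -> ReferenceData:
    """Load the bundled Fisher Iris table (150 x 4, 3 balanced species)."""
    with resources.files("stabclust.data").joinpath("iris.csv").open() as fh:
        df = pd.read_csv(fh)
    return ReferenceData(
        features=df.iloc[:, :4].to_numpy(float),
        class_labels=df["species"].to_numpy(int),
    )


def relative_separation(means: np.ndarray, grand_mean: np.ndarray) -> float:
    """Mean over features and class pairs of |mu_j - mu_k| / grand mean.

    This is the concrete separation statistic the effect levels target:
    the average relative difference between component means.
    """
    means = np.asarray(means, float)
    grand_mean = np.asarray(grand_mean, float)
    K = means.shape[0]
    vals = [
        np.abs(means[j] - means[k]) / grand_mean
        for j in range(K)
        for k in range(j + 1, K)
    ]
    return float(np.mean(vals))


def derive_mixture_params(
    ref: ReferenceData, effect_level: str
) -> MixtureParams:
    """Derive mixture parameters at a named separation level.

    Class means are shrunk toward the grand mean by the factor ``s``
    solving ``relative_separation(mu(s)) == target``; since the
    statistic is linear in ``s`` the solution is exact. Covariances are
    the per-class sample covariances, unscaled; proportions are equal.
    """
    if effect_level not in EFFECT_TARGETS:
        raise ValueError(
            f"effect_level must be one of {sorted(EFFECT_TARGETS)}, "
            f"got {effect_level!r}"
        )
    target = EFFECT_TARGETS[effect_level]
    X, y = ref.features, ref.class_labels
    classes = ref.classes
    grand_mean = X.mean(axis=0)
    if np.any(grand_mean == 0):
        raise ValueError("grand mean has a zero coordinate; relative separation undefined")

    means, covs = [], []
    for c in classes:
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c} has fewer than 2 observations")
        means.append(Xc.mean(axis=0))
        cov = np.cov(Xc, rowvar=False)
        if np.linalg.matrix_rank(cov) == 0:
            raise ValueError(f"class {c} has a singular (zero) covariance")
        covs.append(cov)
    means = np.asarray(means)

    base = relative_separation(means, grand_mean)
    if base <= 1e-9:
        raise ValueError("reference classes have zero mean separation; target unreachable")
    s = target / base
    shrunk = grand_mean + s * (means - grand_mean)

    achieved = relative_separation(shrunk, grand_mean)
    assert abs(achieved - target) <= 0.01 * target

    K = len(classes)
    return MixtureParams(
        component_means=shrunk,
        component_covariances=np.asarray(covs),
        mixing_proportions=np.full(K, 1.0 / K),
        effect_scale=s,
    )


def simulate_dataset(
    params: MixtureParams, config: SimulationConfig
) -> SimulatedDataset:
    """Draw one dataset from the mixture, appending noise covariates.

    Components are drawn from the mixing proportions; informative
    columns from each component's multivariate normal; noise columns
    i.i.d. N(0, 1) independent of component. Deterministic for a fixed
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, K, p = config.n_obs, params.n_components, params.n_features
    comp = rng.choice(K, size=n, p=params.mixing_proportions)
    X = np.empty((n, p))
    for k in range(K):
        mask = comp == k
        X[mask] = rng.multivariate_normal(
            params.component_means[k],
            params.component_covariances[k],
            size=int(mask.sum()),
            method="svd",
        )
    if config.n_noise:
        noise = rng.standard_normal((n, config.n_noise))
        X = np.hstack([X, noise])
    return SimulatedDataset(
        features=X, ground_truth=comp + 1, config=config, params=params
    )


def write_dataset(ds: SimulatedDataset, path: str | Path) -> None:
    """Write a dataset as CSV with a JSON provenance sidecar."""
    path = Path(path)
    ds.to_frame().to_csv(path, index=False, float_format="%.17g")
    sidecar = {"config": ds.config.to_dict()}
    if ds.params is not None:
        sidecar["params"] = ds.params.to_dict()
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_dataset(path: str | Path) -> SimulatedDataset:
    """Read a dataset written by :func:`write_dataset` (round-trip exact)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:  # pandas reports the line number
        raise ValueError(f"{path}: malformed delimited text: {exc}") from exc
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if "ground_truth" not in df.columns:
        raise ValueError(f"{path}: missing required 'ground_truth' column")

    sidecar_path = path.with_suffix(path.suffix + ".json")
    params = None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        config = SimulationConfig(**sidecar["config"])
        if "params" in sidecar:
            params = MixtureParams.from_dict(sidecar["params"])
    else:
        n_noise = sum(c.startswith("noise") for c in df.columns)
        config = SimulationConfig(
            effect_level="large", n_obs=len(df), n_noise=n_noise, seed=0
        )
    feat_cols = [c for c in df.columns if c not in ("obs_id", "ground_truth")]
    return SimulatedDataset(
        features=df[feat_cols].to_numpy(float),
        ground_truth=df["ground_truth"].to_numpy(int),
        config=config,
        params=params,
    )
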