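"""Compression models over a grid of latent dimensionalities.

Five algorithms — PCA, ICA, NMF, a denoising autoencoder (DAE) and a
variational autoencoder (VAE) — are fitted on [0,1]-scaled training data
for every latent dimensionality k in a grid, with several random seeds,
on real and gene-permuted data. Each fitted model exposes a genes x k
weight matrix W (the object that downstream network projection
interprets), a transform contract (data -> samples x k activations) and a
reconstruct contract, plus reconstruction metrics (binary cross-entropy
and per-sample Pearson correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF, PCA, FastICA

from ._nn import DenoisingAutoencoder, VariationalAutoencoder
from .expression import ExpressionMatrix
from .preprocess import permute_within_genes

__all__ = [
    "PAPER_K_GRID",
    "ALGORITHMS",
    "CompressionConfig",
    "FittedModel",
    "ModelRegistry",
    "count_models",
    "count_features",
    "fit_model",
    "reconstruction_bce",
    "sample_pearson",
    "run_grid",
]

#: Reference grid of 28 latent dimensionalities from k=2 to k=200.
PAPER_K_GRID: tuple[int, ...] = (
    2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20, 25, 30, 35, 40,
    45, 50, 60, 70, 80, 90, 100, 125, 150, 200,
)

ALGORITHMS: tuple[str, ...] = ("pca", "ica", "nmf", "dae", "vae")

DEFAULT_AE_HYPERPARAMS: dict[str, float] = {
    "learning_rate": 5e-4,
    "batch_size": 50,
    "epochs": 50,
    "dae_noise_fraction": 0.1,
    "vae_kl_weight": 1.0,
}


# ---------------------------------------------------------------------------
# grid arithmetic
# ---------------------------------------------------------------------------

def count_models(
    n_datasets: int = 3,
    algorithms=ALGORITHMS,
    k_grid=PAPER_K_GRID,
    n_seeds: int = 5,
    n_data_tags: int = 2,
) -> int:
    """Number of compression models in a full grid run."""
    return n_datasets * len(algorithms) * len(k_grid) * n_seeds * n_data_tags


def count_features(
    k_grid=PAPER_K_GRID,
    algorithms=ALGORITHMS,
    n_seeds: int = 5,
    n_datasets: int = 1,
    n_data_tags: int = 1,
) -> int:
    """Number of latent features produced (sum of k across the grid)."""
    return sum(k_grid) * len(algorithms) * n_seeds * n_datasets * n_data_tags


# ---------------------------------------------------------------------------
# configuration and fitted model
# ---------------------------------------------------------------------------

@dataclass
class CompressionConfig:
    algorithm: str
    k: int
    seed: int = 0
    ae_hyperparams: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AE_HYPERPARAMS)
    )
    data_tag: str = "real"

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.data_tag not in ("real", "permuted"):
            raise ValueError(f"data_tag must be 'real' or 'permuted'")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        hp = dict(DEFAULT_AE_HYPERPARAMS)
        hp.update(self.ae_hyperparams)
        self.ae_hyperparams = hp

    @property
    def key(self) -> tuple:
        return (self.algorithm, self.k, self.seed, self.data_tag)


@dataclass
class FittedModel:
    """One trained compression model with its genes x k weight matrix."""

    config: CompressionConfig
    weights: pd.DataFrame          # genes x k, columns feature_0..feature_{k-1}
    _backend: Any
    _gene_ids: list[str]
    _train_min: pd.Series | None = None  # reserved for future use

    @property
    def k(self) -> int:
        return self.config.k

    def _check_genes(self, expr: ExpressionMatrix) -> None:
        if list(expr.gene_ids) != self._gene_ids:
            raise ValueError(
                "gene universe mismatch between model and data; use "
                "evaluate.project_external for transfer to other universes"
            )

    def transform(self, expr: ExpressionMatrix) -> pd.DataFrame:
        """Sample activation scores (samples x k)."""
        self._check_genes(expr)
        x = expr.values
        algo = self.config.algorithm
        if algo in ("pca", "ica", "nmf"):
            z = self._backend.transform(x)
        else:
            z = self._backend.encode(x)
        return pd.DataFrame(z, index=expr.data.index, columns=self.weights.columns)

    def reconstruct(self, expr: ExpressionMatrix) -> pd.DataFrame:
        self._check_genes(expr)
        x = expr.values
        algo = self.config.algorithm
        if algo == "pca":
            xhat = self._backend.inverse_transform(self._backend.transform(x))
        elif algo == "ica":
            xhat = self._backend.inverse_transform(self._backend.transform(x))
        elif algo == "nmf":
            xhat = self._backend.transform(x) @ self._backend.components_
        else:
            xhat = self._backend.reconstruct(x)
        return pd.DataFrame(xhat, index=expr.data.index, columns=expr.data.columns)


def fit_model(config: CompressionConfig, train: ExpressionMatrix) -> FittedModel:
    """Train one compression model on [0,1]-scaled training data.

    Deterministic given ``config.seed`` for all five algorithms (the
    autoencoders seed their initialization, minibatch order, corruption
    masks and reparameterization draws from it).
    """
    x = train.values
    n_samples, n_genes = x.shape
    k = config.k
    algo = config.algorithm
    if algo in ("pca", "ica") and k > min(n_samples, n_genes):
        raise ValueError(f"k={k} exceeds min(samples, genes)={min(n_samples, n_genes)}")
    if algo == "nmf" and (x < 0).any():
        raise ValueError("NMF requires non-negative input")

    hp = config.ae_hyperparams
    if algo == "pca":
        backend = PCA(n_components=k, svd_solver="full", random_state=config.seed)
        backend.fit(x)
        w = backend.components_.T
    elif algo == "ica":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings at tiny n
            backend = FastICA(
                n_components=k, random_state=config.seed,
                whiten="unit-variance", max_iter=1000, tol=1e-4,
            )
            backend.fit(x)
        w = backend.components_.T
        # ICA scale is unidentifiable; unit-norm columns stabilize z-scores
        w = w / np.linalg.norm(w, axis=0, keepdims=True)
    elif algo == "nmf":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            backend = NMF(
                n_components=k, init="random", random_state=config.seed,
                max_iter=500, tol=1e-4,
            )
            backend.fit(x)
        w = backend.components_.T
    elif algo == "dae":
        backend = DenoisingAutoencoder(
            n_genes, k, config.seed,
            learning_rate=hp["learning_rate"], batch_size=int(hp["batch_size"]),
            epochs=int(hp["epochs"]), noise_fraction=hp["dae_noise_fraction"],
        ).fit(x)
        w = backend.decoder_weights
    else:  # vae
        backend = VariationalAutoencoder(
            n_genes, k, config.seed,
            learning_rate=hp["learning_rate"], batch_size=int(hp["batch_size"]),
            epochs=int(hp["epochs"]), kl_weight=hp["vae_kl_weight"],
        ).fit(x)
        w = backend.decoder_weights

    weights = pd.DataFrame(
        w, index=train.gene_ids, columns=[f"feature_{i}" for i in range(k)]
    )
    return FittedModel(config, weights, backend, list(train.gene_ids))


# ---------------------------------------------------------------------------
# reconstruction metrics
# ---------------------------------------------------------------------------

def reconstruction_bce(X, X_hat, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy between input and reconstruction.

    Per-sample mean over genes of -[x ln xhat + (1-x) ln(1-xhat)], averaged
    over samples; reconstructions are clipped to [eps, 1-eps] because the
    linear models can exit [0, 1].
    """
    x = np.asarray(X, dtype=float)
    xhat = np.asarray(X_hat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    xhat = np.clip(xhat, eps, 1.0 - eps)
    per_gene = -(x * np.log(xhat) + (1.0 - x) * np.log(1.0 - xhat))
    return float(per_gene.mean(axis=1).mean())


def sample_pearson(X, X_hat) -> np.ndarray:
    """Per-sample Pearson correlation between input and reconstruction.

    Samples whose input or reconstruction row has zero variance get NaN
    (excluded from means downstream).
    """
    x = np.asarray(X, dtype=float)
    xhat = np.asarray(X_hat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    xc = x - x.mean(axis=1, keepdims=True)
    yc = xhat - xhat.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=1) / (sx * sy)
    # constant rows have zero variance; test constancy exactly rather than
    # the centered norm, which carries mean round-off
    const_x = (x == x[:, :1]).all(axis=1)
    const_y = (xhat == xhat[:, :1]).all(axis=1)
    r[const_x | const_y | (sx == 0) | (sy == 0)] = np.nan
    return r


# ---------------------------------------------------------------------------
# grid runner
# ---------------------------------------------------------------------------

@dataclass
class ModelRegistry:
    """Store of fitted models keyed by (algorithm, k, seed, data_tag)."""

    models: dict[tuple, FittedModel] = field(default_factory=dict)
    activations: dict[tuple, dict[str, pd.DataFrame]] = field(default_factory=dict)
    _metric_records: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)

    def add(self, model: FittedModel) -> None:
        self.models[model.config.key] = model

    def get(self, algorithm: str, k: int, seed: int, data_tag: str = "real") -> FittedModel:
        return self.models[(algorithm, k, seed, data_tag)]

    def __len__(self) -> int:
        return len(self.models)

    @property
    def metrics(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._metric_records,
            columns=["algorithm", "k", "seed", "data_tag", "split", "metric", "value"],
        )

    def record_metric(self, config: CompressionConfig, split: str,
                      metric: str, value: float) -> None:
        self._metric_records.append({
            "algorithm": config.algorithm, "k": config.k, "seed": config.seed,
            "data_tag": config.data_tag, "split": split,
            "metric": metric, "value": value,
        })


def run_grid(
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    algorithms=ALGORITHMS,
    k_grid=(2, 3, 4, 8),
    seeds=(0, 1),
    include_permuted: bool = False,
    permuted_seed: int = 0,
    ae_hyperparams: dict | None = None,
) -> ModelRegistry:
    """Fit every (algorithm, k, seed[, data_tag]) cell and record metrics.

    The permuted baseline trains every model on one gene-permuted copy of
    the training partition and evaluates on the untouched test partition.
    Individual fit failures are logged and the grid continues.
    """
    registry = ModelRegistry()
    datasets = {"real": train}
    if include_permuted:
        datasets["permuted"] = permute_within_genes(train, seed=permuted_seed)

    for data_tag, fit_data in datasets.items():
        for algorithm in algorithms:
            for k in k_grid:
                for seed in seeds:
                    config = CompressionConfig(
                        algorithm=algorithm, k=k, seed=seed, data_tag=data_tag,
                        ae_hyperparams=dict(ae_hyperparams or {}),
                    )
                    try:
                        model = fit_model(config, fit_data)
                    except Exception as exc:  # grid continues on failure
                        registry.failures.append(
                            {"key": config.key, "error": str(exc)}
                        )
                        continue
                    registry.add(model)
                    acts = {}
                    for split, data in (("train", fit_data), ("test", test)):
                        acts[split] = model.transform(data)
                        xhat = model.reconstruct(data)
                        registry.record_metric(
                            config, split, "bce",
                            reconstruction_bce(data.values, xhat.to_numpy()),
                        )
                        r = sample_pearson(data.values, xhat.to_numpy())
                        registry.record_metric(
                            config, split, "mean_pearson", float(np.nanmean(r))
                        )
                    registry.activations[config.key] = acts
    return registry
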