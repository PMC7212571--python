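"""SVCCA similarity between compression weight matrices.

Singular vector canonical correlation analysis compares two genes x k
weight matrices in two steps: (1) reduce each matrix by SVD, keeping the
smallest leading set of directions whose squared singular values account
for a variance threshold (98% by default) of the total; (2) run a
canonical correlation analysis between the two reduced representations
(genes are the observations) and report the mean canonical correlation.
The statistic is 1.0 for a matrix against itself or any invertible linear
transform of itself, and near 0 for unrelated random matrices, which
makes it a scale- and rotation-insensitive measure of whether two models
learned the same latent subspace.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .compress import ModelRegistry

__all__ = ["SVCCAResult", "svcca", "stability_summary"]


@dataclass
class SVCCAResult:
    mean_cc: float
    canonical_correlations: np.ndarray
    retained_dims: tuple[int, int]
    variance_threshold: float


def _reduce(W: np.ndarray, threshold: float, squared: bool) -> np.ndarray:
    """Center columns, SVD, keep directions covering ``threshold`` of signal."""
    x = W - W.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    energy = s ** 2 if squared else s
    total = energy.sum()
    if total == 0:
        raise ValueError("weight matrix has rank 0 after centering")
    keep = int(np.searchsorted(np.cumsum(energy) / total, threshold) + 1)
    keep = max(keep, 1)
    return u[:, :keep] * s[:keep]


def _cca_correlations(X: np.ndarray, Y: np.ndarray, reg: float = 1e-10) -> np.ndarray:
    """Canonical correlations via the SVD-based closed form."""
    X = X - X.mean(axis=0, keepdims=True)
    Y = Y - Y.mean(axis=0, keepdims=True)
    n = X.shape[0]
    sxx = X.T @ X / n + reg * np.eye(X.shape[1])
    syy = Y.T @ Y / n + reg * np.eye(Y.shape[1])
    sxy = X.T @ Y / n

    def inv_sqrt(a: np.ndarray) -> np.ndarray:
        vals, vecs = np.linalg.eigh(a)
        vals = np.clip(vals, reg, None)
        return vecs @ np.diag(vals ** -0.5) @ vecs.T

    m = inv_sqrt(sxx) @ sxy @ inv_sqrt(syy)
    corr = np.linalg.svd(m, compute_uv=False)
    return np.clip(corr, 0.0, 1.0)


def svcca(
    W1: pd.DataFrame | np.ndarray,
    W2: pd.DataFrame | np.ndarray,
    variance_threshold: float = 0.98,
    squared: bool = True,
) -> SVCCAResult:
    """Mean canonical correlation between two weight matrices.

    ``squared=True`` interprets the retention threshold on cumulative
    squared singular values (variance); ``False`` uses the singular values
    themselves.
    """
    a = np.asarray(W1, dtype=float)
    b = np.asarray(W2, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("weight matrices must share gene rows")
    ra = _reduce(a, variance_threshold, squared)
    rb = _reduce(b, variance_threshold, squared)
    corr = _cca_correlations(ra, rb)
    n_cc = min(ra.shape[1], rb.shape[1])
    corr = corr[:n_cc]
    return SVCCAResult(
        mean_cc=float(corr.mean()),
        canonical_correlations=corr,
        retained_dims=(ra.shape[1], rb.shape[1]),
        variance_threshold=variance_threshold,
    )


def stability_summary(
    registry: ModelRegistry,
    scope: str = "within_algorithm",
    data_tag: str = "real",
    variance_threshold: float = 0.98,
) -> pd.DataFrame:
    """Pairwise SVCCA similarities aggregated over a model registry.

    Scopes: ``within_algorithm`` (all seed pairs at fixed algorithm and k),
    ``across_algorithms`` (all cross-algorithm pairs at fixed k, all seed
    combinations), ``across_dimensions`` (all seed pairs between two
    dimensionalities within an algorithm). Returns a long-format frame of
    pairwise mean canonical correlations; missing cells are skipped.
    """
    keys = [k for k in registry.models if k[3] == data_tag]
    algorithms = sorted({k[0] for k in keys})
    k_values = sorted({k[1] for k in keys})
    seeds = sorted({k[2] for k in keys})
    records = []

    def compare(key1, key2):
        m1, m2 = registry.models.get(key1), registry.models.get(key2)
        if m1 is None or m2 is None:
            return None
        res = svcca(m1.weights, m2.weights, variance_threshold)
        return res

    if scope == "within_algorithm":
        pairs = [
            (algo, kdim, s1, s2)
            for algo in algorithms for kdim in k_values
            for s1, s2 in combinations(seeds, 2)
        ]
        for algo, kdim, s1, s2 in pairs:
            res = compare((algo, kdim, s1, data_tag), (algo, kdim, s2, data_tag))
            if res is not None:
                records.append({
                    "algorithm_1": algo, "k_1": kdim, "seed_1": s1,
                    "algorithm_2": algo, "k_2": kdim, "seed_2": s2,
                    "mean_cc": res.mean_cc,
                    "retained_1": res.retained_dims[0],
                    "retained_2": res.retained_dims[1],
                })
    elif scope == "across_algorithms":
        for a1, a2 in combinations(algorithms, 2):
            for kdim in k_values:
                for s1 in seeds:
                    for s2 in seeds:
                        res = compare((a1, kdim, s1, data_tag), (a2, kdim, s2, data_tag))
                        if res is not None:
                            records.append({
                                "algorithm_1": a1, "k_1": kdim, "seed_1": s1,
                                "algorithm_2": a2, "k_2": kdim, "seed_2": s2,
                                "mean_cc": res.mean_cc,
                                "retained_1": res.retained_dims[0],
                                "retained_2": res.retained_dims[1],
                            })
    elif scope == "across_dimensions":
        for algo in algorithms:
            for k1, k2 in combinations(k_values, 2):
                for s1 in seeds:
                    for s2 in seeds:
                        res = compare((algo, k1, s1, data_tag), (algo, k2, s2, data_tag))
                        if res is not None:
                            records.append({
                                "algorithm_1": algo, "k_1": k1, "seed_1": s1,
                                "algorithm_2": algo, "k_2": k2, "seed_2": s2,
                                "mean_cc": res.mean_cc,
                                "retained_1": res.retained_dims[0],
                                "retained_2": res.retained_dims[1],
                            })
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return pd.DataFrame(
        records,
        columns=["algorithm_1", "k_1", "seed_1", "algorithm_2", "k_2", "seed_2",
                 "mean_cc", "retained_1", "retained_2"],
    )
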