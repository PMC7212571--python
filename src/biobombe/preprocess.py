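"""Partitioning, scaling, permutation and gene filtering of expression data.

The training procedure is: split samples into train/test partitions
stratified by tissue (or cancer type), then min-max scale each gene to
[0, 1] *within each partition independently*, and optionally build a
gene-permuted baseline by shuffling each gene's values across samples.
Gene filtering keeps the most variable genes by median absolute deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "PartitionPair",
    "stratified_split",
    "minmax_scale",
    "permute_within_genes",
    "select_top_mad_genes",
]


@dataclass
class PartitionPair:
    """Disjoint train/test partitions of one expression matrix."""

    train: ExpressionMatrix
    test: ExpressionMatrix
    stratify_key: str
    seed: int


def stratified_split(
    expr: ExpressionMatrix,
    train_fraction: float = 0.9,
    stratify_key: str = "tissue",
    seed: int = 0,
) -> PartitionPair:
    """Split samples into train/test, balanced per stratum.

    Within each stratum the train size is ``round(fraction * stratum size)``
    with the remainder going to test; a singleton stratum goes to train with
    a warning. Deterministic given ``seed``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if stratify_key not in expr.metadata.columns:
        raise ValueError(f"metadata lacks stratify column {stratify_key!r}")
    strata = expr.metadata[stratify_key]
    if strata.isna().any():
        raise ValueError("every sample needs a stratify value")

    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for stratum in sorted(strata.unique(), key=str):
        members = list(strata.index[strata == stratum])
        if len(members) == 1:
            warnings.warn(
                f"stratum {stratum!r} has a single sample; assigned to train",
                stacklevel=2,
            )
            train_ids.extend(members)
            continue
        order = rng.permutation(len(members))
        n_train = int(round(train_fraction * len(members)))
        shuffled = [members[i] for i in order]
        train_ids.extend(shuffled[:n_train])
        test_ids.extend(shuffled[n_train:])

    # keep original sample order inside each partition
    order_index = {s: i for i, s in enumerate(expr.sample_ids)}
    train_ids.sort(key=order_index.__getitem__)
    test_ids.sort(key=order_index.__getitem__)
    return PartitionPair(
        train=expr.subset_samples(train_ids),
        test=expr.subset_samples(test_ids),
        stratify_key=stratify_key,
        seed=seed,
    )


def minmax_scale(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every gene column to [0, 1] with its own min and range.

    Constant genes map to all zeros (kept, not dropped, so the gene universe
    stays aligned across partitions). Apply per partition, after splitting.
    """
    x = expr.data
    col_min = x.min(axis=0)
    col_range = x.max(axis=0) - col_min
    safe = col_range.replace(0.0, 1.0)
    scaled = (x - col_min) / safe
    scaled.loc[:, col_range == 0.0] = 0.0
    return ExpressionMatrix(scaled, expr.metadata.copy())


def permute_within_genes(expr: ExpressionMatrix, seed: int = 0) -> ExpressionMatrix:
    """Shuffle each gene's values across samples, independently per gene.

    Destroys gene-gene correlation while preserving every gene's marginal
    distribution; this is the permuted-data baseline for model training.
    """
    rng = np.random.default_rng(seed)
    values = expr.values.copy()
    n = values.shape[0]
    for j in range(values.shape[1]):
        values[:, j] = values[rng.permutation(n), j]
    permuted = pd.DataFrame(values, index=expr.data.index, columns=expr.data.columns)
    return ExpressionMatrix(permuted, expr.metadata.copy())


def select_top_mad_genes(expr: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Keep the ``n`` genes with the largest median absolute deviation.

    MAD here is the raw ``median(|x - median(x)|)`` without the 1.4826
    normal-consistency constant (ranking is invariant to it). Ties break
    deterministically by gene ID.
    """
    if n > expr.n_genes:
        raise ValueError(f"requested {n} genes but matrix has {expr.n_genes}")
    med = expr.data.median(axis=0)
    mad = (expr.data - med).abs().median(axis=0)
    ranked = sorted(expr.gene_ids, key=lambda g: (-mad[g], g))
    keep = ranked[:n]
    # preserve original column order among the kept genes
    keep_set = set(keep)
    ordered = [g for g in expr.gene_ids if g in keep_set]
    return expr.subset_genes(ordered)
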