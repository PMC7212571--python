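"""Downstream evaluation of compressed features.

Covers: transfer of learned representations to external expression data
over the overlapping gene universe, trait enrichment via Welch t-tests,
construction of gene-alteration labels with hypermutator and class-balance
filters, ensembles of compressed features, and elastic-net logistic
regression of sample categories with cross-validated AUROC/AUPR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .compress import ModelRegistry
from .expression import ExpressionMatrix

__all__ = [
    "TransferResult",
    "TraitTestResult",
    "AlterationLabels",
    "ElasticNetResult",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_MIXING_GRID",
    "project_external",
    "welch_ttest",
    "sex_balanced_strata",
    "build_alteration_labels",
    "build_ensemble_features",
    "train_elasticnet",
    "aupr_delta",
    "nonzero_fraction",
]

#: Regularization strengths and l1/l2 mixing values searched by default
#: (36 combinations, selected by cross-validated AUROC).
DEFAULT_ALPHA_GRID: tuple[float, ...] = (0.1, 0.13, 0.15, 0.2, 0.25, 0.3)
DEFAULT_MIXING_GRID: tuple[float, ...] = (0.15, 0.16, 0.2, 0.25, 0.3, 0.4)


# ---------------------------------------------------------------------------
# transfer to external data
# ---------------------------------------------------------------------------

@dataclass
class TransferResult:
    """Activations of learned features on an external dataset.

    ``activations`` is features x external samples (D' = W^T_{g'} D_{g'}),
    computed strictly over the overlapping gene universe g'.
    """

    activations: pd.DataFrame
    overlapping_genes: list[str]
    overlap_fraction: float


def project_external(
    weights: pd.DataFrame | pd.Series,
    external: ExpressionMatrix,
    min_overlap: float = 0.5,
    scale_external: bool = False,
) -> TransferResult:
    """Project a weight matrix (or single feature column) onto external data.

    The product runs over g' = (model genes) ∩ (external genes); no
    re-scaling of the external data is applied unless ``scale_external``
    (the raw product mirrors the transfer procedure; scaling is an opt-in
    for cross-platform comparability). ``overlap_fraction`` is
    |g'| / |model genes|.
    """
    w = weights.to_frame() if isinstance(weights, pd.Series) else weights
    model_genes = list(w.index.astype(str))
    external_genes = set(external.gene_ids)
    g_prime = [g for g in model_genes if g in external_genes]
    if not g_prime:
        raise ValueError("no overlapping genes between model and external data")
    overlap = len(g_prime) / len(model_genes)
    if overlap < min_overlap:
        warnings.warn(
            f"gene overlap {overlap:.1%} below floor {min_overlap:.0%}",
            stacklevel=2,
        )
    d = external.data[g_prime]
    if scale_external:
        rng_ = d.max() - d.min()
        d = (d - d.min()) / rng_.replace(0.0, 1.0)
    d_prime = w.loc[g_prime].to_numpy().T @ d.to_numpy().T
    return TransferResult(
        activations=pd.DataFrame(d_prime, index=list(w.columns), columns=external.sample_ids),
        overlapping_genes=g_prime,
        overlap_fraction=overlap,
    )


# ---------------------------------------------------------------------------
# trait tests
# ---------------------------------------------------------------------------

@dataclass
class TraitTestResult:
    t_statistic: float
    p_value: float
    n_group1: int
    n_group0: int
    feature: str = ""


def welch_ttest(scores: pd.Series, labels: pd.Series, feature: str = "") -> TraitTestResult:
    """Two-tailed independent t-test with unequal variances (Welch).

    Orientation: group coded 1 minus group coded 0. Groups with fewer than
    two members or zero variance yield NaN statistics (undefined marker).
    """
    labels = labels.loc[scores.index]
    g1 = scores[labels == 1].to_numpy(dtype=float)
    g0 = scores[labels == 0].to_numpy(dtype=float)
    if len(g1) < 2 or len(g0) < 2 or (np.var(g1) == 0 and np.var(g0) == 0):
        return TraitTestResult(np.nan, np.nan, len(g1), len(g0), feature)
    t, p = stats.ttest_ind(g1, g0, equal_var=False)
    return TraitTestResult(float(t), float(p), len(g1), len(g0), feature)


def sex_balanced_strata(
    metadata: pd.DataFrame,
    tissue_key: str = "tissue",
    sex_key: str = "sex",
    male_value="male",
    female_value="female",
    lo: float = 0.5,
    hi: float = 1.5,
) -> list[str]:
    """Tissues whose male/female count ratio lies in [lo, hi] (inclusive).

    Tissues with zero female samples have an undefined ratio and are
    dropped.
    """
    kept = []
    for tissue, group in metadata.groupby(tissue_key):
        n_m = int((group[sex_key] == male_value).sum())
        n_f = int((group[sex_key] == female_value).sum())
        if n_f == 0:
            continue
        ratio = n_m / n_f
        if lo <= ratio <= hi:
            kept.append(tissue)
    return sorted(kept, key=str)


# ---------------------------------------------------------------------------
# alteration labels
# ---------------------------------------------------------------------------

@dataclass
class AlterationLabels:
    labels: pd.Series                 # binary status over retained samples
    included_types: list[str]
    exclusion_log: list[str] = field(default_factory=list)


def build_alteration_labels(
    mutations: pd.DataFrame,
    copy_number: pd.DataFrame,
    gene: str,
    gene_class: str,
    burden: pd.Series,
    cancer_types: pd.Series,
    min_fraction: float = 0.05,
    max_fraction: float = 0.95,
    min_class_size: int = 15,
    hypermutator_sds: float = 5.0,
) -> AlterationLabels:
    """Binary alteration status for one gene with the standard filters.

    Positive = non-silent mutation, or a large copy amplification
    (GISTIC score +2) for oncogenes / deep deletion (-2) for tumor
    suppressors. Hypermutators (log10 mutation count more than
    ``hypermutator_sds`` standard deviations above the cohort mean) are
    removed before balance checks; a cancer type is retained only if its
    positive fraction lies in [min_fraction, max_fraction] and both
    classes have at least ``min_class_size`` samples.
    """
    if gene not in mutations.columns or gene not in copy_number.columns:
        raise ValueError(f"gene {gene!r} absent from mutation or copy-number table")
    if gene_class not in ("oncogene", "tsg"):
        raise ValueError("gene_class must be 'oncogene' or 'tsg'")
    samples = mutations.index.intersection(copy_number.index)
    samples = samples.intersection(burden.index).intersection(cancer_types.index)
    log: list[str] = []

    log_burden = np.log10(burden.loc[samples].astype(float).clip(lower=1))
    cut = log_burden.mean() + hypermutator_sds * log_burden.std(ddof=0)
    hyper = log_burden.index[log_burden > cut]
    if len(hyper):
        log.append(f"removed {len(hyper)} hypermutator sample(s)")
    samples = samples.difference(hyper)

    copy_target = 2 if gene_class == "oncogene" else -2
    status = (
        (mutations.loc[samples, gene].astype(int) > 0)
        | (copy_number.loc[samples, gene].astype(int) == copy_target)
    ).astype(int)

    included: list[str] = []
    keep_samples: list = []
    for ctype, members in status.groupby(cancer_types.loc[samples]):
        n_pos = int(members.sum())
        n_neg = int(len(members) - n_pos)
        frac = n_pos / len(members)
        if not (min_fraction <= frac <= max_fraction):
            log.append(f"excluded {ctype}: positive fraction {frac:.1%}")
            continue
        if n_pos < min_class_size or n_neg < min_class_size:
            log.append(f"excluded {ctype}: class sizes {n_pos}/{n_neg} below {min_class_size}")
            continue
        included.append(str(ctype))
        keep_samples.extend(members.index)
    return AlterationLabels(
        labels=status.loc[keep_samples], included_types=sorted(included),
        exclusion_log=log,
    )


# ---------------------------------------------------------------------------
# feature ensembles
# ---------------------------------------------------------------------------

def build_ensemble_features(
    registry: ModelRegistry,
    mode: str,
    k: int | None = None,
    seed: int | None = None,
    split: str = "test",
    data_tag: str = "real",
    algorithms=("pca", "ica", "nmf", "dae", "vae"),
    seeds=None,
) -> pd.DataFrame:
    """Column-concatenate sample activations into an ensemble feature matrix.

    Modes: ``single`` (one model), ``vae_5seed`` (all seeds of the VAE at
    one k), ``one_seed_all_algorithms`` (one seed, every algorithm, one k),
    ``all_features`` (everything in the registry for the data tag).
    Column names encode (algorithm, k, seed, feature index).
    """
    if seeds is None:
        seeds = sorted({key[2] for key in registry.models})

    def want(key) -> bool:
        algo, kdim, s, tag = key
        if tag != data_tag:
            return False
        if mode == "single":
            return algo == algorithms[0] and kdim == k and s == seed
        if mode == "vae_5seed":
            return algo == "vae" and kdim == k
        if mode == "one_seed_all_algorithms":
            return kdim == k and s == seed and algo in algorithms
        if mode == "all_features":
            return True
        raise ValueError(f"unknown ensemble mode {mode!r}")

    selected = sorted(key for key in registry.models if want(key))
    missing: list[str] = []
    if mode == "vae_5seed":
        missing = [f"vae/k={k}/seed={s}" for s in seeds
                   if ("vae", k, s, data_tag) not in registry.models]
    elif mode == "one_seed_all_algorithms":
        missing = [f"{a}/k={k}/seed={seed}" for a in algorithms
                   if (a, k, seed, data_tag) not in registry.models]
    if missing:
        raise ValueError(f"registry is missing models: {missing}")
    if not selected:
        raise ValueError("no models matched the requested ensemble")

    blocks = []
    for key in selected:
        algo, kdim, s, _ = key
        acts = registry.activations[key][split]
        acts = acts.rename(
            columns={c: f"{algo}_k{kdim}_s{s}_{c}" for c in acts.columns}
        )
        blocks.append(acts)
    return pd.concat(blocks, axis=1)


# ---------------------------------------------------------------------------
# elastic-net classification
# ---------------------------------------------------------------------------

@dataclass
class ElasticNetResult:
    model: LogisticRegression
    best_alpha: float
    best_mixing: float
    cv_auroc: float
    cv_aupr: float
    sparsity: float                   # fraction of zero coefficients
    n_nonzero: int
    coefficients: pd.Series


def train_elasticnet(
    features: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    cv_folds: int = 5,
    alpha_grid=DEFAULT_ALPHA_GRID,
    mixing_grid=DEFAULT_MIXING_GRID,
    seed: int = 0,
    max_iter: int = 2000,
) -> ElasticNetResult:
    """Elastic-net logistic regression with CV grid search by AUROC.

    ``alpha`` is the overall regularization strength (mapped to the
    inverse-regularization C = 1/alpha) and ``mixing`` the l1/l2 tradeoff
    (l1_ratio). Covariates, when given, are appended as penalized columns
    (the solver applies one penalty to all columns; see the methods note).
    Requires at least ``min_class_size``-style balance upstream — here
    both classes must simply be present with >= 2 members.
    """
    y = labels.loc[features.index].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    x = features
    if covariates is not None:
        x = pd.concat([features, covariates.loc[features.index]], axis=1)
    xv = x.to_numpy(dtype=float)

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    best = (-np.inf, None, None)
    for alpha in alpha_grid:
        for mixing in mixing_grid:
            clf = LogisticRegression(
                solver="saga", C=1.0 / alpha, l1_ratio=mixing,
                max_iter=max_iter, tol=1e-3, random_state=seed,
            )
            prob = cross_val_predict(clf, xv, y, cv=cv, method="predict_proba")[:, 1]
            auroc = roc_auc_score(y, prob)
            if auroc > best[0]:
                best = (auroc, alpha, mixing, prob)
    cv_auroc, alpha, mixing, prob = best
    cv_aupr = average_precision_score(y, prob)
    final = LogisticRegression(
        solver="saga", C=1.0 / alpha, l1_ratio=mixing,
        max_iter=max_iter, tol=1e-3, random_state=seed,
    ).fit(xv, y)
    coef = pd.Series(final.coef_.ravel(), index=x.columns)
    n_nonzero = int((coef != 0).sum())
    return ElasticNetResult(
        model=final, best_alpha=alpha, best_mixing=mixing,
        cv_auroc=float(cv_auroc), cv_aupr=float(cv_aupr),
        sparsity=float((coef == 0).mean()), n_nonzero=n_nonzero,
        coefficients=coef,
    )


def nonzero_fraction(coefficients: pd.Series | np.ndarray) -> float:
    """Fraction of nonzero entries in a coefficient vector."""
    coef = np.asarray(coefficients, dtype=float)
    if coef.size == 0:
        raise ValueError("empty coefficient vector")
    return float(np.count_nonzero(coef) / coef.size)


def aupr_delta(
    metrics_real: pd.Series | dict,
    metrics_permuted: pd.Series | dict,
) -> float:
    """Mean AUPR(real) - AUPR(permuted) over matched task keys."""
    real = pd.Series(metrics_real, dtype=float)
    perm = pd.Series(metrics_permuted, dtype=float)
    common = real.index.intersection(perm.index)
    skipped = set(real.index).symmetric_difference(perm.index)
    if skipped:
        warnings.warn(f"skipping unmatched keys: {sorted(map(str, skipped))}", stacklevel=2)
    if len(common) == 0:
        raise ValueError("no matched keys between real and permuted metrics")
    return float((real.loc[common] - perm.loc[common]).mean())
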