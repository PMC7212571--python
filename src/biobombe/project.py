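"""Network projection scoring of compressed features.

A single matrix multiplication H (gene sets x genes) x W (genes x k)
yields raw gene-set scores for every latent feature. Because hub genes
and large sets inflate raw scores, each cell is standardized against the
scores obtained from degree-preserving permuted networks: the z-score of
the observed projection against the permutation distribution is the
interpretation score, converted to a two-tailed normal p-value. A gene
set is "captured" by a feature when it attains the highest positive or
highest negative z-score among all sets and passes a Bonferroni-adjusted
threshold; coverage is the fraction of a collection captured by at least
one feature, computed for individual models, seed ensembles, dimension
ensembles, or everything combined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gsnet import MembershipMatrix, PermutedEnsemble

__all__ = [
    "RawScoreMatrix",
    "BioBombeScoreMatrix",
    "TopAssignment",
    "FeatureAssignment",
    "CoverageReport",
    "raw_scores",
    "zscores",
    "score_weight_matrix",
    "assign_top",
    "coverage",
    "ora_fisher",
]


@dataclass
class RawScoreMatrix:
    """Gene-sets x features raw projection scores G = H W."""

    G: pd.DataFrame
    provenance: dict = field(default_factory=dict)


@dataclass
class BioBombeScoreMatrix:
    """Z-scores of raw projections against the permuted-network null."""

    Z: pd.DataFrame            # gene sets x features; NaN where undefined
    p: pd.DataFrame            # two-tailed normal p-values
    permuted_mean: pd.DataFrame
    permuted_sd: pd.DataFrame
    provenance: dict = field(default_factory=dict)


@dataclass
class FeatureAssignment:
    feature: str
    tail: str                  # "positive" or "negative"
    set_name: str
    z: float
    p: float
    passed: bool


@dataclass
class TopAssignment:
    """Per-feature top positive/negative gene-set assignments."""

    assignments: list[FeatureAssignment]
    alpha_base: float
    n_latent_dims: int

    @property
    def threshold(self) -> float:
        return self.alpha_base / self.n_latent_dims

    def captured_sets(self) -> set[str]:
        """Unique set names captured by a Bonferroni-passing assignment."""
        return {a.set_name for a in self.assignments if a.passed}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature": a.feature, "tail": a.tail, "set_name": a.set_name,
                    "z": a.z, "p": a.p, "assigned": a.passed,
                }
                for a in self.assignments
            ]
        )


@dataclass
class CoverageReport:
    captured: set[str]
    collection_size: int
    granularity: str

    @property
    def coverage(self) -> float:
        return len(self.captured) / self.collection_size


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def raw_scores(H: MembershipMatrix, W: pd.DataFrame, provenance=None) -> RawScoreMatrix:
    """G = H W; H columns and W rows must share one gene ordering."""
    if list(H.H.columns) != list(W.index):
        raise ValueError("gene order of H columns and W rows differs; align first")
    g = H.H.to_numpy(dtype=float) @ W.to_numpy(dtype=float)
    return RawScoreMatrix(
        pd.DataFrame(g, index=H.H.index, columns=W.columns),
        provenance=dict(provenance or {}),
    )


def zscores(G: RawScoreMatrix, ensemble_scores: list[RawScoreMatrix]) -> BioBombeScoreMatrix:
    """Standardize each cell of G against its permuted-score distribution.

    The permutation standard deviation is the population SD (divisor n)
    over the permuted values of that cell. Cells where the permuted SD is
    zero get z = 0 when the observed score equals the permuted mean, and
    NaN (flagged undefined, excluded from assignments) otherwise.
    """
    if len(ensemble_scores) < 2:
        raise ValueError("need at least 2 permuted score matrices")
    stack = np.stack([m.G.to_numpy(dtype=float) for m in ensemble_scores])
    for m in ensemble_scores:
        if m.G.shape != G.G.shape:
            raise ValueError("permuted score matrix shape differs from observed")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=0)
    obs = G.G.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mean) / sd
    zero_sd = sd == 0
    z[zero_sd & (obs == mean)] = 0.0
    z[zero_sd & (obs != mean)] = np.nan
    p = 2.0 * stats.norm.sf(np.abs(z))
    idx, cols = G.G.index, G.G.columns
    return BioBombeScoreMatrix(
        Z=pd.DataFrame(z, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        permuted_mean=pd.DataFrame(mean, index=idx, columns=cols),
        permuted_sd=pd.DataFrame(sd, index=idx, columns=cols),
        provenance=dict(G.provenance),
    )


def score_weight_matrix(
    W: pd.DataFrame,
    H: MembershipMatrix,
    ensemble: PermutedEnsemble,
    provenance=None,
) -> BioBombeScoreMatrix:
    """Convenience: raw projection plus z-scoring in one call."""
    observed = raw_scores(H, W, provenance=provenance)
    permuted = [raw_scores(perm, W) for perm in ensemble.permutations]
    return zscores(observed, permuted)


# ---------------------------------------------------------------------------
# top assignment and coverage
# ---------------------------------------------------------------------------

def assign_top(
    Z: BioBombeScoreMatrix,
    alpha_base: float = 0.05,
    n_latent_dims: int | None = None,
) -> TopAssignment:
    """Per feature, assign the top positive and top negative gene set.

    An assignment passes when its two-tailed p-value is below the
    Bonferroni-adjusted threshold alpha_base / n_latent_dims (default
    divisor: the number of latent features in the model). Ties in z break
    toward the lexicographically smallest set name; undefined (NaN) cells
    never contribute.
    """
    if n_latent_dims is None:
        n_latent_dims = Z.Z.shape[1]
    threshold = alpha_base / n_latent_dims
    # lexicographic index order makes idxmax/idxmin tie-breaks deterministic
    z_sorted = Z.Z.sort_index()
    p_sorted = Z.p.sort_index()
    assignments: list[FeatureAssignment] = []
    for feature in z_sorted.columns:
        col = z_sorted[feature]
        if col.isna().all():
            continue
        for tail, name in (("positive", col.idxmax(skipna=True)),
                           ("negative", col.idxmin(skipna=True))):
            zval = float(col[name])
            pval = float(p_sorted.loc[name, feature])
            assignments.append(
                FeatureAssignment(
                    feature=feature, tail=tail, set_name=name,
                    z=zval, p=pval, passed=bool(pval < threshold),
                )
            )
    return TopAssignment(assignments, alpha_base, n_latent_dims)


def coverage(
    assignments: list[TopAssignment] | TopAssignment,
    collection_size: int,
    granularity: str = "individual",
) -> CoverageReport:
    """C = |union of captured set names| / collection size.

    ``granularity`` is a label recording how the assignments were pooled:
    one model ("individual"), seed ensemble ("ensemble"), all models at a
    dimensionality ("dimension"), or everything ("all"). The arithmetic is
    the same union in every case.
    """
    if collection_size <= 0:
        raise ValueError("collection size must be positive")
    if isinstance(assignments, TopAssignment):
        assignments = [assignments]
    captured: set[str] = set()
    for a in assignments:
        captured |= a.captured_sets()
    return CoverageReport(captured, collection_size, granularity)


# ---------------------------------------------------------------------------
# ORA comparison baseline
# ---------------------------------------------------------------------------

def ora_fisher(
    weights: pd.Series,
    sd_cutoff: float,
    geneset,
    background,
    tail: str = "high",
) -> tuple[float, float]:
    """Overrepresentation of a gene set among extreme-weight genes.

    The tail is genes with weight above mean + sd_cutoff * sd (or below
    mean - sd_cutoff * sd for ``tail="low"``), restricted to ``background``
    (the genes of the collection). Returns (odds ratio, two-sided Fisher
    exact p). An empty tail yields (nan, 1.0); odds ratios with a zero
    denominator are returned as inf.
    """
    background = [g for g in background if g in weights.index]
    if not background:
        raise ValueError("background is empty after restricting to weight genes")
    geneset = set(geneset) & set(background)
    if not geneset:
        raise ValueError("gene set does not intersect the background")
    w = weights.loc[background]
    mu, sd = float(w.mean()), float(w.std(ddof=0))
    if tail == "high":
        in_tail = set(w.index[w > mu + sd_cutoff * sd])
    elif tail == "low":
        in_tail = set(w.index[w < mu - sd_cutoff * sd])
    else:
        raise ValueError("tail must be 'high' or 'low'")
    if not in_tail:
        return math.nan, 1.0
    bg = set(background)
    a = len(in_tail & geneset)
    b = len(in_tail - geneset)
    c = len((bg - in_tail) & geneset)
    d = len(bg - in_tail - geneset)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return odds, float(p)
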