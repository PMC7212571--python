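# Methods

## Overview

This package compresses a samples × genes expression matrix with five
algorithms (PCA, ICA, NMF, a denoising autoencoder, a variational
autoencoder) across a grid of latent dimensionalities *k*, then interprets
every latent feature by projecting gene-set membership networks onto the
learned weight matrices and standardizing against a degree-preserving
permutation null. Downstream modules quantify weight-matrix stability
(SVCCA), gene-set coverage, transfer to external data, and the predictive
value of compressed features under elastic-net classification.

## Training procedure

Samples are split 90/10 into train/test partitions, stratified by tissue
(or cancer type) so each partition has proportional tissue representation.
The per-stratum train size is `round(fraction × stratum size)` with the
remainder in test; a singleton stratum goes to train with a warning (the
rounding rule is a package choice — any consistent rule preserves the
stratification contract).

Each gene is then min-max scaled to [0, 1] **within each partition
independently** — the order matters, and a test asserts each partition's
per-gene min/max are exactly 0/1. Constant genes scale to all zeros rather
than being dropped, keeping the gene universe identical across partitions.
Gene filtering, when used, keeps the top-*n* genes by raw median absolute
deviation (no 1.4826 consistency constant; the ranking is invariant to it).

A permuted baseline shuffles every gene's values across samples
independently. This preserves each gene's marginal distribution (and hence
its min-max scaling, up to row order) while destroying all gene-gene
correlation, so any structure a model finds in permuted data is a
degree-of-freedom artifact, not biology.

## Compression algorithms

PCA, ICA and NMF use scikit-learn (`svd_solver="full"`, FastICA with
unit-variance whitening, NMF with random init). ICA columns are rescaled
to unit norm because ICA scale and sign are unidentifiable and unit-norm
columns stabilize downstream projection z-scores. Every fit is
deterministic given its seed.

The two autoencoders are compact numpy implementations with a single
dense bottleneck of *k* units, a sigmoid output layer, a binary
cross-entropy objective (summed over genes, averaged over the minibatch)
and Adam. The DAE uses masking noise — a random fraction (default 0.1) of
input entries zeroed per minibatch — and a linear bottleneck. The VAE
encoder outputs (μ, log σ²) of a diagonal Gaussian; a reparameterized
sample feeds the decoder, and the loss adds `kl_weight × KL(q ‖ N(0, I))`
(default weight 1). Defaults: learning rate 5e-4, batch size 50, 50
epochs. Gradients are hand-derived; the architectures are small enough
that this is easy to audit and fast on one CPU. All random draws
(initialization, shuffling, corruption masks, reparameterization) come
from one generator seeded by the model seed, so repeated fits are
bit-identical.

For the autoencoders, the genes × *k* weight matrix handed to
interpretation is the **decoder** weight matrix (latent → genes),
transposed. The decoder mirrors the generative direction of the linear
factorizations (data ≈ activations × weightsᵀ), which keeps the network
projection's orientation consistent across all five algorithms. Encoder
weights remain accessible on the backend objects.

Reconstruction quality is measured as binary cross-entropy (natural log;
per-sample mean over genes, then mean over samples) with reconstructions
clipped to [1e-7, 1 − 1e-7] because the linear models can exit [0, 1],
and as the per-sample Pearson correlation between input and
reconstruction (zero-variance rows are recorded as NaN and excluded from
means).

The reference grid is the 28 dimensionalities 2–200. Desk-scale runs and
the acceptance script use the sub-grid {2, 3, 4, 8} with two seeds and
three algorithms (PCA, NMF, VAE) — chosen to bracket the number of
planted factors from below and above while exercising one deterministic,
one stochastic-linear and one neural model family.

## Network projection scores

A gene-set collection defines a binary membership matrix H (gene sets ×
genes). Raw scores are the single product G = H·W. Because hub genes and
large sets inflate raw scores, each cell is standardized against the
scores obtained from permuted networks generated by **XSwap**: repeatedly
draw two edges (s₁,g₁), (s₂,g₂) and rewire to (s₁,g₂), (s₂,g₁) when the
endpoints are distinct and neither target edge exists. Degree preservation
is exact by construction. The attempt budget is 10 × edge-count per
permutation (edges drawn with replacement; failed attempts count), and the
null uses 10 permuted networks by default.

The z-score per cell uses the **population** standard deviation (divisor
n) of that cell's permuted scores — the literal reading of standardizing
one observation against an empirical null; with 10 permutations the
distinction from the sample SD is a 5% scale factor applied uniformly.
Cells with zero permuted SD get z = 0 if the observation equals the
permuted mean and are otherwise flagged undefined and excluded from
assignment. Two-tailed normal p-values accompany every z.

A feature "captures" a gene set when that set attains the feature's
highest positive or highest negative z (both tails count) and the p-value
passes a Bonferroni threshold α/k with α = 0.05 and divisor k = the
model's latent dimensionality (overridable). Ties break toward the
lexicographically smallest set name for determinism. Coverage is
|union of captured sets| / collection size, computed for one model
(individual), one algorithm's seed ensemble, all models at one k, or
everything pooled.

The ORA baseline builds a tail of genes with weight above
mean + cutoff·SD (or below, for the negative tail) over the collection's
gene background and applies Fisher's exact test to the 2×2 tail ×
membership table.

## SVCCA

Weight matrices are compared by singular vector canonical correlation
analysis: center columns, SVD, keep the smallest leading set of directions
whose squared singular values reach 98% of the total (interpreting the
threshold on variance; a flag switches to raw singular values), then run
CCA between the two reduced genes × d representations via the SVD-based
closed form with 1e-10 ridge regularization on the covariance diagonals.
The mean of the min(d₁, d₂) canonical correlations is the similarity.
Column centering before the SVD is standard SVCCA preprocessing; the
statistic is invariant to invertible linear maps of either matrix, equals
1.0 for self-comparison, and sits near 0.04 for independent Gaussian
matrices of 2000 genes × 5 features.

## Synthetic data

The generator emulates processed bulk RNA-seq compendia:
X = Z·Lᵀ + E, where L is block-sparse with each of the `n_factors`
factors loading positively (uniform in strength × [0.5, 1.5]) on a
disjoint block of `genes_per_factor` genes; Z is standard normal plus
tissue-specific means (drawn N(0,1) per tissue × factor) plus binary
trait shifts on selected factors; E is i.i.d. Gaussian noise. The global
minimum is subtracted (not clipped) so values are non-negative for NMF
without distorting correlations. Planted blocks double as ground-truth
gene sets; decoy sets are sampled uniformly without replacement within a
set (with replacement across sets).

Defaults — 500 samples × 2000 genes, 3 factors of 50 genes, factor
strength 2.0, noise SD 0.5, 4 tissues, one trait shifting factor 0 by
2.0, 20 decoy sets of 50 genes — describe a compendium whose planted
factors dominate the leading principal axes at roughly 4:1
signal-to-noise, a regime comparable to strong pathway programs in real
tissue panels. What the generator does **not** emulate: read-count
sampling, library-size and batch effects, gene-length bias,
heavy-tailed expression marginals, or overlapping/correlated pathway
membership. Passing tests therefore demonstrate correctness of the
machinery and recoverability of strong planted structure, not performance
on the subtler correlation structure of real compendia.

## Elastic-net evaluation

Classification uses logistic regression with an elastic-net penalty
(saga solver), searching regularization strength α ∈ {0.1, 0.13, 0.15,
0.2, 0.25, 0.3} (mapped to C = 1/α) × mixing l1_ratio ∈ {0.15, 0.16,
0.2, 0.25, 0.3, 0.4}, selecting by 5-fold stratified cross-validated
AUROC; the final model is refit at the best pair and reports AUROC, AUPR,
and sparsity. Covariates (log10 mutation burden, one-hot cancer type) are
appended as **penalized** columns: the solver applies one penalty to all
columns, and this choice is recorded here rather than hidden.

Gene-alteration labels mark a sample positive for a non-silent mutation
or a GISTIC ±2 copy event (sign by gene class). Hypermutators (log10
mutation count > cohort mean + 5 SD) are removed before balance checks;
a cancer type is retained only with positive fraction in [5%, 95%] and
at least 15 samples per class. Sex-balance filtering keeps tissues with
male/female ratio in [0.5, 1.5], boundaries inclusive; tissues with zero
female samples have an undefined ratio and are dropped. Welch t-tests
(unequal-variance, two-tailed) are oriented group-1 minus group-0.

External transfer computes D′ = Wᵀ·D over the gene intersection g′ with
no re-scaling of D (a flag enables min-max scaling for users who want
cross-platform comparability); the overlap fraction |g′|/|model genes| is
always reported and a warning fires below a configurable floor.

## Numerical choices and degenerate inputs

- BCE clipping ε = 1e-7; natural log throughout.
- Zero-variance sample rows → NaN correlations, excluded from means.
- Zero-range genes → scaled to 0, never dropped.
- XSwap on networks with no valid swap (single edge, complete bipartite)
  returns the input unchanged.
- CCA ridge 1e-10; canonical correlations clipped to [0, 1].
- MAD ties and top-assignment ties break by identifier order.

## Known limitations

- The autoencoders are single-bottleneck by design; deeper architectures
  and per-k hyperparameter optimization are out of scope (hyperparameters
  are exposed as configuration).
- The per-model Bonferroni divisor is the model's own k; pooled-model
  coverage reuses each model's threshold rather than re-adjusting across
  the pool (an override exists).
- SVCCA's 98% retention can keep different dimension counts for the two
  inputs; the mean runs over min(d₁, d₂) correlations.
- The elastic-net cannot leave covariates unpenalized; effect sizes for
  covariate-heavy tasks should be read accordingly.
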