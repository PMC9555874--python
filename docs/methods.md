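# Methods

This note documents the models, numerical choices, and limitations of
`daeimpute`, and what its synthetic benchmarks do and do not establish.

## Model

One fully-connected autoencoder spans one genomic segment. The input and
output layers have two nodes per variant (ref-allele presence, alt-allele
presence); hom-ref, het, hom-alt, and missing map to (1,0), (1,1), (0,1),
(0,0). Encoder layers shrink geometrically — layer *k* has
`round(width_{k-1} · size_ratio)` units, floored at 2 — and the decoder
mirrors the encoder. Hidden activations are one of sigmoid, tanh, relu,
softplus, leakyrelu; the output layer is always sigmoid, so each output node
is an allele-presence probability.

The two per-variant outputs (p_ref, p_alt) are folded into three genotype
scores — `p_ref(1−p_alt)`, `p_ref·p_alt`, `(1−p_ref)p_alt` — and normalized
proportionally to probabilities. The fourth product, `(1−p_ref)(1−p_alt)`,
is the null state and is dropped before normalization: imputation must emit
a genotype. A config switch applies a true softmax over the three scores
instead; proportional scaling is the default because the sigmoid outputs are
already probabilities and exponentiating them compresses their range a
second time. If all three scores are zero the output is uniform (1/3 each).
Hard-call ties break toward the fewer-alt genotype.

## Objective

The training loss per batch is

    SFL = FL + β·S(ρ‖ρ̂) + λ₁·‖W‖₁ + λ₂·Σ W²

- **Focal term.** For each output node with truth x ∈ {0,1} and predicted
  presence probability p, let q = x·p + (1−x)·(1−p) be the predicted
  probability of the truth class. Then `FL = −α (1−q)^γ log q`, summed over
  nodes and averaged over the batch. γ = 0 recovers binary cross-entropy
  exactly. The weight α is the batch frequency of the node's truth class
  (a config switch provides the conventional inverse-frequency weighting).
  The factor is applied to the truth-class probability, not to the raw
  sigmoid output: applying `(1−p)^γ` literally to both the x=1 and x=0
  terms makes the x=0 loss vanish as p→1, a degenerate optimum where the
  network predicts every allele present; with that form, training loss
  drops to ~0.02 while held-out dosage r² stays at ~0.07 on the standard
  benchmark below. The truth-class form reaches r² ≈ 0.91 under identical
  conditions.
- **Sparsity.** S is the Bernoulli KL divergence between the target mean
  hidden activation ρ and the observed mean ρ̂ over all hidden nodes of the
  batch. For tanh the activations are affinely mapped to [0,1] first. The
  grid includes the boundary value ρ = 1.0; it is clamped to 1−1e-7 inside
  the KL rather than rejected.
- **Penalties.** L1 is the sum of absolute weights; the L2 term is the sum
  of squared weights (ridge), scaled directly by λ₂. Biases are exempt from
  both.

Probabilities inside logs are clamped to [1e-7, 1−1e-7]. Gradients are
analytic throughout (including the sparsity path through every hidden
layer) and are checked against central finite differences to 1e-4 in the
test suite. Weights initialize with uniform Glorot fan-based bounds from a
seeded generator; optimizers are hand-rolled adam (β₁=0.9, β₂=0.999),
rmsprop (decay 0.9), and plain gradient descent.

## Tiling

Correlations are computed on unphased alt-dosage vectors {0,1,2} — the
standard genotype-LD proxy, since the package never phases — over samples
non-missing at both sites, only between common variants (MAF ≥ 0.005,
default), only within ±`box_halfwidth` (500) positions, and thresholded at
|r| ≥ 0.45. The box count at SNP k counts retained pairs with both ends
within the window at k; it is computed with a difference array in O(pairs).

Minima detection applies a centered moving average (width 11) first and
takes plateau midpoints, since raw counts are integer-valued and noisy.
Each segment is the region between consecutive minima (its high-LD core)
plus weak-LD flanks: from the bounding hotspot minimum, the flank extends
while smoothed counts stay below 10% of the adjacent core's peak, so
neighboring segments overlap across the hotspot. Rare variants are excluded
from the correlation and boundary computations but assigned to the segment
of the nearest common variant, implemented by cutting at midpoints between
bounding common SNPs, so the segment union covers every variant. Oversize
segments split at their deepest internal minima; anything still above 6000
SNPs is sliced into 6000-SNP windows advancing by 3500 (2500 overlap), with
the final window right-anchored.

## Training curriculum

Masking rates escalate linearly (geometric available) from 0.80 at cycle 1
to (m−5)/m at the final cycle implied by `max_epochs / epochs_per_cycle`;
with a single cycle the rate is the initial 0.80. Masks are re-drawn per
batch and per sample — the strongest augmentation granularity — by taking
the ⌈rate·m⌉ smallest of m iid uniforms per row. The loss is computed
against the uncorrupted encoding over all output nodes (a masked-only
variant is available behind a flag). The learning rate is multiplied by the
decay ratio every 500 epochs; optimizer state persists across cycles. Early
stopping compares full-precision cycle-mean losses and fires when the
current cycle fails to be strictly lower.

Defaults keep the published study conditions (0.80, 5, 500 epochs/cycle,
batch 256). The test suite and acceptance script run the same curriculum at
smaller problem sizes — tens of epochs per cycle on 200-variant panels —
which this package treats as its standard desk-scale benchmark
configuration.

## Offspring simulation

Parents are pseudo-phased once (heterozygous sites get seeded random
phase); each offspring draws two distinct parents uniformly (with
replacement across offspring), and each transmitted gamete is a mosaic of
the parent's two pseudo-haplotypes with a Poisson(total cM/100) number of
crossovers placed uniformly on the cM scale — crossover density therefore
follows the local recombination rate, with no interference model. Offspring
collapse back to unphased genotypes. Missing parental genotypes transmit
reference alleles.

## Meta-model

The coarse grid draws distinct combinations uniformly from the published
per-hyperparameter value lists (duplicates redrawn). Segment features:
variant count, mean recombination rate over the segment span (0 without a
map), mean |r| over all defined dosage-correlation pairs, MAF-bin
proportions over the 8 evaluation bins plus a <0.005 rare bin, the number
of principal components covering 90% of dosage variance, the variance share
of the first two components, unique allele-presence row and genotype row
counts, and mean heterozygosity. The XGBoost regressor runs with default
settings, seeded, with categorical hyperparameters one-hot encoded; CV r²
is computed from pooled 10-fold out-of-fold predictions. Candidate
selection returns the top 10 predicted combinations plus the best observed
one, deduplicated.

## Evaluation

Per-variant r² is the squared Pearson correlation between imputed and true
dosages across samples; variants where either vector is constant are
undefined, excluded from means, and counted. MAF (computed on the truth
panel) is binned half-open [lo, hi) over {0.001, 0.005, 0.01, 0.05, 0.1,
0.2, 0.3, 0.4, 0.5}, last bin closed, with MAF < 0.001 reported separately
as ultra-rare. Concordance is the exact-match fraction over non-missing
truth calls; F1 is macro-averaged over the three genotype classes. Method
comparisons report per-segment win counts (ties dropped), a two-sided
Wilcoxon rank-sum p-value, and a two-proportion z-test on win fractions.

## Synthetic panels

The generator builds each LD block from a set of founder haplotypes sharing
one alt-carrier pattern (per-variant ref/alt role swaps preserve |r| = 1
within the block in the noise-free limit); per-site flip noise with
probability ε = (1 − r²_target^{1/4})/2 attenuates pairwise correlation to
the target, following r_noisy = (1−2ε)² r_clean for Bernoulli flips. A
configurable fraction of sites is overwritten with rare variants private to
few haplotypes, producing the rare-heavy MAF tail; hotspot gaps between
blocks are mutually independent variants. The generator returns the true
block ranges and expected per-variant MAFs as oracle metadata.

What this emulates: block-LD structure with sharp hotspot boundaries, a
skewed MAF spectrum, array-style observation biased toward common variants
(sampling weights proportional to MAF), and unphased diploid calls. What it
does not: gradual LD decay within blocks, demographic structure and
admixture, genotyping error, indels/multi-allelic sites, and realistic
rare-variant sharing patterns. Passing the benchmarks therefore shows the
machinery learns and exploits LD as constructed — it does not certify
accuracy on real cohorts, where LD is messier and rare-variant imputation
is much harder.

## Degenerate inputs and edge rules

Fewer than 3 common variants → a single segment. Zero-variance variants
never enter correlation pairs. All-missing segments are rejected by feature
extraction but tolerated by training (the loss is then constant). Variants
imputed by zero observed markers in their segment still produce output
(all-null input), flagged observed=False. Allele matching at inference is
exact; ref/alt-swapped or strand-flipped sites are dropped and counted, not
rescued, because silent strand errors corrupt imputation.

## Reproducibility

All randomness flows through `numpy.random.Generator`s seeded from explicit
arguments; the pipeline derives named substreams from one root seed by
hashing. Two runs with the same config and seed produce byte-identical
manifests (the config hash excludes the output directory). Model bundles
serialize as one `.npz` (weights) plus one JSON (hyperparameters, variant
count) per segment, indexed by a manifest listing variants and segment
ranges.
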