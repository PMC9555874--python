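# daeimpute

Reference-free, unphased genotype imputation with sparse denoising
autoencoders.

## The problem

Genotype imputation infers the genotypes of unobserved variant sites from a
small assayed subset (typically 1–10% of known sites on a genotyping array),
exploiting linkage disequilibrium (LD) — the block-wise correlation structure
that recombination leaves along the genome. Standard imputation uses hidden
Markov models that need runtime access to a large, privacy-sensitive
sequenced reference panel. This package implements the alternative: the
reference panel is distilled into trained neural-network weights, so
imputation needs only the model files, runs fast, and never ships anyone's
genomes.

It is aimed at population-genetics method developers and at anyone who wants
an end-to-end, fully synthetic-testable implementation of the approach:
every stage runs on generated haplotype panels with known LD structure.

## The method

1. **Tiling** (`ld_tiling`). Pairwise Pearson correlations of alt-allele
   dosage between common SNPs (MAF ≥ 0.5%) are computed inside a sliding
   window of ±500 SNPs and thresholded at |r| ≥ 0.45. A per-SNP "box count"
   of retained pairs measures local LD strength; local minima of this curve
   are recombination hotspots and split the chromosome into approximately
   independent segments (a high-LD core plus weak-LD flanks shared with
   neighbors). Segments are capped at 6000 SNPs, splitting first at internal
   count minima and then into fixed 6000-SNP windows overlapping by 2500.

2. **Encoding** (`genotype_io`). Each bi-allelic genotype becomes two binary
   allele-presence nodes: hom-ref → (1,0), het → (1,1), hom-alt → (0,1),
   missing → (0,0). Model outputs are folded back into three normalized
   genotype-class probabilities and the alt-allele dosage
   `P(het) + 2·P(hom-alt)`.

3. **Model and loss** (`autoencoder`). One fully-connected, mirrored
   autoencoder per segment, sigmoid outputs. The objective is a sparse focal
   loss

   `SFL = −α_t (1−q_t)^γ log q_t + β·S(ρ‖ρ̂) + λ₁‖W‖₁ + λ₂‖W‖₂²`

   where `q_t` is the predicted probability of node *t*'s truth class, the
   focal factor `(1−q_t)^γ` down-weights well-classified nodes (mostly the
   abundant reference alleles at rare-variant sites), `α_t` is the batch
   frequency of the node's truth class, and `S` is the Bernoulli KL
   divergence between the target hidden activation ρ and the observed batch
   mean ρ̂. Everything is NumPy with analytic gradients (adam / rmsprop /
   sgd), verified against finite differences.

4. **Training** (`training`). Denoising with an escalating masking
   curriculum: each cycle masks a per-sample random subset of variants to
   (0,0) — starting at 80% and rising until only 5 variants remain observed
   — and runs a fixed number of epochs against the uncorrupted targets.
   Training stops early when a cycle's mean loss stops improving.

5. **Augmentation** (`augmentation`). The panel can be expanded with
   simulated offspring: parents are pseudo-phased, gametes recombine with
   Poisson crossovers placed on the genetic-map cM scale, and offspring are
   collapsed back to unphased genotypes.

6. **Hyperparameter selection** (`hyperopt`). A random coarse grid over the
   published value lists, per-segment LD-complexity features (unique
   haplotypes/diplotypes, heterozygosity, PCA variance profile, MAF-bin
   proportions, recombination rate), and an XGBoost meta-model that predicts
   segment-specific accuracy of untried combinations; the top 10 predicted
   candidates plus the best observed one advance.

7. **Imputation and scoring** (`inference`, `evaluation`). Observed markers
   are matched by exact (chrom, pos, ref, alt), unobserved sites enter as
   (0,0), overlapping segment predictions are averaged, observed genotypes
   pass through unchanged, and results are written as VCF with GT/GP/DS.
   Accuracy is per-variant dosage r², concordance, and macro-F1, stratified
   over the standard MAF bins, with rank-sum and two-proportion tests for
   method comparisons.

## Worked example

```bash
daeimpute simulate-panel --seed 3 --out panel.vcf --truth truth.json \
    --n-haplotypes 300 --n-blocks 2 --block-variants 40 --gap-variants 15
daeimpute tile --vcf panel.vcf --out segments.bed --box 25
```

prints

```
wrote 150 samples x 95 variants
wrote 2 segments to segments.bed
```

— the generator made two 40-variant LD blocks separated by a 15-variant
hotspot gap, and the tiler recovered exactly the two blocks, splitting
inside the gap. The full pipeline (tile → train → mask → impute → evaluate)
runs as

```bash
daeimpute run-all --seed 1 --outdir run/
```

which ends by printing the evaluation summary, e.g.

```json
{
 "mean_r2": 0.727,
 "concordance": 0.866,
 "macro_f1": 0.870,
 "per_bin_mean_r2": {"0.3-0.4": 0.852, "0.4-0.5": 0.786, ...}
}
```

meaning ~87% of held-out hard calls were exact matches and the mean
per-variant squared correlation between imputed and true dosages was 0.73.
The MAF-bin breakdown is informative: the high-MAF bins holding the LD-block
variants impute well (r² ≈ 0.8), while the deliberately LD-free hotspot-gap
variants (the 0.1–0.3 bins here) are near zero — imputation can only
recover what LD determines. `run/manifest.json` records the config hash and
seed for exact reproduction.

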