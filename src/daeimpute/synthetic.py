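"""Synthetic haplotype panels with controllable LD-block structure.

Panels are built from founder haplotypes: within each LD block a small set
of founder haplotypes carries the variant alleles, every simulated haplotype
copies one founder for the whole block, and per-site flip noise attenuates
the within-block correlation to a target r-squared.  Blocks are separated by
recombination-hotspot gaps of mutually independent variants, so the true
block boundaries are known and serve as the oracle for tiling tests.

For two block variants perfectly correlated across founders, flipping each
allele independently with probability ``eps`` attenuates their Pearson
correlation by (1-2*eps)^2, so the flip rate for a target within-block
r-squared is ``eps = (1 - r2**0.25) / 2``.

The minor-allele-frequency spectrum is skewed toward rare variants, as in
real cohorts: block-variant MAFs are quantized to founder multiplicities and
a configurable fraction of sites are rare mutations private to a few
haplotypes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .augmentation import GeneticMap
from .genotype_io import MISSING, GenotypePanel, Variant


@dataclasses.dataclass
class BlockSpec:
    n_variants: int
    within_block_r2: float = 0.9
    n_founders: int = 8
    rare_fraction: float = 0.0  # fraction of block sites made rare/private
    rare_maf: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.within_block_r2 <= 1:
            raise ValueError("within_block_r2 must be in (0, 1]")
        if self.n_founders < 2:
            raise ValueError("need >= 2 founders")


@dataclasses.dataclass
class PanelTruth:
    """Oracle metadata returned alongside a generated panel."""

    block_ranges: list[tuple[int, int]]  # half-open variant-index ranges
    maf: np.ndarray  # realized per-variant MAF
    expected_maf: np.ndarray  # construction's expected per-variant MAF


def generate_panel(
    n_haplotypes: int,
    blocks: list[BlockSpec],
    hotspot_gap_variants: int = 0,
    gap_maf: float = 0.2,
    rng: np.random.Generator | int = 0,
    chrom: str = "1",
    pos_step: int = 1000,
) -> tuple[GenotypePanel, PanelTruth]:
    """Generate an unphased diploid panel of LD blocks separated by
    independent-variant hotspot gaps.

    ``n_haplotypes`` must be even; haplotypes are paired consecutively into
    diploid samples.  Returns the panel and the true block index ranges plus
    realized MAFs.
    """
    if n_haplotypes % 2 != 0 or n_haplotypes < 2:
        raise ValueError("n_haplotypes must be even and >= 2")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    cols: list[np.ndarray] = []
    expected_af: list[np.ndarray] = []
    block_ranges: list[tuple[int, int]] = []
    for bi, spec in enumerate(blocks):
        # flip noise attenuating clean |r|=1 pairs to the target r-squared
        eps = (1.0 - spec.within_block_r2**0.25) / 2.0
        nf = spec.n_founders
        # one carrier set shared by every variant in the block keeps clean
        # within-block |r| exactly 1; per-variant allele swaps preserve |r|
        n_carry = max(1, min(nf - 1, round(0.4 * nf)))
        carriers = rng.choice(nf, size=n_carry, replace=False)
        founder_has_alt = np.zeros(nf, dtype=np.int8)
        founder_has_alt[carriers] = 1
        swap = rng.random(spec.n_variants) < 0.3  # ref/alt roles swapped
        founder_alleles = np.where(
            swap[None, :], 1 - founder_has_alt[:, None], founder_has_alt[:, None]
        ).astype(np.int8)
        assignment = rng.integers(nf, size=n_haplotypes)
        hap_block = founder_alleles[assignment]  # (n_hap, n_variants)
        q = founder_alleles.mean(axis=0)  # clean allele frequency
        e_af = q * (1 - eps) + (1 - q) * eps
        if eps > 0:
            flips = rng.random(hap_block.shape) < eps
            hap_block = np.where(flips, 1 - hap_block, hap_block).astype(np.int8)
        # overwrite a fraction of sites with rare variants private to a few
        # haplotypes (breaks their LD, enriches the rare tail)
        n_rare = int(round(spec.rare_fraction * spec.n_variants))
        if n_rare:
            rare_sites = rng.choice(spec.n_variants, size=n_rare, replace=False)
            hap_block[:, rare_sites] = (
                rng.random((n_haplotypes, n_rare)) < spec.rare_maf
            ).astype(np.int8)
            e_af[rare_sites] = spec.rare_maf
        start = sum(c.shape[1] for c in cols)
        cols.append(hap_block)
        expected_af.append(e_af)
        block_ranges.append((start, start + spec.n_variants))
        if hotspot_gap_variants and bi < len(blocks) - 1:
            gap = (
                rng.random((n_haplotypes, hotspot_gap_variants)) < gap_maf
            ).astype(np.int8)
            cols.append(gap)
            expected_af.append(np.full(hotspot_gap_variants, gap_maf))
    haps = np.concatenate(cols, axis=1)
    geno = (haps[0::2] + haps[1::2]).astype(np.int8)
    m = haps.shape[1]
    variants = [
        Variant(chrom, (i + 1) * pos_step, "A", "G") for i in range(m)
    ]
    panel = GenotypePanel(
        [f"sample_{i}" for i in range(n_haplotypes // 2)], variants, geno
    )
    af = haps.mean(axis=0)
    e_af_all = np.concatenate(expected_af)
    truth = PanelTruth(
        block_ranges,
        np.minimum(af, 1 - af),
        np.minimum(e_af_all, 1 - e_af_all),
    )
    return panel, truth


def array_mask(
    panel: GenotypePanel,
    observed_fraction: float | None = None,
    marker_positions: list[int] | None = None,
    rng: np.random.Generator | int = 0,
) -> tuple[GenotypePanel, np.ndarray]:
    """Mock genotyping-array data: keep a subset of variants observed, set
    the rest to missing.

    Fraction-based selection is biased toward common variants (arrays tag
    common SNPs): sampling weights are proportional to MAF.  Returns the
    masked panel and the observed-variant index array.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    m = panel.n_variants
    if marker_positions is not None:
        pos = {v.pos: i for i, v in enumerate(panel.variants)}
        observed = np.array(sorted(pos[p] for p in marker_positions), dtype=int)
    else:
        if observed_fraction is None or not 0 < observed_fraction <= 1:
            raise ValueError("observed_fraction must be in (0, 1]")
        k = max(1, int(round(observed_fraction * m)))
        maf = np.nan_to_num(panel.maf(), nan=0.0)
        w = maf + 1e-6
        observed = np.sort(rng.choice(m, size=k, replace=False, p=w / w.sum()))
    if observed.size == 0:
        raise ValueError("empty marker selection")
    geno = np.full_like(panel.genotypes, MISSING)
    geno[:, observed] = panel.genotypes[:, observed]
    return GenotypePanel(panel.sample_ids, panel.variants, geno), observed


def generate_genetic_map(
    panel: GenotypePanel,
    hotspot_positions: list[int] | None = None,
    background_cm_per_mb: float = 1.0,
    hotspot_intensity: float = 50.0,
    hotspot_width_bp: int = 2000,
) -> GeneticMap:
    """Piecewise-linear cumulative cM map over the panel's span, with the
    recombination rate elevated to ``hotspot_intensity`` cM/Mb inside
    windows of ``hotspot_width_bp`` around each hotspot position."""
    if background_cm_per_mb < 0 or hotspot_intensity < 0:
        raise ValueError("rates must be non-negative")
    hotspot_positions = hotspot_positions or []
    chrom_maps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chroms = [v.chrom for v in panel.variants]
    for c in dict.fromkeys(chroms):
        pos = np.array([v.pos for v in panel.variants if v.chrom == c], dtype=float)
        knots = set(pos)
        for h in hotspot_positions:
            knots.add(float(h - hotspot_width_bp / 2))
            knots.add(float(h + hotspot_width_bp / 2))
        grid = np.array(sorted(k for k in knots if pos[0] <= k <= pos[-1]))
        rate = np.full(grid.size, background_cm_per_mb)  # cM/Mb on [i, i+1)
        for h in hotspot_positions:
            inside = (grid >= h - hotspot_width_bp / 2) & (
                grid < h + hotspot_width_bp / 2
            )
            rate[inside] = hotspot_intensity
        seg_cm = np.diff(grid) * rate[:-1] / 1e6
        cm = np.concatenate([[0.0], np.cumsum(seg_cm)])
        chrom_maps[c] = (grid, cm)
    return GeneticMap(chrom_maps)
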