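"""Training-panel augmentation by simulated offspring formation.

Offspring are formed by drawing two distinct parents, recombining each
parent's two pseudo-haplotypes into a transmitted gamete, and collapsing the
two gametes back to unphased genotypes.  Crossover counts per chromosome are
Poisson with mean equal to the chromosome's genetic length in Morgans
(total cM / 100), and crossover positions are placed uniformly on the cM
scale, i.e. density follows the local recombination rate.  No crossover
interference is modeled.

Unphased parents are pseudo-phased once per parent (heterozygous sites get a
random phase), seeded, since the panel carries no phase information.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .genotype_io import HET, MISSING, GenotypePanel


@dataclasses.dataclass
class GeneticMap:
    """Cumulative genetic distance per chromosome: pos (1-based bp) -> cM."""

    chrom_maps: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (pos, cM)

    def __post_init__(self) -> None:
        for chrom, (pos, cm) in self.chrom_maps.items():
            pos = np.asarray(pos, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if (np.diff(pos) <= 0).any():
                raise ValueError(f"{chrom}: positions not strictly increasing")
            if (np.diff(cm) < 0).any():
                raise ValueError(f"{chrom}: cM not non-decreasing")
            self.chrom_maps[chrom] = (pos, cm)

    def cm_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Interpolated cumulative cM at the given bp positions."""
        pos, cm = self.chrom_maps[chrom]
        return np.interp(np.asarray(positions, dtype=float), pos, cm)

    def total_cm(self, chrom: str) -> float:
        _, cm = self.chrom_maps[chrom]
        return float(cm[-1] - cm[0])

    @classmethod
    def read(cls, path: str | Path) -> "GeneticMap":
        """Read a 3-column whitespace table: chrom, pos, cumulative cM."""
        chroms: dict[str, list[tuple[float, float]]] = {}
        for line in Path(path).read_text().splitlines():
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            chrom, pos, cm = parts[0], float(parts[1]), float(parts[2])
            chroms.setdefault(chrom, []).append((pos, cm))
        if not chroms:
            raise ValueError(f"empty genetic map: {path}")
        return cls(
            {
                c: (np.array([p for p, _ in rows]), np.array([m for _, m in rows]))
                for c, rows in chroms.items()
            }
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, (pos, cm) in self.chrom_maps.items():
                for p, c in zip(pos, cm):
                    fh.write(f"{chrom}\t{int(p)}\t{c:.8f}\n")


def pseudo_phase(panel: GenotypePanel, rng: np.random.Generator) -> np.ndarray:
    """Haplotype matrix (2*n_samples, n_variants) over {0,1}; het sites get
    random phase, missing sites are imputed as hom-ref alleles for the
    purpose of gamete formation."""
    g = panel.genotypes
    n, m = g.shape
    hap = np.zeros((2 * n, m), dtype=np.int8)
    hap[0::2] = (g == 2).astype(np.int8)
    hap[1::2] = (g == 2).astype(np.int8)
    het = g == HET
    flip = rng.random((n, m)) < 0.5
    hap[0::2][het & flip] = 1
    hap[1::2][het & ~flip] = 1
    return hap


def _gamete(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    cm_positions: np.ndarray,
    total_cm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Recombinant mosaic of two parental haplotypes along one chromosome."""
    n_cross = rng.poisson(total_cm / 100.0) if total_cm > 0 else 0
    start = int(rng.integers(2))
    if n_cross == 0:
        return (hap_a if start == 0 else hap_b).copy()
    cuts = np.sort(rng.uniform(cm_positions[0], cm_positions[0] + total_cm, n_cross))
    phase = (start + np.searchsorted(cuts, cm_positions, side="right")) % 2
    return np.where(phase == 0, hap_a, hap_b).astype(np.int8)


def simulate_offspring(
    panel: GenotypePanel,
    genetic_map: GeneticMap,
    n_offspring: int,
    rng: np.random.Generator | int = 0,
) -> GenotypePanel:
    """Simulate unphased offspring genotypes from panel samples as parents.

    Each offspring draws two distinct parents uniformly (with replacement
    across offspring); each parent transmits one recombinant gamete.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    if panel.n_samples < 2:
        raise ValueError("need at least 2 parents")
    if not genetic_map.chrom_maps:
        raise ValueError("empty genetic map")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    haps = pseudo_phase(panel, rng)
    chroms = [v.chrom for v in panel.variants]
    positions = np.array([v.pos for v in panel.variants], dtype=float)
    chrom_slices: dict[str, np.ndarray] = {}
    for c in dict.fromkeys(chroms):
        chrom_slices[c] = np.flatnonzero(np.array(chroms) == c)
    geno = np.zeros((n_offspring, panel.n_variants), dtype=np.int8)
    for o in range(n_offspring):
        p1, p2 = rng.choice(panel.n_samples, size=2, replace=False)
        gametes = []
        for parent in (p1, p2):
            gam = np.zeros(panel.n_variants, dtype=np.int8)
            for c, idx in chrom_slices.items():
                cm_pos = genetic_map.cm_at(c, positions[idx])
                gam[idx] = _gamete(
                    haps[2 * parent, idx],
                    haps[2 * parent + 1, idx],
                    cm_pos,
                    genetic_map.total_cm(c),
                    rng,
                )
            gametes.append(gam)
        geno[o] = gametes[0] + gametes[1]
    sample_ids = [f"offspring_{o}" for o in range(n_offspring)]
    return GenotypePanel(sample_ids, panel.variants, geno)


def merge_panels(a: GenotypePanel, b: GenotypePanel) -> GenotypePanel:
    """Sample-wise concatenation of two panels over identical variant lists."""
    if [v.key for v in a.variants] != [v.key for v in b.variants]:
        raise ValueError("variant lists differ; cannot merge panels")
    ids = list(a.sample_ids)
    seen = set(ids)
    for s in b.sample_ids:
        new = s
        k = 1
        while new in seen:
            new = f"{s}_{k}"
            k += 1
        seen.add(new)
        ids.append(new)
    geno = np.concatenate([a.genotypes, b.genotypes], axis=0)
    return GenotypePanel(ids, a.variants, geno)
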