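"""Genotype containers, allele-presence encoding, and VCF input/output.

A diploid genotype at a bi-allelic SNP is represented as one of four states
(hom-ref, het, hom-alt, missing).  For the autoencoder each variant becomes a
pair of binary nodes, (ref-allele presence, alt-allele presence):

    hom-ref -> (1, 0)    het -> (1, 1)    hom-alt -> (0, 1)    missing -> (0, 0)

The network's two sigmoid outputs per variant are folded back into three
normalized genotype-class probabilities, from which the alternative-allele
dosage ``P(het) + 2*P(hom-alt)`` and hard calls are derived.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

# genotype state codes used throughout the package
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_GT_TO_PAIR = {HOM_REF: (1, 0), HET: (1, 1), HOM_ALT: (0, 1), MISSING: (0, 0)}


@dataclasses.dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclasses.dataclass
class GenotypePanel:
    """Samples x bi-allelic SNPs with genotype states {0,1,2,-1}.

    ``genotypes`` has shape (n_samples, n_variants), dtype int8.
    Variant positions must be strictly increasing within a chromosome.
    """

    sample_ids: list[str]
    variants: list[Variant]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        last: dict[str, int] = {}
        for v in self.variants:
            if v.chrom in last and v.pos <= last[v.chrom]:
                raise ValueError(
                    f"positions not strictly increasing at {v.chrom}:{v.pos}"
                )
            last[v.chrom] = v.pos

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant, NaN where all calls missing."""
        g = self.genotypes
        called = g >= 0
        alt_counts = np.where(called, g, 0).sum(axis=0).astype(float)
        n_alleles = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(n_alleles > 0, alt_counts / n_alleles, np.nan)
        return np.minimum(af, 1.0 - af)

    def alt_dosage(self) -> np.ndarray:
        """Alt-allele count matrix as float, NaN at missing calls."""
        d = self.genotypes.astype(float)
        d[self.genotypes == MISSING] = np.nan
        return d

    def subset_variants(self, idx: Sequence[int] | np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx, dtype=int)
        return GenotypePanel(
            self.sample_ids,
            [self.variants[i] for i in idx],
            self.genotypes[:, idx],
        )

    def subset_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx, dtype=int)
        return GenotypePanel(
            [self.sample_ids[i] for i in idx],
            self.variants,
            self.genotypes[idx, :],
        )


def encode_genotypes(genotypes: np.ndarray) -> np.ndarray:
    """Encode a genotype-state matrix to allele-presence pairs.

    Parameters
    ----------
    genotypes
        (n_samples, n_variants) over {0: hom-ref, 1: het, 2: hom-alt,
        -1: missing}.

    Returns
    -------
    (n_samples, 2*n_variants) float array; variant i occupies columns
    (2i, 2i+1) = (ref-presence, alt-presence).  Missing maps to (0, 0).
    """
    g = np.asarray(genotypes)
    if not np.isin(g, (HOM_REF, HET, HOM_ALT, MISSING)).all():
        bad = np.unique(g[~np.isin(g, (HOM_REF, HET, HOM_ALT, MISSING))])
        raise ValueError(f"invalid genotype codes {bad.tolist()}")
    n, m = g.shape
    x = np.zeros((n, 2 * m), dtype=np.float64)
    x[:, 0::2] = ((g == HOM_REF) | (g == HET)).astype(float)
    x[:, 1::2] = ((g == HOM_ALT) | (g == HET)).astype(float)
    return x


def decode_presence(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_genotypes` on exact {0,1} pairs."""
    ref = x[:, 0::2] > 0.5
    alt = x[:, 1::2] > 0.5
    g = np.full(ref.shape, MISSING, dtype=np.int8)
    g[ref & ~alt] = HOM_REF
    g[ref & alt] = HET
    g[~ref & alt] = HOM_ALT
    return g


def allele_outputs_to_probabilities(
    p_ref: np.ndarray, p_alt: np.ndarray, softmax: bool = False
) -> np.ndarray:
    """Fold per-variant sigmoid allele outputs into genotype probabilities.

    The two allele-presence outputs are split into three genotype scores
    (hom-ref, het, hom-alt) and normalized:

        s = (p_ref*(1-p_alt), p_ref*p_alt, (1-p_ref)*p_alt)

    The fourth product term, (1-p_ref)*(1-p_alt), is the null state and is
    dropped: imputation must emit a genotype.  With ``softmax=True`` the three
    scores go through exp before normalization instead of plain proportional
    scaling.

    Accepts scalars or arrays of matching shape; returns shape (..., 3).
    """
    p_ref = np.asarray(p_ref, dtype=float)
    p_alt = np.asarray(p_alt, dtype=float)
    if ((p_ref < 0) | (p_ref > 1) | (p_alt < 0) | (p_alt > 1)).any():
        raise ValueError("allele outputs must lie in [0, 1]")
    scores = np.stack(
        [p_ref * (1.0 - p_alt), p_ref * p_alt, (1.0 - p_ref) * p_alt], axis=-1
    )
    if softmax:
        scores = np.exp(scores)
    total = scores.sum(axis=-1, keepdims=True)
    uniform = np.full_like(scores, 1.0 / 3.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(total > 0, scores / np.where(total > 0, total, 1.0), uniform)
    return probs


def dosage(probs: np.ndarray) -> np.ndarray:
    """Alternative-allele dosage ``P(het) + 2*P(hom-alt)``, in [0, 2]."""
    p = np.asarray(probs, dtype=float)
    return p[..., 1] + 2.0 * p[..., 2]


def hard_calls(probs: np.ndarray) -> np.ndarray:
    """Argmax genotype per variant; ties break toward the fewer-alt genotype."""
    p = np.asarray(probs, dtype=float)
    # argmax returns the first maximal index; class order (hom-ref, het,
    # hom-alt) already ranks by alt-allele count, so ties resolve correctly.
    return np.argmax(p, axis=-1).astype(np.int8)


def _parse_gt(sample_field) -> int:
    alleles = sample_field.get("GT", (None, None))
    if alleles is None or any(a is None for a in alleles):
        return MISSING
    return int(sum(alleles))


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a VCF 4.x into a :class:`GenotypePanel`.

    Only bi-allelic SNPs are kept; multi-allelic or non-SNP records are
    skipped with a logged count.  Phase separators are ignored (genotypes are
    treated as unphased).
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    sample_ids = list(vf.header.samples)
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for lineno, rec in enumerate(vf, start=1):
        alts = rec.alts or ()
        if (
            len(alts) != 1
            or len(rec.ref) != 1
            or len(alts[0]) != 1
            or rec.ref not in "ACGT"
            or alts[0] not in "ACGT"
        ):
            n_skipped += 1
            continue
        try:
            row = np.fromiter(
                (_parse_gt(rec.samples[s]) for s in sample_ids),
                dtype=np.int8,
                count=len(sample_ids),
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(
                f"malformed VCF record near data line {lineno} of {path}: {exc}"
            ) from exc
        variants.append(Variant(rec.chrom, rec.pos, rec.ref, alts[0]))
        rows.append(row)
    vf.close()
    if n_skipped:
        logger.info("skipped %d non-bi-allelic-SNP records in %s", n_skipped, path)
    geno = (
        np.stack(rows, axis=1)
        if rows
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypePanel(sample_ids, variants, geno)


_GT_STR = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), MISSING: (None, None)}


def _build_header(sample_ids: Sequence[str], chroms: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(chroms):
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add(
        "GP", "G", "Float", "Genotype probabilities (hom-ref, het, hom-alt)"
    )
    header.formats.add("DS", 1, "Float", "Alternative allele dosage")
    header.info.add("IMPUTED", 0, "Flag", "Site was imputed, not genotyped")
    for s in sample_ids:
        header.add_sample(s)
    return header


def write_vcf(
    path: str | Path,
    sample_ids: Sequence[str],
    variants: Sequence[Variant],
    probs: np.ndarray | None = None,
    genotypes: np.ndarray | None = None,
    imputed_mask: np.ndarray | None = None,
) -> None:
    """Write genotypes and/or genotype probabilities to an uncompressed VCF.

    Exactly one of ``probs`` (n_samples, n_variants, 3) or ``genotypes``
    (n_samples, n_variants; hard states) must be given; with ``probs`` the
    emitted GT is the argmax call and GP/DS carry the probabilities and
    dosage, with hard ``genotypes`` the GP is the degenerate one-hot vector.
    """
    if (probs is None) == (genotypes is None):
        raise ValueError("provide exactly one of probs or genotypes")
    if probs is None:
        probs = np.zeros((*genotypes.shape, 3))
        for state in (HOM_REF, HET, HOM_ALT):
            probs[genotypes == state, state] = 1.0
        probs[genotypes == MISSING] = np.nan
    calls = hard_calls(probs)
    calls = np.where(np.isnan(probs).any(axis=-1), MISSING, calls)
    ds = dosage(probs)
    header = _build_header(sample_ids, [v.chrom for v in variants])
    out = pysam.VariantFile(str(path), "w", header=header)
    for j, v in enumerate(variants):
        rec = out.new_record(
            contig=v.chrom, start=v.pos - 1, stop=v.pos, alleles=(v.ref, v.alt)
        )
        if imputed_mask is not None and imputed_mask[j]:
            rec.info["IMPUTED"] = True
        for i, s in enumerate(sample_ids):
            rec.samples[s]["GT"] = _GT_STR[int(calls[i, j])]
            rec.samples[s].phased = False
            if not np.isnan(probs[i, j]).any():
                rec.samples[s]["GP"] = tuple(
                    round(float(p), 6) for p in probs[i, j]
                )
                rec.samples[s]["DS"] = round(float(ds[i, j]), 6)
        out.write(rec)
    out.close()
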