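"""Reference-free imputation from trained per-segment autoencoders.

Observed array genotypes are matched to the model's variant list by exact
(chrom, pos, ref, alt) identity, encoded with unobserved sites as the null
pair (0,0), pushed through each segment's network, and folded into
three-class genotype probabilities.  Variants covered by overlapping
segments average their class probabilities (renormalized); observed input
genotypes pass through to the output unchanged.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .autoencoder import Autoencoder
from .genotype_io import (
    MISSING,
    GenotypePanel,
    Variant,
    allele_outputs_to_probabilities,
    encode_genotypes,
)
from .ld_tiling import GenomicSegment


@dataclasses.dataclass
class ModelStore:
    """On-disk bundle of per-segment models plus a JSON manifest."""

    directory: Path
    variants: list[Variant]
    segments: list[GenomicSegment]

    @classmethod
    def create(
        cls, directory: str | Path, variants: Sequence[Variant]
    ) -> "ModelStore":
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        return cls(directory, list(variants), [])

    def add_segment(self, segment: GenomicSegment, model: Autoencoder) -> None:
        model.save(self.directory / f"segment_{segment.segment_id}")
        self.segments.append(segment)

    def write_manifest(self, extra: dict | None = None) -> None:
        manifest = {
            "variants": [[v.chrom, v.pos, v.ref, v.alt] for v in self.variants],
            "segments": [
                {
                    "segment_id": s.segment_id,
                    "variant_range": list(s.variant_range),
                    "core_range": list(s.core_range),
                    "origin": s.origin,
                }
                for s in self.segments
            ],
        }
        if extra:
            manifest.update(extra)
        (self.directory / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "ModelStore":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        variants = [Variant(c, p, r, a) for c, p, r, a in manifest["variants"]]
        segments = [
            GenomicSegment(
                s["segment_id"],
                tuple(s["variant_range"]),
                tuple(s["core_range"]),
                s["origin"],
            )
            for s in manifest["segments"]
        ]
        return cls(directory, variants, segments)

    def model_for(self, segment: GenomicSegment) -> Autoencoder:
        return Autoencoder.load(self.directory / f"segment_{segment.segment_id}")


@dataclasses.dataclass
class MatchReport:
    mapping: dict[int, int]  # observed-panel index -> model variant index
    n_matched: int
    n_dropped: int


def match_variants(
    observed_variants: Sequence[Variant], model_variants: Sequence[Variant]
) -> MatchReport:
    """Exact (chrom, pos, ref, alt) join of observed sites onto the model's
    variant list.  No strand-flip or allele-swap rescue is attempted;
    mismatched sites are dropped and counted."""
    for variants in (observed_variants, model_variants):
        by_chrom: dict[str, int] = {}
        for v in variants:
            if v.chrom in by_chrom and v.pos <= by_chrom[v.chrom]:
                raise ValueError("variant list is not position-sorted")
            by_chrom[v.chrom] = v.pos
    index = {v.key: i for i, v in enumerate(model_variants)}
    mapping: dict[int, int] = {}
    dropped = 0
    for i, v in enumerate(observed_variants):
        j = index.get(v.key)
        if j is None:
            dropped += 1
        else:
            mapping[i] = j
    return MatchReport(mapping, len(mapping), dropped)


def impute(
    observed_panel: GenotypePanel,
    store: ModelStore,
) -> tuple[np.ndarray, np.ndarray, MatchReport]:
    """Impute all model variants from the observed panel.

    Returns (probs, observed_mask, match_report): ``probs`` is
    (n_samples, n_model_variants, 3) with rows summing to 1; ``observed_mask``
    flags model variants that were genotyped in the input (these pass
    through as hard one-hot probabilities).
    """
    report = match_variants(observed_panel.variants, store.variants)
    n = observed_panel.n_samples
    m = len(store.variants)
    # genotype matrix on the model's variant axis, missing everywhere else
    geno = np.full((n, m), MISSING, dtype=np.int8)
    for i, j in report.mapping.items():
        geno[:, j] = observed_panel.genotypes[:, i]
    x = encode_genotypes(geno)

    prob_sum = np.zeros((n, m, 3))
    cover = np.zeros(m, dtype=int)
    for seg in store.segments:
        lo, hi = seg.variant_range
        model = store.model_for(seg)
        out = model.forward(x[:, 2 * lo : 2 * hi])
        p_ref, p_alt = out[:, 0::2], out[:, 1::2]
        probs = allele_outputs_to_probabilities(
            np.clip(p_ref, 0, 1), np.clip(p_alt, 0, 1)
        )
        prob_sum[:, lo:hi] += probs
        cover[lo:hi] += 1
    if (cover == 0).any():
        raise ValueError("model segments do not cover every variant")
    probs = prob_sum / cover[None, :, None]
    probs /= probs.sum(axis=-1, keepdims=True)

    # observed genotypes pass through unchanged; a variant counts as
    # observed only if some sample carries an actual call there (input VCFs
    # may list all model sites with missing genotypes at untyped ones)
    observed_mask = np.zeros(m, dtype=bool)
    for i, j in report.mapping.items():
        if (observed_panel.genotypes[:, i] != MISSING).any():
            observed_mask[j] = True
    for state, onehot in ((0, (1, 0, 0)), (1, (0, 1, 0)), (2, (0, 0, 1))):
        sel = (geno == state) & observed_mask[None, :]
        probs[sel] = onehot
    return probs, observed_mask, report
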