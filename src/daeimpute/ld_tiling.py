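"""Genome tiling at recombination hotspots via windowed LD box counts.

A chromosome is split into approximately independent genomic segments by:
(1) computing pairwise Pearson correlations of alt-allele dosage between
common SNPs within a fixed sliding window, keeping pairs with |r| above a
threshold; (2) counting, for every common SNP, the retained pairs whose two
members both lie within the window centered on it (a moving "box count" of
local LD strength); (3) splitting at local minima of the smoothed box-count
curve — recombination hotspots — into high-LD cores flanked by the weak-LD
hotspot shoulders shared with neighboring segments; (4) further splitting any
segment above a maximum SNP count, first at internal count minima, then into
fixed overlapping windows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotype_io import GenotypePanel

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class TilingConfig:
    corr_threshold: float = 0.45
    box_halfwidth: int = 500
    maf_min: float = 0.005
    max_segment_snps: int = 6000
    split_overlap_snps: int = 2500
    smooth_width: int = 11  # centered moving average before minima search
    flank_count_fraction: float = 0.10  # weak-LD: counts below this x core peak

    def __post_init__(self) -> None:
        if not 0 < self.corr_threshold < 1:
            raise ValueError("corr_threshold must be in (0, 1)")
        if self.split_overlap_snps >= self.max_segment_snps:
            raise ValueError("split_overlap_snps must be < max_segment_snps")


@dataclasses.dataclass
class GenomicSegment:
    """One tiling unit: a half-open variant-index range into the full panel.

    ``core_range`` is the high-LD core (disjoint between segments);
    ``variant_range`` adds the weak-LD flanks shared with neighbors.
    Ranges are 0-based half-open over the panel's full variant list
    (common and rare variants alike).
    """

    segment_id: int
    variant_range: tuple[int, int]
    core_range: tuple[int, int]
    origin: str = "independent"  # independent | internal_split | size_split

    @property
    def n_variants(self) -> int:
        return self.variant_range[1] - self.variant_range[0]

    def indices(self) -> np.ndarray:
        return np.arange(*self.variant_range)


def common_variant_indices(panel: GenotypePanel, cfg: TilingConfig) -> np.ndarray:
    maf = panel.maf()
    with np.errstate(invalid="ignore"):
        return np.flatnonzero(maf >= cfg.maf_min)


def windowed_thresholded_correlation(
    panel: GenotypePanel, cfg: TilingConfig | None = None
) -> list[tuple[int, int, float]]:
    """Thresholded pairwise dosage correlations within the sliding window.

    Returns (i, j, r) for common-variant index pairs i < j (indices into the
    common-variant list) with |i-j| <= box_halfwidth and |r| >= corr_threshold.
    Pearson r is computed on samples non-missing at both sites; zero-variance
    variants never pair.
    """
    cfg = cfg or TilingConfig()
    common = common_variant_indices(panel, cfg)
    dos = panel.alt_dosage()[:, common]  # NaN at missing
    m = dos.shape[1]
    pairs: list[tuple[int, int, float]] = []
    n_degenerate = 0
    for i in range(m):
        hi = min(m, i + cfg.box_halfwidth + 1)
        for j in range(i + 1, hi):
            ok = ~np.isnan(dos[:, i]) & ~np.isnan(dos[:, j])
            if ok.sum() < 2:
                continue
            a, b = dos[ok, i], dos[ok, j]
            if a.std() == 0 or b.std() == 0:
                n_degenerate += 1
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if abs(r) >= cfg.corr_threshold:
                pairs.append((i, j, r))
    if n_degenerate:
        logger.info("excluded %d zero-variance pairings", n_degenerate)
    return pairs


def box_counts(
    pairs: Sequence[tuple[int, int, float]],
    n_common_variants: int,
    cfg: TilingConfig | None = None,
) -> np.ndarray:
    """count[k] = retained pairs (i, j) with both ends within the window at k."""
    cfg = cfg or TilingConfig()
    counts = np.zeros(n_common_variants, dtype=np.int64)
    if not pairs:
        return counts
    arr = np.asarray([(i, j) for i, j, _ in pairs], dtype=np.int64)
    lo_k = np.maximum(arr[:, 1] - cfg.box_halfwidth, 0)
    hi_k = np.minimum(arr[:, 0] + cfg.box_halfwidth, n_common_variants - 1)
    # range-increment via difference array
    diff = np.zeros(n_common_variants + 1, dtype=np.int64)
    valid = lo_k <= hi_k
    np.add.at(diff, lo_k[valid], 1)
    np.add.at(diff, hi_k[valid] + 1, -1)
    counts = np.cumsum(diff[:-1])
    return counts


def _smooth(counts: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or counts.size < width:
        return counts.astype(float)
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(counts.astype(float), pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def _local_minima(y: np.ndarray) -> list[int]:
    """Strict local minima; interior plateaus collapse to their midpoint."""
    minima: list[int] = []
    n = y.size
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        # plateau [i, j]; interior minimum if both shoulders rise
        if i > 0 and j < n - 1 and y[i - 1] > y[i] and y[j + 1] > y[j]:
            minima.append((i + j) // 2)
        i = j + 1
    return minima


def segment_boundaries(
    counts: np.ndarray,
    common_idx: np.ndarray,
    n_total_variants: int,
    cfg: TilingConfig | None = None,
) -> list[GenomicSegment]:
    """Split at box-count local minima into cores plus weak-LD flanks.

    ``counts`` is indexed over the common-variant list; ``common_idx`` maps
    that list back into the full variant list.  Rare variants are assigned to
    the segment of the nearest common variant, which the half-open full-index
    ranges below realize by splitting at midpoints between the bounding
    common variants.
    """
    cfg = cfg or TilingConfig()
    m = counts.size
    if m < 3:
        return [GenomicSegment(0, (0, n_total_variants), (0, n_total_variants))]
    smoothed = _smooth(np.asarray(counts), cfg.smooth_width)
    minima = _local_minima(smoothed)
    # cores in common-index space: regions between consecutive minima
    bounds = [0] + [k for k in minima] + [m - 1]
    cores: list[tuple[int, int]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        cores.append((a, b))
    if not minima:
        return [GenomicSegment(0, (0, n_total_variants), (0, n_total_variants))]

    # flank extent around each hotspot minimum: spread while counts stay
    # below flank_count_fraction of the adjacent core's peak
    def flank_extent(center: int, direction: int, peak: float) -> int:
        lim = cfg.flank_count_fraction * peak
        k = center
        while 0 <= k + direction < m and smoothed[k + direction] <= lim:
            k += direction
        return k

    segments: list[GenomicSegment] = []

    def to_full(lo_c: int, hi_c: int, clip_lo: bool, clip_hi: bool) -> tuple[int, int]:
        # common-space inclusive [lo_c, hi_c] -> full-space half-open range,
        # splitting rare variants at midpoints between bounding common SNPs
        if clip_lo:
            lo_f = 0
        else:
            lo_f = (common_idx[lo_c - 1] + common_idx[lo_c]) // 2 + 1
        if clip_hi:
            hi_f = n_total_variants
        else:
            hi_f = (common_idx[hi_c] + common_idx[hi_c + 1]) // 2 + 1
        return int(lo_f), int(hi_f)

    for s, (a, b) in enumerate(cores):
        core_lo, core_hi = (a if s == 0 else a + 1), b
        peak = float(smoothed[core_lo : core_hi + 1].max()) if core_hi >= core_lo else 0.0
        lo = a if s == 0 else flank_extent(a, -1, peak)
        hi = b if s == len(cores) - 1 else flank_extent(b, +1, peak)
        full_range = to_full(lo, hi, lo == 0, hi == m - 1)
        full_core = to_full(core_lo, core_hi, core_lo == 0, core_hi == m - 1)
        segments.append(GenomicSegment(s, full_range, full_core))
    return segments


def enforce_max_size(
    segments: list[GenomicSegment],
    counts: np.ndarray,
    common_idx: np.ndarray,
    cfg: TilingConfig | None = None,
) -> list[GenomicSegment]:
    """Split oversize segments: first at internal count minima, then into
    fixed max-size windows advancing by (max_size - overlap)."""
    cfg = cfg or TilingConfig()
    full_to_common = {int(f): c for c, f in enumerate(common_idx)}
    smoothed = _smooth(np.asarray(counts), cfg.smooth_width)
    out: list[GenomicSegment] = []
    for seg in segments:
        if seg.n_variants <= cfg.max_segment_snps:
            out.append(seg)
            continue
        pieces = _split_at_internal_minima(seg, smoothed, common_idx, full_to_common, cfg)
        for piece in pieces:
            if piece.n_variants <= cfg.max_segment_snps:
                out.append(piece)
            else:
                out.extend(_fixed_windows(piece, cfg))
    for i, seg in enumerate(out):
        seg.segment_id = i
    return out


def _split_at_internal_minima(seg, smoothed, common_idx, full_to_common, cfg):
    lo, hi = seg.variant_range
    inside = [full_to_common[f] for f in range(lo, hi) if f in full_to_common]
    if len(inside) < 3:
        return [seg]
    sub = smoothed[inside[0] : inside[-1] + 1]
    minima = _local_minima(sub)
    if not minima:
        return [seg]
    # deepest minima first, take as many as needed to bring pieces under size
    minima.sort(key=lambda k: sub[k])
    cuts: list[int] = []
    for k in minima:
        cut_full = int(common_idx[inside[0] + k])
        cuts_try = sorted(cuts + [cut_full])
        edges = [lo] + cuts_try + [hi]
        if max(b - a for a, b in zip(edges[:-1], edges[1:])) <= cfg.max_segment_snps:
            cuts = cuts_try
            break
        cuts = cuts_try
    edges = [lo] + sorted(cuts) + [hi]
    pieces = []
    for a, b in zip(edges[:-1], edges[1:]):
        pieces.append(GenomicSegment(0, (a, b), (a, b), origin="internal_split"))
    return pieces


def _fixed_windows(seg: GenomicSegment, cfg: TilingConfig) -> list[GenomicSegment]:
    lo, hi = seg.variant_range
    stride = cfg.max_segment_snps - cfg.split_overlap_snps
    out = []
    start = lo
    while True:
        end = start + cfg.max_segment_snps
        if end >= hi:
            out.append(
                GenomicSegment(
                    0, (max(lo, hi - cfg.max_segment_snps), hi),
                    (max(lo, hi - cfg.max_segment_snps), hi), origin="size_split",
                )
            )
            break
        out.append(GenomicSegment(0, (start, end), (start, end), origin="size_split"))
        start += stride
    return out


def tile_panel(
    panel: GenotypePanel, cfg: TilingConfig | None = None
) -> list[GenomicSegment]:
    """Full tiling pipeline: correlations -> box counts -> split -> size cap."""
    cfg = cfg or TilingConfig()
    common = common_variant_indices(panel, cfg)
    pairs = windowed_thresholded_correlation(panel, cfg)
    counts = box_counts(pairs, common.size, cfg)
    segments = segment_boundaries(counts, common, panel.n_variants, cfg)
    return enforce_max_size(segments, counts, common, cfg)


def write_segments(
    segments: Sequence[GenomicSegment],
    panel: GenotypePanel,
    bed_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Emit segments as BED (0-based half-open bp) plus a JSON sidecar with
    variant-index ranges, core ranges, and origin tags."""
    with open(bed_path, "w") as fh:
        for seg in segments:
            lo, hi = seg.variant_range
            chrom = panel.variants[lo].chrom
            start = panel.variants[lo].pos - 1
            end = panel.variants[hi - 1].pos
            fh.write(f"{chrom}\t{start}\t{end}\tsegment_{seg.segment_id}\n")
    if json_path is not None:
        meta = [
            {
                "segment_id": seg.segment_id,
                "variant_range": list(seg.variant_range),
                "core_range": list(seg.core_range),
                "origin": seg.origin,
            }
            for seg in segments
        ]
        Path(json_path).write_text(json.dumps(meta, indent=1))


def read_segments(json_path: str | Path) -> list[GenomicSegment]:
    """Load segments from the JSON sidecar (a .bed path is redirected to
    its sidecar)."""
    json_path = Path(json_path)
    if json_path.suffix == ".bed":
        json_path = json_path.with_suffix(".json")
    meta = json.loads(json_path.read_text())
    return [
        GenomicSegment(
            m["segment_id"],
            tuple(m["variant_range"]),
            tuple(m["core_range"]),
            m["origin"],
        )
        for m in meta
    ]
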