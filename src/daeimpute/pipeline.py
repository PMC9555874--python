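"""End-to-end pipeline driver: panel -> tile -> (grid search) -> train ->
impute -> evaluate, with every artifact written to disk and a manifest
recording seeds, config hash, and stage outputs."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .evaluation import evaluate_imputation
from .genotype_io import dosage, hard_calls, read_vcf, write_vcf
from .hyperopt import extract_features, sample_grid
from .inference import ModelStore, impute
from .ld_tiling import tile_panel, write_segments
from .synthetic import array_mask, generate_panel
from .training import TrainingSchedule, train_segment

logger = logging.getLogger(__name__)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    # ---- panel
    if config.panel.vcf:
        panel = read_vcf(config.panel.vcf)
        truth_meta = None
    else:
        panel, truth_meta = generate_panel(
            config.panel.n_haplotypes,
            config.block_specs(),
            hotspot_gap_variants=config.panel.hotspot_gap_variants,
            rng=config.substream("panel"),
        )
    write_vcf(out / "panel.vcf", panel.sample_ids, panel.variants,
              genotypes=panel.genotypes)
    manifest["stages"]["panel"] = {
        "n_samples": panel.n_samples, "n_variants": panel.n_variants,
        "path": "panel.vcf",
    }

    # train/test sample split
    rng_split = config.substream("split")
    n_test = max(1, int(round(config.panel.test_fraction * panel.n_samples)))
    order = rng_split.permutation(panel.n_samples)
    test_idx, train_idx = order[:n_test], order[n_test:]
    train_panel = panel.subset_samples(train_idx)
    test_panel = panel.subset_samples(test_idx)

    # ---- tiling
    segments = tile_panel(train_panel, config.tiling)
    write_segments(segments, panel, out / "segments.bed", out / "segments.json")
    manifest["stages"]["tile"] = {
        "n_segments": len(segments),
        "paths": ["segments.bed", "segments.json"],
    }

    # ---- optional per-segment coarse grid search
    specs = {seg.segment_id: config.spec for seg in segments}
    if config.grid.n_combinations > 0:
        grid_specs = sample_grid(
            config.grid.n_combinations, config.substream("grid")
        )
        grid_schedule = TrainingSchedule(
            epochs_per_cycle=config.grid.epochs_per_cycle,
            max_epochs=config.grid.max_epochs,
            batch_size=config.training.batch_size,
            seed=config.seed,
        )
        for seg in segments:
            best, best_r2 = config.spec, -np.inf
            for cand in grid_specs:
                try:
                    res = train_segment(train_panel, seg, cand, grid_schedule)
                except FloatingPointError:
                    continue
                r2 = -res.cycle_losses[-1]  # screen by final loss
                if r2 > best_r2:
                    best, best_r2 = cand, r2
            specs[seg.segment_id] = best
        manifest["stages"]["grid_search"] = {
            "n_combinations": config.grid.n_combinations
        }

    # ---- training
    store = ModelStore.create(out / "models", panel.variants)
    traces = {}
    for seg in segments:
        result = train_segment(
            train_panel, seg, specs[seg.segment_id], config.training
        )
        store.add_segment(seg, result.model)
        traces[seg.segment_id] = {
            "cycle_losses": result.cycle_losses,
            "cycle_rates": result.cycle_rates,
            "stopped_early": result.stopped_early,
        }
    store.write_manifest({"seed": config.seed})
    (out / "loss_traces.json").write_text(json.dumps(traces, indent=1, sort_keys=True))
    manifest["stages"]["train"] = {
        "n_models": len(segments), "path": "models",
    }

    # ---- array masking + imputation on held-out samples
    observed_panel, observed_idx = array_mask(
        test_panel,
        observed_fraction=config.panel.observed_fraction,
        rng=config.substream("mask"),
    )
    probs, observed_mask, match = impute(observed_panel, store)
    write_vcf(
        out / "imputed.vcf", test_panel.sample_ids, panel.variants,
        probs=probs, imputed_mask=~observed_mask,
    )
    manifest["stages"]["impute"] = {
        "n_observed_variants": int(observed_mask.sum()),
        "n_matched": match.n_matched,
        "path": "imputed.vcf",
    }

    # ---- evaluation against the held-out truth
    maf = train_panel.maf()
    report = evaluate_imputation(
        dosage(probs), hard_calls(probs), test_panel.genotypes,
        np.nan_to_num(maf, nan=0.0),
        [f"{v.chrom}:{v.pos}" for v in panel.variants],
    )
    report.per_variant.to_csv(out / "report.tsv", sep="\t", index=False)
    summary = {
        "mean_r2": report.mean_r2,
        "n_undefined_r2": report.n_undefined_r2,
        "per_bin_mean_r2": report.per_bin_mean_r2,
        "concordance": report.concordance,
        "macro_f1": report.macro_f1,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest["stages"]["evaluate"] = {
        "paths": ["report.tsv", "summary.json"], **summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
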