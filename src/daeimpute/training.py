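"""Denoising-autoencoder training with an escalating masking curriculum.

Training proceeds in masking/training cycles.  Each cycle masks a fixed
fraction of input variants per sample (set to the null encoding (0,0)) and
runs a fixed number of epochs; the masking rate escalates linearly from an
initial 80% of variants up to the rate that leaves only ``min_unmasked``
variants observed.  The learning rate is multiplied by the decay ratio every
500 epochs.  Training stops early once a cycle's mean total loss fails to
improve on the previous cycle's.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .autoencoder import Autoencoder, AutoencoderSpec, Optimizer, build_autoencoder
from .genotype_io import GenotypePanel, encode_genotypes
from .ld_tiling import GenomicSegment

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class TrainingSchedule:
    initial_mask_rate: float = 0.80
    min_unmasked: int = 5
    epochs_per_cycle: int = 500
    max_epochs: int = 35000
    batch_size: int = 256
    seed: int = 0
    lr_decay_every: int = 500  # epochs between learning-rate decay steps
    escalation: str = "linear"  # or "geometric"

    def __post_init__(self) -> None:
        if not 0 < self.initial_mask_rate < 1:
            raise ValueError("initial_mask_rate must be in (0, 1)")
        if self.min_unmasked < 1:
            raise ValueError("min_unmasked must be >= 1")
        if self.max_epochs % self.epochs_per_cycle != 0:
            raise ValueError("epochs_per_cycle must divide max_epochs")

    @property
    def n_cycles(self) -> int:
        return self.max_epochs // self.epochs_per_cycle


def masking_schedule(n_variants: int, schedule: TrainingSchedule) -> list[float]:
    """Per-cycle masking rates, escalating from the initial rate to the rate
    leaving ``min_unmasked`` variants observed."""
    if n_variants <= schedule.min_unmasked:
        raise ValueError(
            f"n_variants={n_variants} must exceed min_unmasked={schedule.min_unmasked}"
        )
    final = (n_variants - schedule.min_unmasked) / n_variants
    n = schedule.n_cycles
    if n == 1:
        return [schedule.initial_mask_rate]
    if schedule.escalation == "geometric":
        ratio = (final / schedule.initial_mask_rate) ** (1.0 / (n - 1))
        rates = [schedule.initial_mask_rate * ratio**k for k in range(n)]
    else:
        rates = list(np.linspace(schedule.initial_mask_rate, final, n))
    return [min(r, final) for r in rates]


def apply_mask(
    x: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Mask a fresh uniform-random subset of ceil(rate * n_variants) variants
    per sample to the null encoding (0, 0).  Returns a copy."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    out = np.array(x, copy=True)
    n, two_m = out.shape
    m = two_m // 2
    k = math.ceil(rate * m)
    if k == 0:
        return out
    # per-sample uniform subset without replacement, vectorized: the k
    # smallest of m iid uniforms per row are a uniform k-subset
    keys = rng.random((n, m))
    cols = np.argpartition(keys, k - 1, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    flat = cols.ravel()
    out[rows, 2 * flat] = 0.0
    out[rows, 2 * flat + 1] = 0.0
    return out


@dataclasses.dataclass
class TrainingResult:
    model: Autoencoder
    cycle_losses: list[float]  # mean total loss per completed cycle
    cycle_rates: list[float]
    stopped_early: bool


def train_segment(
    panel: GenotypePanel,
    segment: GenomicSegment,
    spec: AutoencoderSpec,
    schedule: TrainingSchedule,
) -> TrainingResult:
    """Train one segment's autoencoder under the masking curriculum.

    Masks are re-drawn per batch and per sample; the loss is computed against
    the uncorrupted truth encoding over all output nodes.  Optimizer state
    persists across cycles; early stop fires when a cycle's mean total loss
    is not strictly below the previous cycle's.
    """
    sub = panel.subset_variants(segment.indices())
    truth = encode_genotypes(sub.genotypes)
    n_samples, m = sub.n_samples, sub.n_variants
    rng = np.random.default_rng(schedule.seed)
    model = build_autoencoder(spec, m, seed=int(rng.integers(2**31)))
    opt = Optimizer(model, spec.learning_rate, spec.optimizer)
    rates = masking_schedule(m, schedule)
    cycle_losses: list[float] = []
    stopped = False
    epoch = 0
    for cycle, rate in enumerate(rates):
        batch_losses: list[float] = []
        for _ in range(schedule.epochs_per_cycle):
            order = rng.permutation(n_samples)
            for start in range(0, n_samples, schedule.batch_size):
                idx = order[start : start + schedule.batch_size]
                xb = apply_mask(truth[idx], rate, rng)
                terms, gW, gb = model.loss_and_gradients(xb, truth[idx])
                if not np.isfinite(terms.total):
                    raise FloatingPointError(
                        f"non-finite loss {terms.total} at cycle {cycle} "
                        f"epoch {epoch} (lr={opt.lr:g})"
                    )
                opt.step(gW, gb)
                batch_losses.append(terms.total)
            epoch += 1
            if epoch % schedule.lr_decay_every == 0:
                opt.lr *= spec.lr_decay
        mean_loss = float(np.mean(batch_losses))
        cycle_losses.append(mean_loss)
        logger.info(
            "segment %s cycle %d rate %.3f mean loss %.6f",
            segment.segment_id, cycle, rate, mean_loss,
        )
        if cycle > 0 and mean_loss >= cycle_losses[-2]:
            stopped = True
            break
    return TrainingResult(model, cycle_losses, rates[: len(cycle_losses)], stopped)
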