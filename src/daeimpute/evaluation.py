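"""Imputation accuracy metrics: dosage r-squared, concordance, macro-F1,
MAF stratification, and paired method comparisons.

The primary accuracy measure is the squared Pearson correlation between
imputed and true alternative-allele dosages, computed per variant across
samples and averaged within minor-allele-frequency bins, genomic segments,
or whole chromosomes.  Concordance (exact hard-call agreement) and a
macro-averaged F1 over the three genotype classes complement it.  Method
comparisons use per-segment win counts, a two-sided Wilcoxon rank-sum test,
and a two-proportion z-test on win fractions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score

MAF_BIN_EDGES = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
ULTRA_RARE = "ultra-rare"


def per_variant_r2(imputed_dosages: np.ndarray, truth_dosages: np.ndarray) -> float:
    """Squared Pearson correlation of dosage vectors across samples.

    Returns NaN (undefined) when either vector has zero variance; callers
    exclude undefined values from averages but count them.
    """
    a = np.asarray(imputed_dosages, dtype=float)
    b = np.asarray(truth_dosages, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("dosage vectors must be 1-D and of equal length")
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def maf_bin(maf: float) -> str:
    """Bin label for a minor allele frequency.

    Bins are half-open [lo, hi) over the published edges, with the last bin
    closed at 0.5; MAF below 0.001 is reported separately as "ultra-rare".
    """
    if not 0 <= maf <= 0.5:
        raise ValueError(f"MAF {maf} outside [0, 0.5]")
    if maf < MAF_BIN_EDGES[0]:
        return ULTRA_RARE
    for lo, hi in zip(MAF_BIN_EDGES[:-1], MAF_BIN_EDGES[1:]):
        if lo <= maf < hi or (hi == MAF_BIN_EDGES[-1] and maf == hi):
            return f"{lo}-{hi}"
    raise AssertionError("unreachable")  # pragma: no cover


def concordance_and_f1(
    imputed_genotypes: np.ndarray, truth_genotypes: np.ndarray
) -> tuple[float, float]:
    """Exact-agreement fraction and macro-F1 over {hom-ref, het, hom-alt}.

    Truth entries coded missing (-1) are excluded; returns (NaN, NaN) when
    no truth call remains.
    """
    pred = np.asarray(imputed_genotypes).ravel()
    truth = np.asarray(truth_genotypes).ravel()
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    ok = truth >= 0
    if not ok.any():
        return float("nan"), float("nan")
    pred, truth = pred[ok], truth[ok]
    conc = float((pred == truth).mean())
    f1 = float(
        f1_score(truth, pred, labels=[0, 1, 2], average="macro", zero_division=0)
    )
    return conc, f1


def compare_methods(
    per_segment_metric_a: np.ndarray, per_segment_metric_b: np.ndarray
) -> tuple[int, int, float, float]:
    """Paired per-segment comparison of two methods.

    Returns (n_wins_a, n_wins_b, rank_sum_p, two_proportion_p): win counts
    by sign of the per-segment difference (ties dropped), the two-sided
    Wilcoxon rank-sum p-value on the two metric samples, and a two-sided
    two-proportion z-test on the win fractions.
    """
    a = np.asarray(per_segment_metric_a, dtype=float)
    b = np.asarray(per_segment_metric_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired segments")
    diff = a - b
    wins_a = int((diff > 0).sum())
    wins_b = int((diff < 0).sum())
    rank_p = float(stats.ranksums(a, b).pvalue)
    n = wins_a + wins_b
    if n == 0:
        prop_p = 1.0
    else:
        from statsmodels.stats.proportion import proportions_ztest

        _, prop_p = proportions_ztest([wins_a, wins_b], [n, n])
        prop_p = float(prop_p)
    return wins_a, wins_b, rank_p, prop_p


@dataclasses.dataclass
class AccuracyReport:
    per_variant: pd.DataFrame  # variant, maf, bin, r2, concordance, f1
    mean_r2: float
    n_undefined_r2: int
    per_bin_mean_r2: dict[str, float]
    concordance: float
    macro_f1: float


def evaluate_imputation(
    imputed_dosages: np.ndarray,
    imputed_calls: np.ndarray,
    truth_genotypes: np.ndarray,
    maf: np.ndarray,
    variant_labels: list[str] | None = None,
) -> AccuracyReport:
    """Per-variant and aggregate accuracy of imputed vs truth genotypes.

    ``imputed_dosages`` and ``imputed_calls`` are (n_samples, n_variants);
    ``truth_genotypes`` are hard states with -1 for missing; ``maf`` is the
    ground-truth panel's per-variant minor allele frequency.
    """
    n, m = truth_genotypes.shape
    truth_dos = truth_genotypes.astype(float)
    truth_dos[truth_genotypes < 0] = np.nan
    rows = []
    for j in range(m):
        r2 = per_variant_r2(imputed_dosages[:, j], truth_dos[:, j])
        conc, f1 = concordance_and_f1(imputed_calls[:, j], truth_genotypes[:, j])
        rows.append(
            {
                "variant": variant_labels[j] if variant_labels else str(j),
                "maf": float(maf[j]),
                "bin": maf_bin(float(min(maf[j], 0.5))),
                "r2": r2,
                "concordance": conc,
                "f1": f1,
            }
        )
    df = pd.DataFrame(rows)
    defined = df["r2"].notna()
    mean_r2 = float(df.loc[defined, "r2"].mean()) if defined.any() else float("nan")
    per_bin = {
        b: float(g.loc[g["r2"].notna(), "r2"].mean())
        for b, g in df.groupby("bin")
        if g["r2"].notna().any()
    }
    conc, f1 = concordance_and_f1(imputed_calls, truth_genotypes)
    return AccuracyReport(
        per_variant=df,
        mean_r2=mean_r2,
        n_undefined_r2=int((~defined).sum()),
        per_bin_mean_r2=per_bin,
        concordance=conc,
        macro_f1=f1,
    )
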