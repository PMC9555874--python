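"""Coarse random grid search and meta-model-guided hyperparameter selection.

The coarse grid draws random hyperparameter combinations from the published
value lists; each combination trained briefly per segment yields a validation
dosage r-squared.  A gradient-boosted regression model (XGBoost) then maps
(hyperparameters, segment LD-complexity features) to expected r-squared, so
that a large candidate pool can be ranked without training, and the top 10
predicted candidates per segment (plus the best observed combination)
advance to fine tuning.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .autoencoder import AutoencoderSpec
from .evaluation import MAF_BIN_EDGES
from .genotype_io import GenotypePanel
from .ld_tiling import GenomicSegment

# coarse-grid value lists for each hyperparameter
COARSE_GRID: dict[str, list] = {
    "lambda1": [1e-3, 1e-4, 1e-5, 1e-6, 1e-1, 1e-2, 1e-7, 1e-8],
    "lambda2": [1e-3, 1e-4, 1e-5, 1e-6, 1e-1, 1e-2, 1e-7, 1e-8],
    "beta": [0, 0.001, 0.01, 0.05, 1, 5, 10],
    "rho": [0.001, 0.004, 0.007, 0.01, 0.04, 0.07, 0.1, 0.4, 0.7, 1.0],
    "activation": ["sigmoid", "tanh", "relu", "softplus"],
    "learning_rate": [1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1, 10, 100],
    "gamma": [0, 0.5, 1, 2, 3, 5],
    "optimizer": ["adam", "rmsprop", "sgd"],
    "loss_type": ["cross_entropy", "focal"],
    "n_hidden_layers": [1, 2, 4, 6, 8],
    "size_ratio": [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1],
    "lr_decay": [0.0, 0.25, 0.5, 0.75, 0.95, 0.99, 0.999, 0.9999],
}

_CATEGORICAL = ("activation", "optimizer", "loss_type")


def grid_size() -> int:
    n = 1
    for vals in COARSE_GRID.values():
        n *= len(vals)
    return n


def _spec_from_values(values: dict) -> AutoencoderSpec:
    return AutoencoderSpec(**values)


def sample_grid(
    n_combinations: int, rng: np.random.Generator | int = 0
) -> list[AutoencoderSpec]:
    """Draw distinct random hyperparameter combinations from the grid."""
    if n_combinations < 1:
        raise ValueError("n_combinations must be >= 1")
    if n_combinations > grid_size():
        raise ValueError(
            f"requested {n_combinations} combinations but the grid has "
            f"only {grid_size()} distinct points"
        )
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    keys = list(COARSE_GRID)
    seen: set[tuple] = set()
    out: list[AutoencoderSpec] = []
    while len(out) < n_combinations:
        combo = tuple(
            COARSE_GRID[k][rng.integers(len(COARSE_GRID[k]))] for k in keys
        )
        if combo in seen:
            continue
        seen.add(combo)
        out.append(_spec_from_values(dict(zip(keys, combo))))
    return out


@dataclasses.dataclass
class SegmentFeatures:
    """LD-complexity descriptors of one genomic segment."""

    n_variants: int
    mean_recombination_rate: float  # cM/Mb over the segment span (0 if no map)
    mean_pairwise_correlation: float
    maf_bin_proportions: dict[str, float]
    n_pcs_for_90pct_variance: int
    var_explained_first2_pcs: float
    n_unique_haplotypes: int
    n_unique_diplotypes: int
    mean_heterozygosity: float

    def to_row(self) -> dict[str, float]:
        row = dataclasses.asdict(self)
        props = row.pop("maf_bin_proportions")
        for k, v in props.items():
            row[f"maf_prop_{k}"] = v
        return row


def extract_features(
    panel: GenotypePanel,
    segment: GenomicSegment,
    genetic_map=None,
) -> SegmentFeatures:
    """Compute the meta-model features for one segment."""
    sub = panel.subset_variants(segment.indices())
    if sub.n_variants == 0:
        raise ValueError("empty segment")
    dos = np.nan_to_num(sub.alt_dosage(), nan=0.0)
    if np.all(sub.genotypes == -1):
        raise ValueError("all-missing segment")
    m = sub.n_variants
    # mean |r| over variant pairs with defined correlation
    sd = dos.std(axis=0)
    ok = sd > 0
    if ok.sum() >= 2:
        corr = np.corrcoef(dos[:, ok], rowvar=False)
        iu = np.triu_indices_from(corr, k=1)
        mean_corr = float(np.abs(corr[iu]).mean())
    else:
        mean_corr = 0.0
    # PCA on the centered dosage matrix
    centered = dos - dos.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    var = sv**2
    if var.sum() > 0:
        frac = var / var.sum()
        cum = np.cumsum(frac)
        n_pcs_90 = int(np.searchsorted(cum, 0.90) + 1)
        var_first2 = float(frac[:2].sum())
    else:
        n_pcs_90, var_first2 = 1, 1.0
    # MAF bin proportions: the 8 evaluation bins plus rare (<0.005) split
    maf = sub.maf()
    props: dict[str, float] = {"rare_lt_0.005": float(np.mean(maf < 0.005))}
    edges = MAF_BIN_EDGES
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi == edges[-1]:
            inbin = (maf >= lo) & (maf <= hi)
        else:
            inbin = (maf >= lo) & (maf < hi)
        props[f"{lo}-{hi}"] = float(np.mean(inbin))
    # haplotype/diplotype uniqueness on exact genotype-string matches; with
    # unphased data the "haplotype" proxy counts distinct allele-presence rows
    geno_rows = {tuple(row) for row in sub.genotypes}
    from .genotype_io import encode_genotypes

    hap_rows = {tuple(row) for row in encode_genotypes(sub.genotypes)}
    het = float((sub.genotypes == 1).mean())
    if genetic_map is not None:
        chrom = sub.variants[0].chrom
        lo_pos, hi_pos = sub.variants[0].pos, sub.variants[-1].pos
        if hi_pos > lo_pos:
            cm = genetic_map.cm_at(chrom, np.array([lo_pos, hi_pos]))
            rate = float((cm[1] - cm[0]) / ((hi_pos - lo_pos) / 1e6))
        else:
            rate = 0.0
    else:
        rate = 0.0
    return SegmentFeatures(
        n_variants=m,
        mean_recombination_rate=rate,
        mean_pairwise_correlation=mean_corr,
        maf_bin_proportions=props,
        n_pcs_for_90pct_variance=n_pcs_90,
        var_explained_first2_pcs=var_first2,
        n_unique_haplotypes=len(hap_rows),
        n_unique_diplotypes=len(geno_rows),
        mean_heterozygosity=het,
    )


@dataclasses.dataclass
class GridResult:
    segment_id: int
    spec: AutoencoderSpec
    validation_r2: float
    concordance: float = float("nan")
    f1: float = float("nan")


def _design_matrix(
    specs: list[AutoencoderSpec], features: list[SegmentFeatures]
) -> pd.DataFrame:
    rows = []
    for spec, feat in zip(specs, features):
        row = spec.to_dict()
        row.update(feat.to_row())
        rows.append(row)
    df = pd.DataFrame(rows)
    df = pd.get_dummies(df, columns=list(_CATEGORICAL))
    return df


@dataclasses.dataclass
class PerformancePredictor:
    model: object
    columns: list[str]
    cv_r2: float

    def predict(
        self, specs: list[AutoencoderSpec], features: list[SegmentFeatures]
    ) -> np.ndarray:
        df = _design_matrix(specs, features)
        for col in self.columns:
            if col not in df:
                df[col] = 0.0
        return np.asarray(self.model.predict(df[self.columns].astype(float).values))


def fit_performance_model(
    results: list[GridResult],
    features: dict[int, SegmentFeatures],
    n_folds: int = 10,
    seed: int = 0,
) -> PerformancePredictor:
    """Fit the gradient-boosted meta-model on coarse-grid results.

    Categorical hyperparameters are one-hot encoded; segment features are
    appended as numeric predictors.  Returns the fitted predictor plus its
    k-fold cross-validated r-squared.
    """
    from xgboost import XGBRegressor

    if len(results) < 50:
        raise ValueError("need at least 50 grid results")
    y = np.array([r.validation_r2 for r in results], dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("degenerate constant validation target")
    specs = [r.spec for r in results]
    feats = [features[r.segment_id] for r in results]
    df = _design_matrix(specs, feats)
    columns = list(df.columns)
    X = df.astype(float).values

    def make_model():
        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    preds = np.empty_like(y)
    for train_idx, test_idx in kf.split(X):
        mdl = make_model()
        mdl.fit(X[train_idx], y[train_idx])
        preds[test_idx] = mdl.predict(X[test_idx])
    ss_res = float(((y - preds) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    cv_r2 = 1.0 - ss_res / ss_tot
    final = make_model()
    final.fit(X, y)
    return PerformancePredictor(final, columns, cv_r2)


def select_candidates(
    predictor: PerformancePredictor,
    candidate_specs: list[AutoencoderSpec],
    features: SegmentFeatures,
    observed_best: AutoencoderSpec | None = None,
    top_k: int = 10,
) -> list[AutoencoderSpec]:
    """Top-k candidates by predicted r-squared, plus the best observed
    combination (deduplicated)."""
    if not candidate_specs:
        raise ValueError("candidate_specs must be non-empty")
    preds = predictor.predict(
        candidate_specs, [features] * len(candidate_specs)
    )
    order = np.argsort(-preds, kind="stable")
    selected = [candidate_specs[i] for i in order[:top_k]]
    if observed_best is not None and observed_best.to_dict() not in [
        s.to_dict() for s in selected
    ]:
        selected.append(observed_best)
    return selected


def results_table(results: list[GridResult]) -> pd.DataFrame:
    """Tab-separable ledger of grid results: segment, spec fields, metrics."""
    rows = []
    for r in results:
        row = {"segment_id": r.segment_id}
        row.update(r.spec.to_dict())
        row.update(
            validation_r2=r.validation_r2, concordance=r.concordance, f1=r.f1
        )
        rows.append(row)
    return pd.DataFrame(rows)
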