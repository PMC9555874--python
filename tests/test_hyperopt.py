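"""Grid sampling, segment features, and meta-model selection."""

import numpy as np
import pytest

import daeimpute as d
from daeimpute.hyperopt import (
    COARSE_GRID,
    GridResult,
    SegmentFeatures,
    grid_size,
)
from daeimpute.ld_tiling import GenomicSegment


class TestSampleGrid:
    def test_values_come_from_grid(self):
        specs = d.sample_grid(50, rng=0)
        for spec in specs:
            sd = spec.to_dict()
            for key, values in COARSE_GRID.items():
                assert sd[key] in values

    def test_seeded_reproducibility(self):
        a = [s.to_dict() for s in d.sample_grid(20, rng=5)]
        b = [s.to_dict() for s in d.sample_grid(20, rng=5)]
        assert a == b

    def test_distinctness(self):
        specs = d.sample_grid(100, rng=1)
        seen = {tuple(sorted(s.to_dict().items())) for s in specs}
        assert len(seen) == 100

    def test_rejects_oversized_request(self):
        with pytest.raises(ValueError):
            d.sample_grid(grid_size() + 1)


class TestExtractFeatures:
    def test_identical_samples_degenerate(self):
        row = np.array([0, 1, 2, 1, 0], dtype=np.int8)
        geno = np.tile(row, (15, 1))
        panel = d.GenotypePanel(
            [f"s{i}" for i in range(15)],
            [d.Variant("1", 10 * (i + 1), "A", "G") for i in range(5)],
            geno,
        )
        seg = GenomicSegment(0, (0, 5), (0, 5))
        f = d.extract_features(panel, seg)
        assert f.n_unique_diplotypes == 1
        assert f.n_pcs_for_90pct_variance == 1

    def test_independent_variants_low_mean_correlation(self):
        rng = np.random.default_rng(2)
        n = 2000
        geno = rng.binomial(2, 0.5, size=(n, 20)).astype(np.int8)
        panel = d.GenotypePanel(
            [f"s{i}" for i in range(n)],
            [d.Variant("1", 10 * (i + 1), "A", "G") for i in range(20)],
            geno,
        )
        f = d.extract_features(panel, GenomicSegment(0, (0, 20), (0, 20)))
        # mean |r| of independent pairs ~ E|N(0,1)|/sqrt(n); 3 SE bound
        assert f.mean_pairwise_correlation < 3.0 / np.sqrt(n)

    def test_brute_force_oracle_small_panel(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, size=(20, 30)).astype(np.int8)
        panel = d.GenotypePanel(
            [f"s{i}" for i in range(20)],
            [d.Variant("1", 10 * (i + 1), "A", "G") for i in range(30)],
            geno,
        )
        f = d.extract_features(panel, GenomicSegment(0, (0, 30), (0, 30)))
        assert f.n_variants == 30
        # brute-force uniqueness counts
        assert f.n_unique_diplotypes == len({tuple(r) for r in geno})
        # brute-force mean |r|
        corr = np.corrcoef(geno.astype(float), rowvar=False)
        iu = np.triu_indices(30, 1)
        assert f.mean_pairwise_correlation == pytest.approx(
            np.abs(corr[iu]).mean()
        )
        # brute-force PCA via eigendecomposition of the covariance
        cen = geno - geno.mean(axis=0)
        ev = np.linalg.eigvalsh(cen.T @ cen)[::-1]
        frac = ev / ev.sum()
        assert f.var_explained_first2_pcs == pytest.approx(frac[:2].sum())
        assert f.n_pcs_for_90pct_variance == int(
            np.searchsorted(np.cumsum(frac), 0.90) + 1
        )
        # heterozygosity by direct count
        assert f.mean_heterozygosity == pytest.approx((geno == 1).mean())

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        geno = rng.integers(0, 3, size=(25, 10)).astype(np.int8)
        panel = d.GenotypePanel(
            [f"s{i}" for i in range(25)],
            [d.Variant("1", 10 * (i + 1), "A", "G") for i in range(10)],
            geno,
        )
        seg = GenomicSegment(0, (0, 10), (0, 10))
        f1 = d.extract_features(panel, seg)
        f2 = d.extract_features(panel.subset_samples(rng.permutation(25)), seg)
        assert f1.mean_pairwise_correlation == pytest.approx(
            f2.mean_pairwise_correlation
        )
        assert f1.n_unique_diplotypes == f2.n_unique_diplotypes


def _features(n):
    return SegmentFeatures(
        n, 1.0, 0.5, {"rare_lt_0.005": 0.1}, 3, 0.6, 40, 80, 0.3
    )


def _true_r2(spec, n_variants):
    """Known smooth response surface over (learning rate, gamma, size)."""
    lr_term = np.exp(-((np.log10(spec.learning_rate) + 3.0) ** 2) / 8.0)
    g_term = 1.0 / (1.0 + 0.15 * spec.gamma)
    size_term = 1.0 / (1.0 + n_variants / 4000.0)
    return 0.95 * lr_term * g_term * size_term


class TestPerformanceModel:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(0)
        specs = d.sample_grid(500, rng)
        sizes = rng.integers(500, 6000, size=500)
        features = {i: _features(int(sizes[i])) for i in range(500)}
        results = [
            GridResult(i, s, _true_r2(s, int(sizes[i])))
            for i, s in enumerate(specs)
        ]
        return d.fit_performance_model(results, features, seed=0)

    def test_cv_r2_high_on_noiseless_surface(self, fitted):
        assert fitted.cv_r2 >= 0.9

    def test_predictions_in_plausible_range(self, fitted):
        specs = d.sample_grid(20, rng=2)
        preds = fitted.predict(specs, [_features(2000)] * 20)
        assert (preds > -0.2).all() and (preds < 1.2).all()

    def test_needs_enough_results(self):
        specs = d.sample_grid(10, rng=3)
        results = [GridResult(0, s, 0.5 + 0.01 * i) for i, s in enumerate(specs)]
        with pytest.raises(ValueError):
            d.fit_performance_model(results, {0: _features(100)})

    def test_constant_target_rejected(self):
        specs = d.sample_grid(60, rng=4)
        results = [GridResult(0, s, 0.5) for s in specs]
        with pytest.raises(ValueError):
            d.fit_performance_model(results, {0: _features(100)})


class TestSelectCandidates:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(1)
        specs = d.sample_grid(400, rng)
        features = {i: _features(2000) for i in range(400)}
        results = [
            GridResult(i, s, _true_r2(s, 2000)) for i, s in enumerate(specs)
        ]
        return d.fit_performance_model(results, features, seed=1)

    def test_returns_all_when_pool_small(self, fitted):
        pool = d.sample_grid(10, rng=5)
        sel = d.select_candidates(fitted, pool, _features(2000))
        assert len(sel) == 10

    def test_observed_best_appended_unless_duplicate(self, fitted):
        pool = d.sample_grid(30, rng=6)
        sel = d.select_candidates(fitted, pool, _features(2000))
        best = sel[0]
        again = d.select_candidates(
            fitted, pool, _features(2000), observed_best=best
        )
        assert len(again) == 10  # duplicate not re-added
        other = d.sample_grid(200, rng=7)[-1]
        with_other = d.select_candidates(
            fitted, pool, _features(2000), observed_best=other
        )
        assert len(with_other) == 11

    def test_ranking_matches_sort_oracle(self, fitted):
        pool = d.sample_grid(50, rng=8)
        feats = _features(2000)
        sel = d.select_candidates(fitted, pool, feats)
        preds = fitted.predict(pool, [feats] * 50)
        expected = [pool[i] for i in np.argsort(-preds, kind="stable")[:10]]
        assert [s.to_dict() for s in sel] == [s.to_dict() for s in expected]

    def test_recovers_true_top_decile(self, fitted):
        pool = d.sample_grid(2000, rng=9)
        feats = _features(2000)
        sel = d.select_candidates(fitted, pool, feats)
        truth_perf = np.array([_true_r2(s, 2000) for s in pool])
        thresh = np.quantile(truth_perf, 0.9)
        hits = sum(1 for s in sel[:10] if _true_r2(s, 2000) >= thresh)
        assert hits >= 8
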