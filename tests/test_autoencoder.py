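"""Penalized focal loss, network construction, and analytic gradients."""

import numpy as np
import pytest

import daeimpute as d
from daeimpute.autoencoder import (
    Autoencoder,
    AutoencoderSpec,
    Optimizer,
    class_frequency_alpha,
)


class TestFocalLoss:
    def test_gamma_zero_equals_bce(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, size=1000)
        x = rng.integers(0, 2, size=1000).astype(float)
        fl = d.focal_loss(p, x, alpha_t=1.0, gamma=0.0)
        bce = float(-(x * np.log(p) + (1 - x) * np.log(1 - p)).sum())
        assert abs(fl - bce) < 1e-9

    def test_perfectly_classified_zero(self):
        assert d.focal_loss(1.0, 1, alpha_t=1.0, gamma=2.0) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_worked_value(self):
        # -0.25 * (1-0.9)^2 * log(0.9), verified by hand
        assert d.focal_loss(0.9, 1, alpha_t=0.25, gamma=2.0) == pytest.approx(
            2.634e-4, rel=1e-3
        )

    def test_rejects_negative_gamma(self):
        with pytest.raises(ValueError):
            d.focal_loss(0.5, 1, gamma=-1.0)

    def test_monotone_in_p_for_each_truth(self):
        p = np.linspace(0.01, 0.99, 50)
        loss_x1 = [d.focal_loss(v, 1, 1.0, 2.0) for v in p]
        loss_x0 = [d.focal_loss(v, 0, 1.0, 2.0) for v in p]
        assert (np.diff(loss_x1) <= 1e-12).all()  # non-increasing for x=1
        assert (np.diff(loss_x0) >= -1e-12).all()  # non-decreasing for x=0

    def test_gamma_never_increases_well_classified_loss(self):
        for p, x in ((0.9, 1), (0.1, 0), (0.6, 1)):
            losses = [d.focal_loss(p, x, 1.0, g) for g in (0, 0.5, 1, 2, 3, 5)]
            assert (np.diff(losses) <= 1e-12).all()


class TestSparsityPenalty:
    def test_zero_iff_equal(self):
        assert d.sparsity_penalty(0.1, 0.1) == pytest.approx(0.0, abs=1e-9)

    def test_worked_value(self):
        # 0.1*log(0.5) + 0.9*log(0.9/0.8), verified by hand
        assert d.sparsity_penalty(0.1, 0.2) == pytest.approx(0.0367, abs=1e-4)

    def test_non_negative(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            rho = rng.uniform(0.01, 0.99)
            rho_hat = rng.uniform(0.01, 0.99, size=rng.integers(1, 5))
            assert d.sparsity_penalty(rho, rho_hat) >= 0

    def test_sums_over_batches(self):
        single = d.sparsity_penalty(0.1, 0.3)
        assert d.sparsity_penalty(0.1, [0.3, 0.3]) == pytest.approx(2 * single)

    def test_rejects_rho_outside_open_interval(self):
        with pytest.raises(ValueError):
            d.sparsity_penalty(0.0, 0.5)


class TestTotalLoss:
    def _setup(self, **kw):
        spec = AutoencoderSpec(activation="sigmoid", **kw)
        net = Autoencoder(spec, 4, seed=0)
        rng = np.random.default_rng(2)
        x = (rng.random((6, 8)) > 0.5).astype(float)
        t = (rng.random((6, 8)) > 0.5).astype(float)
        acts, _ = net._forward_full(x)
        return net, acts, t

    def test_penalties_off_total_equals_focal(self):
        net, acts, t = self._setup(lambda1=0.0, lambda2=0.0, beta=0.0)
        terms = net.loss_terms(acts[-1], t, hidden_acts=acts[1:-1])
        assert terms.total == pytest.approx(terms.focal)

    def test_assembly_identity(self):
        net, acts, t = self._setup(lambda1=1e-3, lambda2=1e-2, beta=0.5, rho=0.05)
        terms = net.loss_terms(acts[-1], t, hidden_acts=acts[1:-1])
        expected = (
            terms.focal
            + net.spec.beta * terms.sparsity
            + net.spec.lambda1 * terms.l1
            + net.spec.lambda2 * terms.l2
        )
        assert abs(terms.total - expected) < 1e-9

    def test_l2_is_sum_of_squares(self):
        net, acts, t = self._setup(lambda1=0.0, lambda2=0.1, beta=0.0)
        terms = net.loss_terms(acts[-1], t, hidden_acts=acts[1:-1])
        for W in net.weights:
            W *= 2.0
        terms2 = net.loss_terms(acts[-1], t, hidden_acts=acts[1:-1])
        # outputs held fixed: the L2 part scales by 4
        assert terms2.l2 == pytest.approx(4 * terms.l2)
        assert terms2.total - terms2.focal == pytest.approx(
            4 * (terms.total - terms.focal)
        )

    def test_cross_entropy_mode_ignores_gamma_alpha(self):
        net, acts, t = self._setup(
            lambda1=0.0, lambda2=0.0, beta=0.0, loss_type="cross_entropy", gamma=5.0
        )
        terms = net.loss_terms(acts[-1], t, hidden_acts=acts[1:-1])
        assert terms.focal == pytest.approx(
            d.focal_loss(acts[-1], t, alpha_t=1.0, gamma=0.0)
        )

    def test_shape_mismatch_rejected(self):
        net, acts, t = self._setup()
        with pytest.raises(ValueError):
            net.loss_terms(acts[-1], t[:, :4])

    def test_permutation_equivariance(self):
        # relabeling variants permutes encoding columns pairwise but leaves
        # the total loss unchanged
        spec = AutoencoderSpec(lambda1=0, lambda2=0, beta=0)
        net = Autoencoder(spec, 5, seed=1)
        rng = np.random.default_rng(3)
        out = rng.uniform(0.1, 0.9, size=(7, 10))
        t = (rng.random((7, 10)) > 0.5).astype(float)
        perm_v = rng.permutation(5)
        cols = np.stack([2 * perm_v, 2 * perm_v + 1], axis=1).ravel()
        a = net.loss_terms(out, t).focal
        b = net.loss_terms(out[:, cols], t[:, cols]).focal
        assert a == pytest.approx(b)


class TestBuild:
    def test_width_arithmetic(self):
        net = d.build_autoencoder(
            AutoencoderSpec(n_hidden_layers=1, size_ratio=0.5), 100
        )
        assert net.widths == [200, 100, 200]

    def test_ratio_one_keeps_width(self):
        net = d.build_autoencoder(
            AutoencoderSpec(n_hidden_layers=3, size_ratio=1.0), 10
        )
        assert net.widths == [20] * 7

    def test_minimum_width_floor(self):
        net = d.build_autoencoder(
            AutoencoderSpec(n_hidden_layers=4, size_ratio=0.2), 3
        )
        assert min(net.widths) >= 2

    def test_outputs_in_unit_interval(self):
        net = d.build_autoencoder(AutoencoderSpec(activation="tanh"), 6, seed=4)
        rng = np.random.default_rng(5)
        out = net.forward(rng.normal(size=(9, 12)))
        assert ((out > 0) & (out < 1)).all()

    @pytest.mark.parametrize("bad", [
        dict(activation="gelu"), dict(optimizer="lbfgs"),
        dict(size_ratio=0.0), dict(n_hidden_layers=0), dict(gamma=-1),
    ])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            AutoencoderSpec(**bad)


@pytest.mark.parametrize("activation", ["sigmoid", "tanh", "relu", "softplus", "leakyrelu"])
def test_gradient_matches_finite_differences(activation):
    """Analytic SFL gradients vs central differences on a 5-variant net."""
    spec = AutoencoderSpec(
        lambda1=1e-3, lambda2=1e-3, beta=0.5, rho=0.1,
        activation=activation, gamma=2.0, loss_type="focal",
        n_hidden_layers=1, size_ratio=0.5,
    )
    net = Autoencoder(spec, 5, seed=3)
    rng = np.random.default_rng(7)
    x = (rng.random((6, 10)) > 0.5).astype(float)
    t = (rng.random((6, 10)) > 0.3).astype(float)
    _, gW, gb = net.loss_and_gradients(x, t)

    def total():
        acts, _ = net._forward_full(x)
        return net.loss_terms(acts[-1], t, hidden_acts=acts[1:-1]).total

    eps = 1e-6
    for k in range(net.n_layers):
        W = net.weights[k]
        for _ in range(15):
            i, j = rng.integers(W.shape[0]), rng.integers(W.shape[1])
            orig = W[i, j]
            W[i, j] = orig + eps
            lp = total()
            W[i, j] = orig - eps
            lm = total()
            W[i, j] = orig
            assert abs((lp - lm) / (2 * eps) - gW[k][i, j]) < 1e-4
        b = net.biases[k]
        for _ in range(5):
            j = rng.integers(b.size)
            orig = b[j]
            b[j] = orig + eps
            lp = total()
            b[j] = orig - eps
            lm = total()
            b[j] = orig
            assert abs((lp - lm) / (2 * eps) - gb[k][j]) < 1e-4


class TestAlphaAndOptimizer:
    def test_alpha_is_truth_class_frequency(self):
        x = np.array([[1, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        a = class_frequency_alpha(x)
        # node 0: freq of 1 is 0.75 -> samples with x=1 get 0.75, x=0 get 0.25
        assert a[0, 0] == pytest.approx(0.75)
        assert a[2, 0] == pytest.approx(0.25)
        inv = class_frequency_alpha(x, invert=True)
        assert inv[0, 0] == pytest.approx(0.25)

    def test_sgd_step(self):
        net = Autoencoder(AutoencoderSpec(), 2, seed=0)
        opt = Optimizer(net, 0.1, "sgd")
        W0 = net.weights[0].copy()
        gW = [np.ones_like(w) for w in net.weights]
        gb = [np.ones_like(b) for b in net.biases]
        opt.step(gW, gb)
        assert np.allclose(net.weights[0], W0 - 0.1)

    def test_serialization_round_trip(self, tmp_path):
        net = Autoencoder(AutoencoderSpec(n_hidden_layers=2), 4, seed=9)
        rng = np.random.default_rng(10)
        x = (rng.random((3, 8)) > 0.5).astype(float)
        net.save(tmp_path / "model")
        back = Autoencoder.load(tmp_path / "model")
        assert np.allclose(net.forward(x), back.forward(x))
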