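"""Fully-connected denoising autoencoder and its penalized focal loss.

One autoencoder spans one genomic segment.  Input and output are the
allele-presence encoding (two nodes per variant); hidden layers shrink by a
per-layer width ratio through the encoder and mirror back out through the
decoder; the output layer is sigmoid so every node is an allele-presence
probability.

The training objective is a sparse focal loss: a focal-modulated binary
cross-entropy over all allele-presence output nodes, plus a KL sparsity
penalty pushing the mean hidden activation toward a small target, plus L1
and L2 weight penalties:

    SFL = -alpha_t (1-p_t)^gamma [x_t log p_t + (1-x_t) log(1-p_t)]
          + beta * S(rho || rho_hat) + lambda1 * ||W||_1 + lambda2 * ||W||_2

with S the Bernoulli KL divergence of the target activation rho from the
observed batch-mean activation rho_hat.  alpha_t is set per output node to
the batch frequency of that node's truth class, countering the overwhelming
abundance of present reference alleles at rare-variant sites.

Everything here is NumPy with analytic gradients; reproducibility is exact
given a seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable

import numpy as np

EPS = 1e-7

ACTIVATIONS = ("sigmoid", "tanh", "relu", "softplus", "leakyrelu")
OPTIMIZERS = ("adam", "rmsprop", "sgd")
LOSS_TYPES = ("cross_entropy", "focal")


@dataclasses.dataclass
class AutoencoderSpec:
    """One segment's hyperparameter assignment."""

    lambda1: float = 1e-6
    lambda2: float = 1e-6
    beta: float = 0.0
    rho: float = 0.07
    activation: str = "relu"
    learning_rate: float = 1e-3
    gamma: float = 2.0
    optimizer: str = "adam"
    loss_type: str = "focal"
    n_hidden_layers: int = 1
    size_ratio: float = 0.5
    lr_decay: float = 0.99

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss_type not in LOSS_TYPES:
            raise ValueError(f"unknown loss_type {self.loss_type!r}")
        if not 0 < self.size_ratio <= 1:
            raise ValueError("size_ratio must be in (0, 1]")
        if self.n_hidden_layers < 1:
            raise ValueError("need at least one hidden layer")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AutoencoderSpec":
        return cls(**d)


@dataclasses.dataclass
class LossTerms:
    focal: float
    sparsity: float
    l1: float
    l2: float
    total: float


# ---------------------------------------------------------------- losses


def focal_loss(
    p_t: np.ndarray,
    x_t: np.ndarray,
    alpha_t: np.ndarray | float = 1.0,
    gamma: float = 0.0,
) -> float:
    """Focal-modulated binary cross-entropy, summed over nodes, averaged
    over samples.

    ``p_t`` are predicted allele-presence probabilities, ``x_t`` the {0,1}
    truth encoding.  The per-node cross-entropy ``x log p + (1-x) log(1-p)``
    equals ``log q`` with q the predicted probability of the truth class,
    ``q = x*p + (1-x)*(1-p)``; the modulating factor (1-q)^gamma and the
    weight ``alpha_t`` down-weight well-classified (abundant) alleles.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p = np.clip(np.asarray(p_t, dtype=float), EPS, 1.0 - EPS)
    x = np.asarray(x_t, dtype=float)
    q = x * p + (1.0 - x) * (1.0 - p)  # truth-class predicted probability
    val = -np.asarray(alpha_t, dtype=float) * (1.0 - q) ** gamma * np.log(q)
    if val.ndim >= 2:
        return float(val.sum(axis=-1).mean())
    return float(val.sum())


def sparsity_penalty(rho: float, rho_hat: np.ndarray | float) -> float:
    """KL divergence of Bernoulli(rho) from each batch-mean activation
    Bernoulli(rho_hat_j), summed over batches j."""
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    rh = np.clip(np.atleast_1d(np.asarray(rho_hat, dtype=float)), EPS, 1.0 - EPS)
    return float(
        np.sum(rho * np.log(rho / rh) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rh)))
    )


def class_frequency_alpha(x_t: np.ndarray, invert: bool = False) -> np.ndarray:
    """Per-node, per-sample alpha: the batch frequency of the node's truth
    class (``invert=True`` gives the conventional inverse-frequency weight)."""
    x = np.asarray(x_t, dtype=float)
    f1 = x.mean(axis=0, keepdims=True)  # freq of class "1" per node
    freq = np.where(x > 0.5, f1, 1.0 - f1)
    freq = np.clip(freq, EPS, 1.0)
    return 1.0 - freq if invert else freq


# ---------------------------------------------------------------- activations

def _act(name: str) -> tuple[Callable, Callable]:
    """Return (f, df) where df takes (pre_activation, activation)."""
    if name == "sigmoid":
        f = lambda z: 1.0 / (1.0 + np.exp(-z))
        df = lambda z, a: a * (1.0 - a)
    elif name == "tanh":
        f = np.tanh
        df = lambda z, a: 1.0 - a * a
    elif name == "relu":
        f = lambda z: np.maximum(z, 0.0)
        df = lambda z, a: (z > 0).astype(float)
    elif name == "softplus":
        f = lambda z: np.logaddexp(0.0, z)
        df = lambda z, a: 1.0 / (1.0 + np.exp(-z))
    elif name == "leakyrelu":
        f = lambda z: np.where(z > 0, z, 0.01 * z)
        df = lambda z, a: np.where(z > 0, 1.0, 0.01)
    else:  # pragma: no cover
        raise ValueError(name)
    return f, df


def _hidden_unit_interval(name: str, a: np.ndarray) -> tuple[np.ndarray, float]:
    """Map hidden activations to [0,1] for the sparsity penalty; returns the
    mapped values and the Jacobian scale of the (affine) map."""
    if name == "tanh":
        return (a + 1.0) / 2.0, 0.5
    return a, 1.0


# ---------------------------------------------------------------- network


class Autoencoder:
    """Mirrored fully-connected autoencoder over allele-presence inputs.

    Layer widths: 2*n_variants, then ``n_hidden_layers`` encoder layers each
    ``round(previous * size_ratio)`` wide (minimum 2), then the mirrored
    decoder widths, ending at 2*n_variants with sigmoid output.
    """

    def __init__(self, spec: AutoencoderSpec, n_variants: int, seed: int = 0):
        if n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        self.spec = spec
        self.n_variants = n_variants
        widths = [2 * n_variants]
        for _ in range(spec.n_hidden_layers):
            widths.append(max(2, round(widths[-1] * spec.size_ratio)))
        widths += widths[-2::-1]  # mirrored decoder
        self.widths = widths
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            lim = np.sqrt(6.0 / (fan_in + fan_out))  # uniform Glorot
            self.weights.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._f, self._df = _act(spec.activation)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    # -------------------------------------------------- forward / loss

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self._forward_full(x)[0][-1]

    def _forward_full(self, x: np.ndarray):
        acts = [np.asarray(x, dtype=float)]
        pres = []
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = acts[-1] @ W + b
            pres.append(z)
            if k == self.n_layers - 1:
                acts.append(1.0 / (1.0 + np.exp(-z)))  # sigmoid output
            else:
                acts.append(self._f(z))
        return acts, pres

    def loss_terms(
        self,
        outputs: np.ndarray,
        truth: np.ndarray,
        hidden_acts: list[np.ndarray] | None = None,
        alpha: np.ndarray | float | None = None,
    ) -> LossTerms:
        spec = self.spec
        if outputs.shape != truth.shape:
            raise ValueError("output/truth shape mismatch")
        if alpha is None:
            alpha = class_frequency_alpha(truth)
        if spec.loss_type == "cross_entropy":
            fl = focal_loss(outputs, truth, alpha_t=1.0, gamma=0.0)
        else:
            fl = focal_loss(outputs, truth, alpha_t=alpha, gamma=spec.gamma)
        if hidden_acts is not None and spec.beta > 0:
            pooled = np.concatenate(
                [
                    _hidden_unit_interval(spec.activation, a)[0].reshape(a.shape[0], -1)
                    for a in hidden_acts
                ],
                axis=1,
            )
            rho_hat = float(pooled.mean())
            # grid rho values include the boundary 1.0; clamp into the KL's
            # open interval rather than rejecting the spec
            sp = sparsity_penalty(float(np.clip(spec.rho, EPS, 1 - EPS)), rho_hat)
        else:
            sp = 0.0
        l1 = float(sum(np.abs(W).sum() for W in self.weights))
        l2 = float(sum((W * W).sum() for W in self.weights))
        total = fl + spec.beta * sp + spec.lambda1 * l1 + spec.lambda2 * l2
        return LossTerms(fl, sp, l1, l2, total)

    # -------------------------------------------------- backward

    def loss_and_gradients(self, x: np.ndarray, truth: np.ndarray):
        """Forward + analytic gradients of the full objective.

        Returns (LossTerms, grads_W, grads_b).  The focal term is averaged
        over the batch; the sparsity term uses the batch-mean hidden
        activation pooled over all hidden layers.
        """
        spec = self.spec
        acts, pres = self._forward_full(x)
        out = acts[-1]
        n = x.shape[0]
        hidden = acts[1:-1]
        alpha = class_frequency_alpha(truth)
        terms = self.loss_terms(out, truth, hidden_acts=hidden, alpha=alpha)

        p = np.clip(out, EPS, 1.0 - EPS)
        t = np.asarray(truth, dtype=float)
        if spec.loss_type == "cross_entropy":
            a_w, gamma = 1.0, 0.0
        else:
            a_w, gamma = alpha, spec.gamma
        # focal = mean over samples of sum over nodes of -a (1-q)^g log q,
        # with q the truth-class probability; dq/dp = 2t - 1
        q = t * p + (1.0 - t) * (1.0 - p)
        if gamma == 0:
            dL_dq = -(a_w) / q
        else:
            dL_dq = -(a_w) * (
                -gamma * (1.0 - q) ** (gamma - 1.0) * np.log(q)
                + (1.0 - q) ** gamma / q
            )
        dL_dp = dL_dq * (2.0 * t - 1.0) / n
        dL_dp = np.where((out > EPS) & (out < 1.0 - EPS), dL_dp, 0.0)
        delta = dL_dp * out * (1.0 - out)  # sigmoid output layer

        # sparsity gradient wrt each hidden activation
        n_hidden_units = sum(a.shape[1] for a in hidden) if hidden else 0
        sp_grads: list[np.ndarray | None] = [None] * len(hidden)
        if spec.beta > 0 and n_hidden_units > 0:
            pooled = np.concatenate(
                [
                    _hidden_unit_interval(spec.activation, a)[0]
                    for a in hidden
                ],
                axis=1,
            )
            rho_hat = float(np.clip(pooled.mean(), EPS, 1.0 - EPS))
            rho = float(np.clip(spec.rho, EPS, 1 - EPS))
            dS_drho_hat = -rho / rho_hat + (1.0 - rho) / (1.0 - rho_hat)
            scale = _hidden_unit_interval(spec.activation, hidden[0])[1]
            coeff = spec.beta * dS_drho_hat * scale / (n * n_hidden_units)
            for k, a in enumerate(hidden):
                sp_grads[k] = np.full_like(a, coeff)

        grads_W = [np.zeros_like(W) for W in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]
        for k in range(self.n_layers - 1, -1, -1):
            grads_W[k] = acts[k].T @ delta
            grads_b[k] = delta.sum(axis=0)
            if k > 0:
                delta = delta @ self.weights[k].T
                if sp_grads[k - 1] is not None:
                    delta = delta + sp_grads[k - 1]
                delta = delta * self._df(pres[k - 1], acts[k])
        for k, W in enumerate(self.weights):
            grads_W[k] += spec.lambda1 * np.sign(W) + 2.0 * spec.lambda2 * W
        return terms, grads_W, grads_b

    # -------------------------------------------------- serialization

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {}
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{k}"] = W
            arrays[f"b{k}"] = b
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"spec": self.spec.to_dict(), "n_variants": self.n_variants}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Autoencoder":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(AutoencoderSpec.from_dict(meta["spec"]), meta["n_variants"])
        with np.load(path.with_suffix(".npz")) as data:
            for k in range(model.n_layers):
                model.weights[k] = data[f"W{k}"]
                model.biases[k] = data[f"b{k}"]
        return model


def build_autoencoder(
    spec: AutoencoderSpec, n_variants: int, seed: int = 0
) -> Autoencoder:
    """Construct the mirrored autoencoder for a segment of ``n_variants``."""
    return Autoencoder(spec, n_variants, seed=seed)


# ---------------------------------------------------------------- optimizers


class Optimizer:
    """Adam / RMSprop / plain gradient-descent over the model parameters."""

    def __init__(self, model: Autoencoder, learning_rate: float, kind: str = "adam"):
        if kind not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {kind!r}")
        self.model = model
        self.lr = learning_rate
        self.kind = kind
        params = model.weights + model.biases
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads_W: list[np.ndarray], grads_b: list[np.ndarray]) -> None:
        params = self.model.weights + self.model.biases
        grads = grads_W + grads_b
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            if self.kind == "sgd":
                p -= self.lr * g
            elif self.kind == "rmsprop":
                self.v[i] = 0.9 * self.v[i] + 0.1 * g * g
                p -= self.lr * g / (np.sqrt(self.v[i]) + eps)
            else:  # adam
                self.m[i] = b1 * self.m[i] + (1 - b1) * g
                self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
                mhat = self.m[i] / (1 - b1**self.t)
                vhat = self.v[i] / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)
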