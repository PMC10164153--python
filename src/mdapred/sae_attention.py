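"""Stacked autoencoder with a multi-head self-attention output block.

Learns node attribute features from a square similarity matrix X whose rows
are node profiles. The network is a mirror-symmetric stack of autoencoders
(encoders d0 -> n1[0] -> ... -> n1[-1], decoders back to d0), greedily
pretrained layer by layer and then fine-tuned end to end on the squared
reconstruction error ``L(X, X') = ||X - X'||^2`` with Adam. A multi-head
scaled-dot-product self-attention block -- tokens are the node rows of the
reconstruction -- is applied to the final decoder output with a residual
connection, so the returned attribute features have exactly the shape of the
input similarity matrix.

Everything here is plain numpy with hand-written gradients; a finite
difference check in the test suite validates every parameter gradient.

Gradient conventions: layers cache their forward pass; ``backward(dY)``
accumulates parameter gradients and returns the gradient w.r.t. the layer
input. Loss is the mean squared entry-wise error (a constant rescaling of
the Frobenius objective, so the minimizer is unchanged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from mdapred.data_io import Entity

logger = logging.getLogger(__name__)

Activation = Literal["relu", "sigmoid", "linear"]


@dataclass
class SAEConfig:
    """Stacked-autoencoder hyperparameters.

    hidden_sizes : encoder widths, outermost first (default (128, 64, 32)).
    n_stacked : number of stacked autoencoders; must equal len(hidden_sizes)
        (kept as an explicit field so configs can cross-check it).
    heads : number of attention heads (default 4).
    learning_rate : Adam step size for both pretraining and fine-tuning
        (default 0.01).
    epochs : full-batch fine-tuning epochs (default 200).
    pretrain_epochs : greedy pretraining epochs per autoencoder (default 50).
    use_attention : disable for the ablation arm; the network then differs
        only in the absence of the attention block.
    attention_placement : "final" applies one attention block after the last
        decoder; "per_ae" inserts one after every decoder (exploratory).
    """

    hidden_sizes: tuple[int, ...] = (128, 64, 32)
    n_stacked: int | None = None
    heads: int = 4
    learning_rate: float = 0.01
    epochs: int = 200
    pretrain_epochs: int = 50
    seed: int = 0
    hidden_activation: Activation = "relu"
    output_activation: Activation = "sigmoid"
    use_attention: bool = True
    attention_placement: Literal["final", "per_ae"] = "final"

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be positive integers")
        if self.n_stacked is None:
            self.n_stacked = len(self.hidden_sizes)
        if self.n_stacked != len(self.hidden_sizes):
            raise ValueError(
                f"n_stacked={self.n_stacked} does not match len(hidden_sizes)={len(self.hidden_sizes)}"
            )
        if self.heads < 1:
            raise ValueError("heads must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class AttributeFeatures:
    """Attention-enhanced reconstruction of a similarity matrix (same shape)."""

    entity: Entity
    source_measure: str
    values: np.ndarray = field(repr=False)
    loss_curve: np.ndarray = field(default=None, repr=False)
    final_loss: float = float("nan")


def _activate(name: Activation, Z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(Z, 0.0)
    if name == "sigmoid":
        # numerically stable logistic
        out = np.empty_like(Z)
        pos = Z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-Z[pos]))
        ez = np.exp(Z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    if name == "linear":
        return Z
    raise ValueError(f"unknown activation {name!r}")


def _activate_grad(name: Activation, Z: np.ndarray, Y: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (Z > 0).astype(Z.dtype)
    if name == "sigmoid":
        return Y * (1.0 - Y)
    if name == "linear":
        return np.ones_like(Z)
    raise ValueError(f"unknown activation {name!r}")


def _glorot(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-limit, limit, size=(d_in, d_out))


class Dense:
    """Affine map + activation: ``Y = f(A W + b)`` over row-vector samples."""

    def __init__(self, d_in: int, d_out: int, activation: Activation, rng: np.random.Generator):
        self.W = _glorot(rng, d_in, d_out)
        self.b = np.zeros(d_out)
        self.activation: Activation = activation
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._A: np.ndarray | None = None
        self._Z: np.ndarray | None = None
        self._Y: np.ndarray | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]

    def forward(self, A: np.ndarray) -> np.ndarray:
        self._A = A
        self._Z = A @ self.W + self.b
        self._Y = _activate(self.activation, self._Z)
        return self._Y

    def backward(self, dY: np.ndarray) -> np.ndarray:
        dZ = dY * _activate_grad(self.activation, self._Z, self._Y)
        self.dW[...] = self._A.T @ dZ
        self.db[...] = dZ.sum(axis=0)
        return dZ @ self.W.T


class MultiHeadSelfAttention:
    """Scaled dot-product self-attention over node rows, with residual add.

    Per head, queries/keys/values are learned linear maps of dimension
    ``ceil(d / heads)``; head outputs are concatenated and projected back to
    d before the residual addition. When d is not divisible by the head
    count the internal model dimension is the next multiple (equivalent to
    zero-padding, truncated by the output projection; logged).
    """

    def __init__(self, d: int, heads: int, rng: np.random.Generator):
        self.d = d
        self.heads = heads
        self.head_dim = -(-d // heads)  # ceil
        self.d_model = self.head_dim * heads
        if self.d_model != d:
            logger.info(
                "attention model dim padded from %d to %d for %d heads", d, self.d_model, heads
            )
        self.Wq = _glorot(rng, d, self.d_model)
        self.Wk = _glorot(rng, d, self.d_model)
        self.Wv = _glorot(rng, d, self.d_model)
        self.Wo = _glorot(rng, self.d_model, d)
        self.dWq = np.zeros_like(self.Wq)
        self.dWk = np.zeros_like(self.Wk)
        self.dWv = np.zeros_like(self.Wv)
        self.dWo = np.zeros_like(self.Wo)
        self.last_attention_weights: np.ndarray | None = None  # (heads, n, n)
        self._cache: tuple | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wq, self.Wk, self.Wv, self.Wo]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dWq, self.dWk, self.dWv, self.dWo]

    def _split(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        return X.reshape(n, self.heads, self.head_dim).transpose(1, 0, 2)

    def _merge(self, Xh: np.ndarray) -> np.ndarray:
        n = Xh.shape[1]
        return Xh.transpose(1, 0, 2).reshape(n, self.d_model)

    def forward(self, H: np.ndarray) -> np.ndarray:
        Q, K, V = H @ self.Wq, H @ self.Wk, H @ self.Wv
        Qh, Kh, Vh = self._split(Q), self._split(K), self._split(V)
        scale = 1.0 / math.sqrt(self.head_dim)
        S = np.einsum("hid,hjd->hij", Qh, Kh) * scale
        S -= S.max(axis=-1, keepdims=True)  # softmax shift, gradient-free
        E = np.exp(S)
        A = E / E.sum(axis=-1, keepdims=True)
        Oh = np.einsum("hij,hjd->hid", A, Vh)
        O = self._merge(Oh)
        out = H + O @ self.Wo
        self.last_attention_weights = A
        self._cache = (H, Qh, Kh, Vh, A, O, scale)
        return out

    def backward(self, dOut: np.ndarray) -> np.ndarray:
        H, Qh, Kh, Vh, A, O, scale = self._cache
        dH = dOut.copy()
        self.dWo[...] = O.T @ dOut
        dO = dOut @ self.Wo.T
        dOh = self._split(dO)
        dA = np.einsum("hid,hjd->hij", dOh, Vh)
        dVh = np.einsum("hij,hid->hjd", A, dOh)
        # softmax Jacobian, rows of A sum to 1
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dQh = np.einsum("hij,hjd->hid", dS, Kh) * scale
        dKh = np.einsum("hij,hid->hjd", dS, Qh) * scale
        dQ, dK, dV = self._merge(dQh), self._merge(dKh), self._merge(dVh)
        self.dWq[...] = H.T @ dQ
        self.dWk[...] = H.T @ dK
        self.dWv[...] = H.T @ dV
        dH += dQ @ self.Wq.T + dK @ self.Wk.T + dV @ self.Wv.T
        return dH


def multi_head_attention(H: np.ndarray, heads: int, seed: int = 0) -> np.ndarray:
    """Apply a freshly initialized multi-head self-attention block to H."""
    H = np.asarray(H, dtype=np.float64)
    block = MultiHeadSelfAttention(H.shape[1], heads, np.random.default_rng(seed))
    return block.forward(H)


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params: Sequence[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class SAENetwork:
    """Mirror-symmetric autoencoder stack with optional attention block(s)."""

    def __init__(self, input_dim: int, cfg: SAEConfig):
        if input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        self.cfg = cfg
        self.input_dim = input_dim
        rng = np.random.default_rng(cfg.seed)
        dims = [input_dim, *cfg.hidden_sizes]
        for h in cfg.hidden_sizes:
            if h > input_dim:
                logger.warning("hidden size %d exceeds input dim %d (over-complete layer)", h, input_dim)
        self.encoders = [
            Dense(dims[i], dims[i + 1], cfg.hidden_activation, rng)
            for i in range(len(cfg.hidden_sizes))
        ]
        # decoder i mirrors encoder i: maps dims[i+1] back to dims[i];
        # the outermost decoder (i == 0) reproduces the [0,1] input range
        self.decoders = [
            Dense(dims[i + 1], dims[i],
                  cfg.output_activation if i == 0 else cfg.hidden_activation, rng)
            for i in range(len(cfg.hidden_sizes))
        ]
        self.attentions: list[MultiHeadSelfAttention | None] = [None] * len(self.decoders)
        if cfg.use_attention:
            if cfg.attention_placement == "final":
                self.attentions[0] = MultiHeadSelfAttention(input_dim, cfg.heads, rng)
            else:
                for i in range(len(self.decoders)):
                    self.attentions[i] = MultiHeadSelfAttention(dims[i], cfg.heads, rng)

    # fine-tune stack, outermost-first encoders then innermost-first decoders
    def _blocks(self) -> list:
        blocks: list = list(self.encoders)
        for i in reversed(range(len(self.decoders))):
            blocks.append(self.decoders[i])
            if self.attentions[i] is not None:
                blocks.append(self.attentions[i])
        return blocks

    @property
    def params(self) -> list[np.ndarray]:
        return [p for blk in self._blocks() for p in blk.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for blk in self._blocks() for g in blk.grads]

    def forward(self, X: np.ndarray) -> np.ndarray:
        H = X
        for blk in self._blocks():
            H = blk.forward(H)
        return H

    def backward(self, dOut: np.ndarray) -> np.ndarray:
        d = dOut
        for blk in reversed(self._blocks()):
            d = blk.backward(d)
        return d

    def encode(self, X: np.ndarray) -> np.ndarray:
        H = X
        for enc in self.encoders:
            H = enc.forward(H)
        return H


def build_sae(input_dim: int, cfg: SAEConfig) -> SAENetwork:
    """Construct an untrained stacked autoencoder for ``input_dim`` features."""
    return SAENetwork(input_dim, cfg)


def _mse(X: np.ndarray, Xp: np.ndarray) -> float:
    return float(np.mean((X - Xp) ** 2))


def _check_finite(loss: float, where: str, lr: float) -> None:
    if not math.isfinite(loss):
        raise FloatingPointError(
            f"non-finite reconstruction loss during {where}; try a lower learning rate (got lr={lr})"
        )


def _pretrain(net: SAENetwork, X: np.ndarray, cfg: SAEConfig) -> None:
    """Greedy layer-wise pretraining of each encoder/decoder pair."""
    Z = X
    for i, (enc, dec) in enumerate(zip(net.encoders, net.decoders)):
        opt = Adam(enc.params + dec.params, cfg.learning_rate)
        for _ in range(cfg.pretrain_epochs):
            Y = dec.forward(enc.forward(Z))
            loss = _mse(Z, Y)
            _check_finite(loss, f"pretraining of autoencoder {i}", cfg.learning_rate)
            dY = 2.0 * (Y - Z) / Z.size
            enc.backward(dec.backward(dY))
            opt.step(enc.grads + dec.grads)
        Z = enc.forward(Z)


def train_sae(
    X: np.ndarray,
    cfg: SAEConfig | None = None,
    entity: Entity = "drug",
    source_measure: str = "cosine",
    return_model: bool = False,
):
    """Train the stacked autoencoder on a similarity matrix and return its features.

    Two phases: greedy layer-wise pretraining (each autoencoder fitted to the
    previous encoder's output), then end-to-end fine-tuning of the full stack
    plus attention on the reconstruction loss, full-batch Adam. The returned
    features are the final post-attention reconstruction -- same shape as X.
    Deterministic given ``cfg.seed``.

    ``loss_curve[k]`` is the loss *before* the k-th fine-tuning update;
    the last entry is the loss after the final update.
    """
    cfg = cfg or SAEConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix of node profiles")
    net = build_sae(X.shape[1], cfg)
    _pretrain(net, X, cfg)

    opt = Adam(net.params, cfg.learning_rate)
    losses = []
    for _ in range(cfg.epochs):
        Xp = net.forward(X)
        loss = _mse(X, Xp)
        _check_finite(loss, "fine-tuning", cfg.learning_rate)
        losses.append(loss)
        net.backward(2.0 * (Xp - X) / X.size)
        opt.step(net.grads)
    Xp = net.forward(X)
    final_loss = _mse(X, Xp)
    _check_finite(final_loss, "fine-tuning", cfg.learning_rate)
    losses.append(final_loss)
    logger.info(
        "SAE(%s/%s): reconstruction loss %.3e -> %.3e over %d epochs",
        entity, source_measure, losses[0], final_loss, cfg.epochs,
    )
    features = AttributeFeatures(
        entity=entity,
        source_measure=source_measure,
        values=Xp,
        loss_curve=np.array(losses),
        final_loss=final_loss,
    )
    return (features, net) if return_model else features
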