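"""Greedy stacked autoencoder for pair-feature compression.

Three tanh autoencoders are trained layer by layer: the first reconstructs
the raw pair features, each subsequent one reconstructs the previous layer's
codes.  Encoders use tanh activations; decoders are linear (the inputs live
in [0,1] and codes in (-1,1), so a linear readout reconstructs both ranges).
The training objective per layer is the summed squared reconstruction error

    l(x, x~) = sum_i || x_i - x~_i ||^2

minimised with Adam.  For the canonical 1756-dimensional features the code
dimensions are 1024, 512 and 256; for narrower inputs each width is capped
at the input width, so the final 256-dimensional code is kept whenever the
input affords it (see :func:`plan_code_dims`).

Everything is plain numpy, single-threaded, and bit-reproducible given
(data, seed, hyperparameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AutoencoderLayer",
    "EncoderStack",
    "plan_code_dims",
    "fit_sae",
    "encode",
    "reconstruction_loss",
]

_REFERENCE_IN_DIM = 1756
_REFERENCE_DIMS = (1024, 512, 256)


@dataclass
class AutoencoderLayer:
    """One encoder/decoder pair: z = tanh(W x + b), x~ = W' z + b'."""

    W: np.ndarray
    b: np.ndarray
    W_dec: np.ndarray
    b_dec: np.ndarray
    f_e: str = "tanh"
    f_d: str = "linear"

    @property
    def in_dim(self) -> int:
        return self.W.shape[1]

    @property
    def code_dim(self) -> int:
        return self.W.shape[0]

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.in_dim:
            raise ValueError(f"expected {self.in_dim} input columns, got {X.shape[1]}")
        return np.tanh(X @ self.W.T + self.b)

    def decode(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.W_dec.T + self.b_dec


@dataclass
class EncoderStack:
    """Ordered autoencoder layers plus the per-layer training loss log."""

    layers: list[AutoencoderLayer]
    training_log: list[list[float]] = field(default_factory=list)
    seed: int = 0

    @property
    def in_dim(self) -> int:
        return self.layers[0].in_dim

    @property
    def code_dim(self) -> int:
        return self.layers[-1].code_dim


def plan_code_dims(in_dim: int, dims: tuple[int, ...] = _REFERENCE_DIMS) -> tuple[int, ...]:
    """Code widths for an input of ``in_dim`` columns.

    Inputs at least as wide as the first code use ``dims`` unchanged; for
    narrower inputs every width is capped at the input width, so the final
    code keeps its canonical absolute size (256 by default) whenever the
    input affords it.  Shrinking the code proportionally to the input
    instead discards far too much: a 400-column input compressed to ~58
    dimensions loses low-variance directions that carry most of the signal.
    """
    return tuple(min(d, in_dim) for d in dims)


def reconstruction_loss(layer: AutoencoderLayer, X: np.ndarray) -> float:
    """Summed squared reconstruction error over all rows."""
    X = np.asarray(X, dtype=float)
    X_hat = layer.decode(layer.encode(X))
    return float(((X - X_hat) ** 2).sum())


def _fit_layer(
    X: np.ndarray,
    code_dim: int,
    epochs: int,
    batch: int,
    lr: float,
    rng: np.random.Generator,
) -> tuple[AutoencoderLayer, list[float]]:
    n, d = X.shape
    # Glorot-uniform init
    lim_e = np.sqrt(6.0 / (d + code_dim))
    W = rng.uniform(-lim_e, lim_e, size=(code_dim, d))
    b = np.zeros(code_dim)
    W_dec = rng.uniform(-lim_e, lim_e, size=(d, code_dim))
    b_dec = np.zeros(d)

    params = [W, b, W_dec, b_dec]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    losses: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            xb = X[order[start : start + batch]]
            bsz = xb.shape[0]
            z = np.tanh(xb @ W.T + b)
            x_hat = z @ W_dec.T + b_dec
            diff = x_hat - xb
            epoch_loss += float((diff**2).sum())
            # gradients of the per-batch mean loss
            g_out = (2.0 / bsz) * diff
            gW_dec = g_out.T @ z
            gb_dec = g_out.sum(axis=0)
            g_z = g_out @ W_dec
            g_a = g_z * (1.0 - z**2)
            gW = g_a.T @ xb
            gb = g_a.sum(axis=0)
            grads = [gW, gb, gW_dec, gb_dec]
            t += 1
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= beta1
                mi += (1 - beta1) * g
                vi *= beta2
                vi += (1 - beta2) * g**2
                m_hat = mi / (1 - beta1**t)
                v_hat = vi / (1 - beta2**t)
                p -= lr * m_hat / (np.sqrt(v_hat) + eps)
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"non-finite reconstruction loss at epoch {epoch}")
        losses.append(epoch_loss)
    layer = AutoencoderLayer(W=W, b=b, W_dec=W_dec, b_dec=b_dec)
    return layer, losses


def fit_sae(
    X: np.ndarray,
    dims: tuple[int, ...] = _REFERENCE_DIMS,
    epochs: int = 100,
    batch: int = 128,
    lr: float = 1e-3,
    seed: int = 0,
) -> EncoderStack:
    """Train the stack greedily: layer k fits on layer k-1's codes."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty 2-D matrix")
    if X.shape[0] < batch:
        raise ValueError(f"batch size {batch} exceeds the {X.shape[0]} training rows")
    rng = np.random.default_rng(seed)
    code_dims = plan_code_dims(X.shape[1], dims)
    layers: list[AutoencoderLayer] = []
    log: list[list[float]] = []
    current = X
    for code_dim in code_dims:
        layer, losses = _fit_layer(current, code_dim, epochs, batch, lr, rng)
        layers.append(layer)
        log.append(losses)
        current = layer.encode(current)
    return EncoderStack(layers=layers, training_log=log, seed=seed)


def encode(stack: EncoderStack, X: np.ndarray) -> np.ndarray:
    """Apply every encoder in sequence; output is bounded in (-1,1)."""
    Z = np.asarray(X, dtype=float)
    for layer in stack.layers:
        Z = layer.encode(Z)
    return Z
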