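"""Minimal NumPy computation-graph engine for encoder-decoder CNNs.

Networks are declared as a flat list of :class:`LayerDef` nodes forming a
DAG (named inputs), then executed by :class:`Network` with explicit
forward caches and reverse-order backpropagation. Convolutions run as
im2col + BLAS sgemm in float32, which is what makes CPU-only training of
the U-Net variants practical.

Supported ops
-------------
input, conv (k x k, 'same' zero padding, bias), bn (batch norm), relu,
maxpool (2x2/2), upconv (2x2/2 transposed conv), concat (channel axis),
add, dropout.

All tensors are NCHW float32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

F32 = np.float32


# ---------------------------------------------------------------------------
# Graph declaration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerDef:
    """One node of the network DAG.

    ``in_channels``/``out_channels`` are resolved at build time so that
    parameter counts can be computed without instantiating weights.
    """

    name: str
    op: str
    inputs: tuple[str, ...]
    in_channels: int = 0
    out_channels: int = 0
    kernel: int = 3
    rate: float = 0.0  # dropout rate

    def n_params(self) -> int:
        if self.op == "conv":
            return self.kernel * self.kernel * self.in_channels * self.out_channels + self.out_channels
        if self.op == "upconv":
            return 4 * self.in_channels * self.out_channels + self.out_channels
        if self.op == "bn":
            return 2 * self.out_channels
        return 0


def count_graph_parameters(graph: list[LayerDef]) -> int:
    """Total trainable scalars (kernels + biases + norm scales/shifts)."""
    return sum(node.n_params() for node in graph)


# ---------------------------------------------------------------------------
# Functional primitives (forward + backward)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) patch matrix, 'same' zero padding."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # windows: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols, dtype=F32)


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """'Same' convolution. w: (O, C, k, k). Returns (y, cache)."""
    n, c, h, width = x.shape
    o, _, k, _ = w.shape
    cols = _im2col(x, k, k // 2)
    wmat = w.reshape(o, c * k * k).T
    y = cols @ wmat + b
    y = y.reshape(n, h, width, o).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(y), (cols, x.shape, w)


def conv2d_backward(dy: np.ndarray, cache):
    cols, x_shape, w = cache
    n, c, h, width = x_shape
    o, _, k, _ = w.shape
    dy_mat = dy.transpose(0, 2, 3, 1).reshape(n * h * width, o)
    dw = (cols.T @ dy_mat).T.reshape(o, c, k, k)
    db = dy_mat.sum(axis=0)
    # dx = 'same' convolution of dy with the flipped, channel-transposed kernel
    w_flip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, O, k, k)
    cols_dy = _im2col(dy, k, k // 2)
    dx = cols_dy @ w_flip.reshape(c, o * k * k).T
    dx = dx.reshape(n, h, width, c).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(dx), dw, db


def maxpool2(x: np.ndarray):
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValidationError(f"maxpool needs even spatial dims; got {h}x{w}")
    blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return np.ascontiguousarray(y), (idx, x.shape)


def maxpool2_backward(dy: np.ndarray, cache):
    idx, x_shape = cache
    n, c, h, w = x_shape
    dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
    np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
    dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx.reshape(n, c, h, w))


def upconv2(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """2x2 stride-2 transposed convolution. w: (C, O, 2, 2)."""
    n, c, h, width = x.shape
    o = w.shape[1]
    y = np.tensordot(x, w, axes=([1], [0]))  # (N, H, W, O, 2, 2)
    y = y.transpose(0, 3, 1, 4, 2, 5).reshape(n, o, 2 * h, 2 * width)
    y = y + b[None, :, None, None]
    return np.ascontiguousarray(y.astype(F32)), (x, w)


def upconv2_backward(dy: np.ndarray, cache):
    x, w = cache
    n, c, h, width = x.shape
    o = w.shape[1]
    blocks = dy.reshape(n, o, h, 2, width, 2).transpose(0, 2, 4, 1, 3, 5)
    # blocks: (N, H, W, O, 2, 2)
    dx = np.tensordot(blocks, w, axes=([3, 4, 5], [1, 2, 3]))  # (N, H, W, C)
    dx = dx.transpose(0, 3, 1, 2)
    dw = np.tensordot(x, blocks, axes=([0, 2, 3], [0, 1, 2]))  # (C, O, 2, 2)
    db = dy.sum(axis=(0, 2, 3))
    return (
        np.ascontiguousarray(dx.astype(F32)),
        dw.astype(F32),
        db.astype(F32),
    )


def batchnorm(x, gamma, beta, running_mean, running_var, training, momentum=0.1, eps=1e-5):
    if training:
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
    y = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return y.astype(F32), (xhat, invstd, gamma)


def batchnorm_backward(dy: np.ndarray, cache):
    xhat, invstd, gamma = cache
    m = dy.shape[0] * dy.shape[2] * dy.shape[3]
    dgamma = (dy * xhat).sum(axis=(0, 2, 3))
    dbeta = dy.sum(axis=(0, 2, 3))
    dxhat = dy * gamma[None, :, None, None]
    dx = (
        dxhat
        - dxhat.mean(axis=(0, 2, 3), keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
    ) * invstd[None, :, None, None]
    return dx.astype(F32), dgamma.astype(F32), dbeta.astype(F32)


# ---------------------------------------------------------------------------
# Network executor
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """Executes a LayerDef DAG with owned parameters and BN statistics."""

    graph: list[LayerDef]
    params: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    bn_stats: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def build(cls, graph: list[LayerDef], seed: int) -> "Network":
        """He-normal conv init (fan-in), BN gamma=1/beta=0, zero biases."""
        rng = np.random.default_rng(seed)
        params: dict[str, dict[str, np.ndarray]] = {}
        bn_stats: dict[str, dict[str, np.ndarray]] = {}
        for node in graph:
            if node.op == "conv":
                fan_in = node.kernel * node.kernel * node.in_channels
                std = np.sqrt(2.0 / fan_in)
                params[node.name] = {
                    "w": rng.normal(0, std, (node.out_channels, node.in_channels,
                                             node.kernel, node.kernel)).astype(F32),
                    "b": np.zeros(node.out_channels, dtype=F32),
                }
            elif node.op == "upconv":
                fan_in = 4 * node.in_channels
                std = np.sqrt(2.0 / fan_in)
                params[node.name] = {
                    "w": rng.normal(0, std, (node.in_channels, node.out_channels,
                                             2, 2)).astype(F32),
                    "b": np.zeros(node.out_channels, dtype=F32),
                }
            elif node.op == "bn":
                params[node.name] = {
                    "gamma": np.ones(node.out_channels, dtype=F32),
                    "beta": np.zeros(node.out_channels, dtype=F32),
                }
                bn_stats[node.name] = {
                    "mean": np.zeros(node.out_channels, dtype=F32),
                    "var": np.ones(node.out_channels, dtype=F32),
                }
        return cls(graph=graph, params=params, bn_stats=bn_stats)

    # -- execution ----------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Run the DAG; returns (output, tape) with per-node caches."""
        values: dict[str, np.ndarray] = {}
        tape: dict[str, object] = {}
        out = None
        for node in self.graph:
            if node.op == "input":
                values[node.name] = x.astype(F32)
                continue
            ins = [values[i] for i in node.inputs]
            if node.op == "conv":
                p = self.params[node.name]
                y, cache = conv2d(ins[0], p["w"], p["b"])
                tape[node.name] = cache
            elif node.op == "upconv":
                p = self.params[node.name]
                y, cache = upconv2(ins[0], p["w"], p["b"])
                tape[node.name] = cache
            elif node.op == "bn":
                p, s = self.params[node.name], self.bn_stats[node.name]
                y, cache = batchnorm(ins[0], p["gamma"], p["beta"],
                                     s["mean"], s["var"], training)
                tape[node.name] = cache
            elif node.op == "relu":
                y = np.maximum(ins[0], 0)
                tape[node.name] = y
            elif node.op == "maxpool":
                y, cache = maxpool2(ins[0])
                tape[node.name] = cache
            elif node.op == "concat":
                y = np.concatenate(ins, axis=1)
                tape[node.name] = [v.shape[1] for v in ins]
            elif node.op == "add":
                y = ins[0] + ins[1]
            elif node.op == "dropout":
                if training and node.rate > 0:
                    if rng is None:
                        raise ValidationError("dropout in training mode needs an rng")
                    mask = (rng.random(ins[0].shape) >= node.rate).astype(F32)
                    mask /= F32(1.0 - node.rate)
                    y = ins[0] * mask
                    tape[node.name] = mask
                else:
                    y = ins[0]
                    tape[node.name] = None
            else:
                raise ValidationError(f"unknown op {node.op!r}")
            values[node.name] = y
            out = y
        return out, (values, tape)

    def backward(self, dy: np.ndarray, state) -> dict[str, dict[str, np.ndarray]]:
        """Backpropagate; returns parameter gradients keyed like params."""
        values, tape = state
        grads: dict[str, np.ndarray] = {self.graph[-1].name: dy.astype(F32)}
        pgrads: dict[str, dict[str, np.ndarray]] = {}
        for node in reversed(self.graph):
            if node.op == "input" or node.name not in grads:
                continue
            g = grads.pop(node.name)
            if node.op == "conv":
                dx, dw, db = conv2d_backward(g, tape[node.name])
                pgrads[node.name] = {"w": dw, "b": db}
                _accum(grads, node.inputs[0], dx)
            elif node.op == "upconv":
                dx, dw, db = upconv2_backward(g, tape[node.name])
                pgrads[node.name] = {"w": dw, "b": db}
                _accum(grads, node.inputs[0], dx)
            elif node.op == "bn":
                dx, dgamma, dbeta = batchnorm_backward(g, tape[node.name])
                pgrads[node.name] = {"gamma": dgamma, "beta": dbeta}
                _accum(grads, node.inputs[0], dx)
            elif node.op == "relu":
                _accum(grads, node.inputs[0], g * (tape[node.name] > 0))
            elif node.op == "maxpool":
                _accum(grads, node.inputs[0], maxpool2_backward(g, tape[node.name]))
            elif node.op == "concat":
                splits = np.cumsum(tape[node.name])[:-1]
                for name, part in zip(node.inputs, np.split(g, splits, axis=1)):
                    _accum(grads, name, np.ascontiguousarray(part))
            elif node.op == "add":
                _accum(grads, node.inputs[0], g)
                _accum(grads, node.inputs[1], g)
            elif node.op == "dropout":
                mask = tape[node.name]
                _accum(grads, node.inputs[0], g if mask is None else g * mask)
        return pgrads

    # -- parameter access ---------------------------------------------------

    def parameter_count(self) -> int:
        return int(sum(a.size for d in self.params.values() for a in d.values()))

    def state_dict(self) -> dict:
        return {
            "params": {k: {n: v.copy() for n, v in d.items()} for k, d in self.params.items()},
            "bn_stats": {k: {n: v.copy() for n, v in d.items()} for k, d in self.bn_stats.items()},
        }

    def load_state_dict(self, state: dict) -> None:
        for k, d in state["params"].items():
            for n, v in d.items():
                self.params[k][n][...] = v
        for k, d in state["bn_stats"].items():
            for n, v in d.items():
                self.bn_stats[k][n][...] = v


def _accum(grads: dict[str, np.ndarray], name: str, g: np.ndarray) -> None:
    if name in grads:
        grads[name] = grads[name] + g
    else:
        grads[name] = g


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, net: Network, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: {n: np.zeros_like(v) for n, v in d.items()}
                  for k, d in net.params.items()}
        self.v = {k: {n: np.zeros_like(v) for n, v in d.items()}
                  for k, d in net.params.items()}

    def step(self, pgrads: dict[str, dict[str, np.ndarray]]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for layer, gd in pgrads.items():
            for name, g in gd.items():
                m = self.m[layer][name]
                v = self.v[layer][name]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * (g * g)
                update = (self.lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)
                self.net.params[layer][name] -= update.astype(F32)
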