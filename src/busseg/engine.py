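"""NumPy execution engine for the layer graphs.

Interprets a :class:`busseg.graph.LayerGraph` with explicit forward and
backward passes.  Convolutions and transposed convolutions are lowered
to im2col + matrix multiplication so the heavy lifting runs in BLAS;
the transposed convolution (and the input-gradient of a convolution,
which is the same operation) is realized by zero-stuffing the map by
the stride and correlating with the spatially flipped, channel-swapped
kernel.

Tensors are NCHW.  Weight layouts:

* conv   — W: (filters, in_channels, k, k), b: (filters,)
* deconv — W: (in_channels, out_channels, 4, 4), b: (out_channels,);
  geometry chosen so a stride-s deconv multiplies the spatial size by
  exactly s (padding (4 - s) / 2).

Batch normalization keeps running statistics inside the parameter store
(keys prefixed ``running_``, excluded from gradient updates); inference
uses them, so prediction is deterministic.  Dropout draws its masks
from an explicit generator passed to the training-mode forward.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .graph import LayerGraph

__all__ = [
    "init_parameters",
    "forward",
    "loss_and_gradients",
    "softmax_probs",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
#: parameter keys updated by the optimizer
TRAINABLE_KEYS = ("W", "b", "gamma", "beta")
#: weight init: zero-mean Gaussian, std 0.01; biases zero
WEIGHT_INIT_STD = 0.01


# ---------------------------------------------------------------------------
# im2col primitives

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, C*k*k, L) patch matrix plus output spatial size."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def _conv_core(x, W, stride, pad):
    """Cross-correlation; W: (F, C, k, k)."""
    f, c, k, _ = W.shape
    cols, oh, ow = _im2col(x, k, stride, pad)
    y = np.matmul(W.reshape(f, -1)[None], cols)  # (N, F, L)
    return y.reshape(x.shape[0], f, oh, ow), cols


def _zero_stuff(x, stride):
    if stride == 1:
        return x
    n, c, h, w = x.shape
    z = np.zeros((n, c, (h - 1) * stride + 1, (w - 1) * stride + 1), dtype=x.dtype)
    z[:, :, ::stride, ::stride] = x
    return z


def _conv_transpose_core(g, W, stride, pad, out_hw):
    """Adjoint of _conv_core w.r.t. its input.

    g: (N, F, h, w) gradient-like map; W: (F, C, k, k); output (N, C, *out_hw).
    """
    f, c, k, _ = W.shape
    z = _zero_stuff(g, stride)
    wt = W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, F, k, k), flipped
    y, _ = _conv_core(np.pad(z, ((0, 0), (0, 0), (k - 1 - pad,) * 2, (k - 1 - pad,) * 2)),
                      wt, 1, 0)
    assert y.shape[2:] == tuple(out_hw), (y.shape, out_hw)
    return y


def _conv_dw(dy, x, k, stride, pad):
    """Weight gradient of _conv_core: (F, C, k, k)."""
    cols, _, _ = _im2col(x, k, stride, pad)
    f = dy.shape[1]
    dy_flat = dy.reshape(dy.shape[0], f, -1)
    dw = np.tensordot(dy_flat, cols, axes=([0, 2], [0, 2]))  # (F, C*k*k)
    return dw.reshape(f, x.shape[1], k, k)


# ---------------------------------------------------------------------------
# parameter initialization

def init_parameters(
    g: LayerGraph, seed: int, input_side: int | None = None, dtype=np.float32
) -> dict:
    """Gaussian N(0, 0.01^2) conv/deconv weights, zero biases, unit
    batchnorm scale, zero offset; deterministic per seed."""
    from .graph import infer_shapes

    rng = np.random.default_rng(seed)
    shapes = infer_shapes(g, input_side)
    params: dict[str, dict[str, np.ndarray]] = {}
    for name in g.topological_order():
        layer = g.layer(name)
        hp = layer.hyperparams
        if layer.kind == "conv":
            (pred,) = g.predecessors(name)
            cin = shapes[pred][0]
            f, k = hp["filters"], hp["kernel"]
            params[name] = {
                "W": rng.normal(0.0, WEIGHT_INIT_STD, (f, cin, k, k)).astype(dtype),
                "b": np.zeros(f, dtype=dtype),
            }
        elif layer.kind == "deconv":
            (pred,) = g.predecessors(name)
            cin = shapes[pred][0]
            f, k = hp["filters"], hp["kernel"]
            params[name] = {
                "W": rng.normal(0.0, WEIGHT_INIT_STD, (cin, f, k, k)).astype(dtype),
                "b": np.zeros(f, dtype=dtype),
            }
        elif layer.kind == "batchnorm":
            (pred,) = g.predecessors(name)
            c = shapes[pred][0]
            params[name] = {
                "gamma": np.ones(c, dtype=dtype),
                "beta": np.zeros(c, dtype=dtype),
                "running_mean": np.zeros(c, dtype=dtype),
                "running_var": np.ones(c, dtype=dtype),
            }
    return params


# ---------------------------------------------------------------------------
# forward / backward

def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Channel softmax, numerically stabilized."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_graph(g, params, x, training, rng):
    """Run the graph; returns (activations, caches) keyed by layer name."""
    acts: dict[str, np.ndarray] = {}
    caches: dict[str, tuple] = {}
    for name in g.topological_order():
        layer = g.layer(name)
        hp = layer.hyperparams
        kind = layer.kind
        if kind == "input":
            acts[name] = x
            continue
        preds = g.predecessors(name)
        xin = acts[preds[0]]
        if kind == "conv":
            p = params[name]
            y, cols = _conv_core(xin, p["W"], hp["stride"], hp["padding"])
            y += p["b"][None, :, None, None]
            acts[name] = y
            caches[name] = ("conv", xin.shape)
        elif kind == "deconv":
            p = params[name]
            oh = (xin.shape[2] - 1) * hp["stride"] + hp["kernel"] - 2 * hp["padding"]
            y = _conv_transpose_core(xin, p["W"], hp["stride"], hp["padding"], (oh, oh))
            y += p["b"][None, :, None, None]
            acts[name] = y
            caches[name] = ("deconv",)
        elif kind == "batchnorm":
            p = params[name]
            if training:
                mean = xin.mean(axis=(0, 2, 3))
                var = xin.var(axis=(0, 2, 3))
                p["running_mean"] = (
                    (1 - _BN_MOMENTUM) * p["running_mean"] + _BN_MOMENTUM * mean
                ).astype(p["running_mean"].dtype)
                p["running_var"] = (
                    (1 - _BN_MOMENTUM) * p["running_var"] + _BN_MOMENTUM * var
                ).astype(p["running_var"].dtype)
            else:
                mean, var = p["running_mean"], p["running_var"]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (xin - mean[None, :, None, None]) * inv_std[None, :, None, None]
            acts[name] = p["gamma"][None, :, None, None] * xhat + p["beta"][None, :, None, None]
            caches[name] = ("batchnorm", xhat, inv_std)
        elif kind == "relu":
            acts[name] = np.maximum(xin, 0)
            caches[name] = ("relu",)
        elif kind == "maxpool":
            if hp["padding"] == "same":  # 2x2, stride 1, size-preserving
                xp = np.pad(xin, ((0, 0), (0, 0), (0, 1), (0, 1)),
                            constant_values=-np.inf)
                win = sliding_window_view(xp, (2, 2), axis=(2, 3))
                flat = win.reshape(win.shape[:4] + (4,))
                idx = flat.argmax(axis=-1)
                acts[name] = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
                caches[name] = ("maxpool_same", idx)
            else:  # 2x2, stride 2
                n, c, h, w = xin.shape
                win = xin.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
                flat = win.reshape(n, c, h // 2, w // 2, 4)
                idx = flat.argmax(axis=-1)
                acts[name] = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
                caches[name] = ("maxpool2", idx, (h, w))
        elif kind == "dropout":
            if training:
                ratio = hp["ratio"]
                mask = (rng.random(xin.shape) >= ratio).astype(xin.dtype)
                acts[name] = xin * mask / (1.0 - ratio)
                caches[name] = ("dropout", mask, ratio)
            else:
                acts[name] = xin
                caches[name] = ("identity",)
        elif kind == "concat":
            parts = [acts[p] for p in preds]
            acts[name] = np.concatenate(parts, axis=1)
            caches[name] = ("concat", [q.shape[1] for q in parts], preds)
        elif kind == "softmax":
            acts[name] = softmax_probs(xin)
            caches[name] = ("softmax",)
        elif kind == "pixelclass":
            acts[name] = xin
            caches[name] = ("identity",)
        else:  # pragma: no cover
            raise ValueError(f"unhandled layer kind {kind}")
    return acts, caches


def forward(g: LayerGraph, params: dict, images: np.ndarray) -> np.ndarray:
    """Inference pass: (N, H, W) or (N, 1, H, W) images -> (N, 2, H, W)
    per-pixel class probabilities (channel 0 background, 1 lesion)."""
    x = np.asarray(images)
    if x.ndim == 3:
        x = x[:, None]
    if x.ndim != 4 or x.shape[1] != 1:
        raise ValueError(f"expected (N, 1, H, W) input, got {x.shape}")
    side = g.layer(g.input_name).hyperparams["side"]
    if x.shape[2] != side or x.shape[3] != side:
        raise ValueError(f"input is {x.shape[2]}x{x.shape[3]}, graph expects {side}x{side}")
    dtype = np.float64
    for p in params.values():
        if "W" in p:
            dtype = p["W"].dtype
            break
    acts, _ = _forward_graph(g, params, x.astype(dtype), training=False, rng=None)
    return acts[g.output_name]


def loss_and_gradients(
    g: LayerGraph,
    params: dict,
    images: np.ndarray,
    masks: np.ndarray,
    rng: np.random.Generator,
):
    """Training pass: mean per-pixel cross-entropy and its gradients.

    The softmax and the multinomial logistic loss are fused: the
    gradient at the softmax input is (p - onehot(target)) / n_pixels.
    Returns (loss, grads) with grads matching the trainable parameter
    tree.
    """
    x = np.asarray(images)
    if x.ndim == 3:
        x = x[:, None]
    dtype = np.float64
    for p in params.values():
        if "W" in p:
            dtype = p["W"].dtype
            break
    x = x.astype(dtype)
    t = np.asarray(masks).astype(np.int64)
    acts, caches = _forward_graph(g, params, x, training=True, rng=rng)
    probs = acts[g.output_name]
    n, _, h, w = probs.shape
    m = n * h * w
    p_target = np.take_along_axis(probs, t[:, None], axis=1)[:, 0]
    loss = float(-np.log(np.maximum(p_target, 1e-12)).mean())

    # gradient w.r.t. softmax input (fused softmax + NLL)
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, t[:, None], 1.0, axis=1)
    dsoftmax_in = (probs - onehot) / m

    # reverse topological accumulation
    order = g.topological_order()
    grads_out: dict[str, np.ndarray] = {}
    param_grads: dict[str, dict[str, np.ndarray]] = {}

    def _accumulate(name, value):
        if name in grads_out:
            grads_out[name] = grads_out[name] + value
        else:
            grads_out[name] = value

    # seed: gradient flowing into the softmax layer's predecessor
    for name in reversed(order):
        layer = g.layer(name)
        kind = layer.kind
        preds = g.predecessors(name)
        if kind == "pixelclass":
            continue  # loss is seeded at the softmax layer below
        if kind == "softmax":
            _accumulate(preds[0], dsoftmax_in.astype(dtype))
            continue
        if kind == "input":
            continue
        dy = grads_out.get(name)
        if dy is None:
            continue
        hp = layer.hyperparams
        cache = caches[name]
        if kind == "conv":
            p = params[name]
            xin = acts[preds[0]]
            k, s, pad = hp["kernel"], hp["stride"], hp["padding"]
            param_grads[name] = {
                "W": _conv_dw(dy, xin, k, s, pad),
                "b": dy.sum(axis=(0, 2, 3)),
            }
            dx = _conv_transpose_core(dy, p["W"], s, pad, xin.shape[2:])
            _accumulate(preds[0], dx)
        elif kind == "deconv":
            p = params[name]
            xin = acts[preds[0]]
            k, s, pad = hp["kernel"], hp["stride"], hp["padding"]
            # adjoint pair of the forward: dx is a strided correlation of dy
            dx, _ = _conv_core(dy, p["W"], s, pad)
            param_grads[name] = {
                "W": _conv_dw(xin, dy, k, s, pad),
                "b": dy.sum(axis=(0, 2, 3)),
            }
            _accumulate(preds[0], dx)
        elif kind == "batchnorm":
            p = params[name]
            _, xhat, inv_std = cache
            axes = (0, 2, 3)
            mloc = dy.shape[0] * dy.shape[2] * dy.shape[3]
            dbeta = dy.sum(axis=axes)
            dgamma = (dy * xhat).sum(axis=axes)
            param_grads[name] = {"gamma": dgamma, "beta": dbeta}
            coef = (p["gamma"] * inv_std)[None, :, None, None]
            dx = coef * (
                dy
                - dbeta[None, :, None, None] / mloc
                - xhat * dgamma[None, :, None, None] / mloc
            )
            _accumulate(preds[0], dx)
        elif kind == "relu":
            _accumulate(preds[0], dy * (acts[preds[0]] > 0))
        elif kind == "maxpool":
            xin = acts[preds[0]]
            if cache[0] == "maxpool_same":
                idx = cache[1]
                n_, c_, h_, w_ = xin.shape
                dx = np.zeros((n_, c_, h_ + 1, w_ + 1), dtype=dy.dtype)
                for u in range(2):
                    for v in range(2):
                        sel = (idx == u * 2 + v) * dy
                        dx[:, :, u : u + h_, v : v + w_] += sel
                _accumulate(preds[0], dx[:, :, :h_, :w_])
            else:
                idx, (h_, w_) = cache[1], cache[2]
                n_, c_ = xin.shape[:2]
                flat = np.zeros((n_, c_, h_ // 2, w_ // 2, 4), dtype=dy.dtype)
                np.put_along_axis(flat, idx[..., None], dy[..., None], axis=-1)
                dx = (
                    flat.reshape(n_, c_, h_ // 2, w_ // 2, 2, 2)
                    .transpose(0, 1, 2, 4, 3, 5)
                    .reshape(n_, c_, h_, w_)
                )
                _accumulate(preds[0], dx)
        elif kind == "dropout":
            if cache[0] == "dropout":
                _, mask, ratio = cache
                _accumulate(preds[0], dy * mask / (1.0 - ratio))
            else:
                _accumulate(preds[0], dy)
        elif kind == "concat":
            _, channels, cpreds = cache
            offset = 0
            for pname, nc in zip(cpreds, channels):
                _accumulate(pname, dy[:, offset : offset + nc])
                offset += nc
        else:  # pragma: no cover
            raise ValueError(f"unhandled layer kind in backward: {kind}")
    return loss, param_grads
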