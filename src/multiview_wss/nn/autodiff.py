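"""Minimal reverse-mode automatic differentiation on numpy arrays.

Exactly the operator set the surrogate network needs: 3×3/1×1 convolution
(shift-and-matmul, no im2col materialization), 2^k max pooling, bilinear
up-sampling expressed as a pair of linear interpolation matrices, batch
normalization, ReLU/sigmoid, channel concatenation, and a foreground-masked
MSE. Every operator's gradient is verified against central finite
differences in the test suite.

Arrays are NHWC — channel-last keeps the inner matmuls contiguous, which is
what makes a pure-numpy training loop viable on one CPU. Computation keeps
the caller's dtype (float32 for training, float64 for gradient checks).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "max_pool",
    "upsample_bilinear",
    "batch_norm",
    "relu",
    "sigmoid",
    "concat",
    "masked_mse",
]


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        """Reverse-mode sweep from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           padding: int | None = None) -> Tensor:
    """Same-size stride-1 convolution; weight is (k, k, Cin, Cout).

    Computed as a sum of k² shifted matmuls: each kernel offset contributes
    ``x[:, i:i+H, j:j+W, :] @ weight[i, j]``, a contiguous (⋯, Cin)·(Cin,
    Cout) product.
    """
    x, weight = _as_tensor(x), _as_tensor(weight)
    B, H, W, Cin = x.shape
    kh, kw, Cin_w, Cout = weight.shape
    if Cin != Cin_w or kh != kw:
        raise ValueError("weight shape incompatible with input")
    k = kh
    pad = (k - 1) // 2 if padding is None else padding
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x.data
    Ho, Wo = H + 2 * pad - k + 1, W + 2 * pad - k + 1
    out = np.zeros((B, Ho, Wo, Cout), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            out += xp[:, i:i + Ho, j:j + Wo, :] @ weight.data[i, j]
    if bias is not None:
        out += bias.data
    parents = (x, weight) if bias is None else (x, weight, bias)
    result = Tensor(out, parents=parents)

    def _backward(g: np.ndarray) -> None:
        gf = g.reshape(-1, Cout)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gf.sum(axis=0))
        if weight.requires_grad:
            if k == 1:
                dw = (xp.reshape(-1, Cin).T @ gf).reshape(weight.shape)
            else:
                # one im2col copy + one GEMM beats k^2 strided reductions
                windows = np.lib.stride_tricks.sliding_window_view(
                    xp, (k, k), axis=(1, 2))  # (B, Ho, Wo, Cin, k, k)
                cols = windows.reshape(B * Ho * Wo, Cin * k * k)
                dw = (cols.T @ gf).reshape(Cin, k, k, Cout).transpose(1, 2, 0, 3)
            weight._accumulate(np.ascontiguousarray(dw))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, i:i + Ho, j:j + Wo, :] += g @ weight.data[i, j].T
            x._accumulate(dxp[:, pad:pad + H, pad:pad + W, :] if pad else dxp)

    result._backward = _backward
    return result


# ---------------------------------------------------------------------------
# Pooling / resampling
# ---------------------------------------------------------------------------

def max_pool(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping max pooling by an integer factor."""
    x = _as_tensor(x)
    B, H, W, C = x.shape
    if H % factor or W % factor:
        raise ValueError(f"spatial size {H}x{W} not divisible by {factor}")
    Ho, Wo = H // factor, W // factor
    blocks = (x.data.reshape(B, Ho, factor, Wo, factor, C)
              .transpose(0, 1, 3, 5, 2, 4).reshape(B, Ho, Wo, C, factor * factor))
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
    result = Tensor(out, parents=(x,))

    def _backward(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        dblocks = np.zeros((B, Ho, Wo, C, factor * factor), dtype=g.dtype)
        np.put_along_axis(dblocks, idx[..., None], g[..., None], axis=-1)
        dx = (dblocks.reshape(B, Ho, Wo, C, factor, factor)
              .transpose(0, 1, 4, 2, 5, 3).reshape(B, H, W, C))
        x._accumulate(dx)

    result._backward = _backward
    return result


@lru_cache(maxsize=None)
def _interp_matrix(n_in: int, factor: int) -> np.ndarray:
    """(n_in*factor, n_in) linear-interpolation matrix (half-pixel centers)."""
    n_out = n_in * factor
    src = (np.arange(n_out) + 0.5) / factor - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    frac = np.clip(src - i0, 0.0, 1.0)
    M = np.zeros((n_out, n_in))
    M[np.arange(n_out), i0] += 1.0 - frac
    M[np.arange(n_out), i1] += frac
    return M


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Bilinear up-sampling by an integer factor (separable linear maps)."""
    x = _as_tensor(x)
    B, H, W, C = x.shape
    Mh = _interp_matrix(H, factor).astype(x.data.dtype)
    Mw = _interp_matrix(W, factor).astype(x.data.dtype)
    # rows: (P,H)·(B,H,W,C) → (B,P,W,C); cols: (Q,W)·(B,P,W,C) → (B,P,Q,C)
    tmp = np.tensordot(Mh, x.data, axes=(1, 1)).transpose(1, 0, 2, 3)
    out = np.tensordot(Mw, tmp, axes=(1, 2)).transpose(1, 2, 0, 3)
    result = Tensor(np.ascontiguousarray(out), parents=(x,))

    def _backward(g: np.ndarray) -> None:
        if x.requires_grad:
            tmp_g = np.tensordot(Mw.T, g, axes=(1, 2)).transpose(1, 2, 0, 3)
            dx = np.tensordot(Mh.T, tmp_g, axes=(1, 1)).transpose(1, 0, 2, 3)
            x._accumulate(np.ascontiguousarray(dx))

    result._backward = _backward
    return result


# ---------------------------------------------------------------------------
# Normalization and activations
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization; updates running stats in place."""
    x = _as_tensor(x)
    axes = (0, 1, 2)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean = running_mean.astype(x.data.dtype)
        var = running_var.astype(x.data.dtype)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    out = gamma.data * xhat + beta.data
    result = Tensor(out, parents=(x, gamma, beta))

    def _backward(g: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if not x.requires_grad:
            return
        gs = gamma.data * inv_std
        if training:
            gm = g.mean(axis=axes)
            gxm = (g * xhat).mean(axis=axes)
            x._accumulate(gs * (g - gm - xhat * gxm))
        else:
            x._accumulate(gs * g)

    result._backward = _backward
    return result


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    result = Tensor(np.where(mask, x.data, 0.0), parents=(x,))

    def _backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * mask)

    result._backward = _backward
    return result


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    result = Tensor(s, parents=(x,))

    def _backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    result._backward = _backward
    return result


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    result = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                    parents=tuple(tensors))
    offsets = np.cumsum([0] + sizes)

    def _backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(np.ascontiguousarray(g[tuple(sl)]))

    result._backward = _backward
    return result


def masked_mse(pred: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean squared error over foreground pixels only.

    ``mask`` is (B, H, W) boolean; each masked pixel contributes the mean of
    its channel squared differences, so the result equals
    sum((pred-target)^2 * mask) / (N_e * C).
    """
    pred = _as_tensor(pred)
    target = np.asarray(target, dtype=pred.data.dtype)
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 3 or m.shape != pred.shape[:3]:
        raise ValueError("mask must be (B, H, W) matching the images")
    n_e = int(m.sum())
    if n_e == 0:
        raise ValueError("empty mask: no foreground pixels to average over")
    mb = m[..., None]
    diff = (pred.data - target) * mb
    denom = n_e * pred.shape[-1]
    result = Tensor(np.asarray((diff ** 2).sum() / denom), parents=(pred,))

    def _backward(g: np.ndarray) -> None:
        if pred.requires_grad:
            pred._accumulate((2.0 / denom) * diff * g)

    result._backward = _backward
    return result
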