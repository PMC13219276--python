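"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: :class:`Tensor` wraps an ``ndarray``,
records its parents and a backward closure, and :meth:`Tensor.backward`
walks the tape in reverse topological order.  Only the operations needed by
the convolution/attention classifier stack are provided; convolution is a
single fused primitive (im2col forward, col2im backward) rather than a
composition, both for speed and for exact gradient accounting.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "pad_replicate",
           "softmax_cross_entropy"]


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t: "Tensor") -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.data.shape))

        return Tensor._node(self.data + o.data, (self, o), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._node(-self.data, (self,), back)

    def __sub__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-o)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * self.data, o.data.shape))

        return Tensor._node(self.data * o.data, (self, o), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g * self.data / o.data**2, o.data.shape))

        return Tensor._node(self.data / o.data, (self, o), back)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, k: float):
        def back(g):
            if self.requires_grad:
                self._accum(g * k * self.data ** (k - 1))

        return Tensor._node(self.data**k, (self,), back)

    def __matmul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(o.data, -1, -2), self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, o.data.shape))

        return Tensor._node(self.data @ o.data, (self, o), back)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._node(out_data, (self,), back)

    def log(self):
        def back(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._node(np.log(self.data), (self,), back)

    def relu(self):
        mask = self.data > 0

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._node(self.data * mask, (self,), back)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def back(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return Tensor._node(s, (self,), back)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def back(g):
            if self.requires_grad:
                self._accum(g * (s + out_data * (1.0 - s)))

        return Tensor._node(out_data, (self,), back)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        """Max reduction; the gradient is split evenly among tied maxima."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def back(g):
            if not self.requires_grad:
                return
            kept = self.data.max(axis=axis, keepdims=True)
            mask = self.data == kept
            counts = mask.sum(axis=axis, keepdims=True)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(mask / counts * g)

        return Tensor._node(out_data, (self,), back)

    def max_detached(self, axis, keepdims: bool = True) -> "Tensor":
        """Max treated as a constant (for numerically stable softmax)."""
        return Tensor(self.data.max(axis=axis, keepdims=keepdims))

    def reshape(self, *shape):
        src = self.data.shape

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(src))

        return Tensor._node(self.data.reshape(*shape), (self,), back)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def back(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return Tensor._node(self.data.transpose(*axes), (self,), back)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - self.max_detached(axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def back(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), back)


def pad_replicate(x: Tensor, pad: int) -> Tensor:
    """Edge-replicate padding of the two trailing (spatial) axes."""
    B, C, H, W = x.data.shape
    iy = np.clip(np.arange(-pad, H + pad), 0, H - 1)
    jx = np.clip(np.arange(-pad, W + pad), 0, W - 1)

    def back(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            np.add.at(dx, (slice(None), slice(None), iy[:, None], jx[None, :]), g)
            x._accum(dx)

    return Tensor._node(x.data[:, :, iy[:, None], jx[None, :]], (x,), back)


def _conv_geometry(H, W, KH, KW, stride, padding, dilation):
    OH = (H + 2 * padding - dilation * (KH - 1) - 1) // stride + 1
    OW = (W + 2 * padding - dilation * (KW - 1) - 1) // stride + 1
    i0 = dilation * np.repeat(np.arange(KH), KW)
    j0 = dilation * np.tile(np.arange(KW), KH)
    i1 = stride * np.repeat(np.arange(OH), OW)
    j1 = stride * np.tile(np.arange(OW), OH)
    return OH, OW, i0[:, None] + i1[None, :], j0[:, None] + j1[None, :]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel geometry."""
    B, C, H, W = x.data.shape
    Co, Ci, KH, KW = weight.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    OH, OW, ii, jj = _conv_geometry(H, W, KH, KW, stride, padding, dilation)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = xp[:, :, ii, jj].reshape(B, C * KH * KW, OH * OW)
    Wm = weight.data.reshape(Co, C * KH * KW)
    out = (Wm @ cols).reshape(B, Co, OH, OW)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def back(g):
        gflat = g.reshape(B, Co, OH * OW)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.einsum("bop,bkp->ok", gflat, cols)
            weight._accum(gw.reshape(weight.data.shape))
        if x.requires_grad:
            dcols = np.einsum("ok,bop->bkp", Wm, gflat)
            dcols = dcols.reshape(B, C, KH * KW, OH * OW)
            dxp = np.zeros_like(xp)
            np.add.at(dxp, (slice(None), slice(None), ii, jj), dcols)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._node(out, parents, back)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                          class_weights: np.ndarray | None = None) -> Tensor:
    """Mean (class-weighted) cross-entropy over a batch of logits (B, C).

    Weighted form matches the usual convention: per-sample losses scaled by
    the weight of the true class and normalized by the sum of those weights.
    """
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    B = z.shape[0]
    w = np.ones(B) if class_weights is None else np.asarray(class_weights)[labels]
    wsum = w.sum()
    loss = -(w * logp[np.arange(B), labels]).sum() / wsum

    def back(g):
        if logits.requires_grad:
            p = np.exp(logp)
            grad = p * w[:, None]
            grad[np.arange(B), labels] -= w
            logits._accum(g * grad / wsum)

    return Tensor._node(loss, (logits,), back)
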