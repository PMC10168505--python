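"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operator set needed by the convolutional VAE:
dense layers, 1D convolution (stride 1, "same" padding), max pooling,
nearest-neighbour upsampling, ReLU, exp, and the arithmetic required by a
Gaussian VAE loss. Gradients flow through a dynamically built tape; call
``backward()`` on a scalar-valued :class:`Tensor`.

Deterministic given single-threaded numpy; no global state.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["Tensor", "Adam", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=_GRAD_ENABLED
                     and any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _sum_to_shape(np.asarray(grad), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        if np.isscalar(other):  # python scalars promote weakly: dtype kept
            c = float(other)

            def backward_s():
                self._accum(out.grad)

            out = self._make(self.data + c, (self,), backward_s)
            return out
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward():
            self._accum(out.grad)
            other._accum(out.grad)

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            self._accum(-out.grad)

        out = self._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        if np.isscalar(other):
            return self + (-float(other))
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        if np.isscalar(other):
            return (-self) + float(other)
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        if np.isscalar(other):
            c = float(other)

            def backward_s():
                self._accum(out.grad * c)

            out = self._make(self.data * c, (self,), backward_s)
            return out
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward():
            self._accum(out.grad * other.data)
            other._accum(out.grad * self.data)

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward():
            self._accum(out.grad * p * self.data ** (p - 1))

        out = self._make(out_data, (self,), backward)
        return out

    def exp(self):
        out_data = np.exp(self.data)

        def backward():
            self._accum(out.grad * out_data)

        out = self._make(out_data, (self,), backward)
        return out

    def relu(self):
        mask = self.data > 0

        def backward():
            self._accum(out.grad * mask)

        out = self._make(self.data * mask, (self,), backward)
        return out

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape

        def backward():
            self._accum(out.grad.reshape(orig))

        out = self._make(self.data.reshape(*shape), (self,), backward)
        return out

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 1) -> "Tensor":
        datas = [t.data for t in tensors]
        sizes = [d.shape[axis] for d in datas]
        out_data = np.concatenate(datas, axis=axis)
        offsets = np.cumsum([0] + sizes)

        def backward():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * out_data.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

        parents = tuple(tensors)
        out = tensors[0]._make(out_data, parents, backward)
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None):
        out_data = self.data.sum(axis=axis)

        def backward():
            g = out.grad
            if axis is not None:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    # -- linear algebra ------------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward():
            self._accum(out.grad @ other.data.T)
            other._accum(self.data.T @ out.grad)

        out = self._make(out_data, (self, other), backward)
        return out

    __matmul__ = matmul

    # -- neural-network ops --------------------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """Stride-1 cross-correlation with "same" zero padding.

        self: (B, C_in, L); weight: (C_out, C_in, K); bias: (C_out,).
        Output: (B, C_out, L).
        """
        x = self.data
        w = weight.data
        B, Cin, L = x.shape
        Cout, _, K = w.shape
        pl = (K - 1) // 2
        pr = K - 1 - pl
        # (B, L+K-1, Cin) channel-last layout keeps the K shifted batched
        # matmuls below BLAS-friendly (no im2col window gather)
        xt = np.empty((B, L + K - 1, Cin), dtype=x.dtype)
        xt[:, pl:pl + L, :] = x.transpose(0, 2, 1)
        xt[:, :pl, :] = 0.0
        xt[:, pl + L:, :] = 0.0
        acc = xt[:, 0:L, :] @ w[:, :, 0].T
        for j in range(1, K):
            acc += xt[:, j:j + L, :] @ w[:, :, j].T
        acc += bias.data
        out_data = acc.transpose(0, 2, 1)

        def backward():
            gt = np.ascontiguousarray(out.grad.transpose(0, 2, 1))  # (B,L,Cout)
            dw = np.empty_like(w)
            for j in range(K):
                dw[:, :, j] = np.tensordot(gt, xt[:, j:j + L, :],
                                           axes=([0, 1], [0, 1]))
            weight._accum(dw)
            bias._accum(gt.sum(axis=(0, 1)))
            if self.requires_grad:
                dxt = np.zeros_like(xt)
                for j in range(K):
                    dxt[:, j:j + L, :] += gt @ w[:, :, j]
                self._accum(dxt[:, pl:pl + L, :].transpose(0, 2, 1))

        out = self._make(out_data, (self, weight, bias), backward)
        return out

    def maxpool1d(self, factor: int) -> "Tensor":
        """Non-overlapping max pooling along the last axis (truncates remainder)."""
        x = self.data
        B, C, L = x.shape
        Lo = L // factor
        xr = x[:, :, : Lo * factor].reshape(B, C, Lo, factor)
        idx = xr.argmax(axis=3)
        out_data = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

        def backward():
            g = np.zeros((B, C, Lo, factor))
            np.put_along_axis(g, idx[..., None], out.grad[..., None], axis=3)
            gx = np.zeros_like(x)
            gx[:, :, : Lo * factor] = g.reshape(B, C, Lo * factor)
            self._accum(gx)

        out = self._make(out_data, (self,), backward)
        return out

    def upsample_to(self, target_len: int) -> "Tensor":
        """Nearest-neighbour upsampling of the last axis to ``target_len``."""
        B, C, L = self.data.shape
        src = (np.arange(target_len) * L) // target_len
        out_data = self.data[:, :, src]
        # src is non-decreasing: target positions form contiguous runs per
        # source index, so the backward pass is a segmented sum
        starts = np.searchsorted(src, np.arange(L), side="left")

        def backward():
            gx = np.add.reduceat(out.grad, starts, axis=2)
            empty = starts == np.append(starts[1:], target_len)
            if empty.any():  # source positions skipped by downsampling
                gx[:, :, empty] = 0.0
            self._accum(gx)

        out = self._make(out_data, (self,), backward)
        return out

    # -- backward pass -------------------------------------------------------
    def backward(self) -> None:
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
            if node._backward is not None:
                node._backward()
                # tear down the tape as it is consumed: breaks the
                # closure reference cycles and frees intermediate
                # activations/gradients immediately
                node._backward = None
                node._parents = ()
                node.grad = None


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        c1 = 1 - self.b1 ** self.t
        c2 = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            m, v = self.m[i], self.v[i]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * (g * g)
            denom = np.sqrt(v / c2)
            denom += self.eps
            p.data -= (self.lr / c1) * m / denom
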