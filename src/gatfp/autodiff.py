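"""A minimal vectorized reverse-mode autodiff engine on numpy arrays.

Only the operations the graph-attention encoder needs are implemented:
dense linear algebra, elementwise nonlinearities, row gather/scatter and
segment-wise softmax/sum/max (the sparse-attention primitives).  Gradients
are accumulated by topological-order backpropagation from a scalar loss.

This exists because the runtime environment ships no deep-learning
framework; correctness is established by finite-difference tests.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape*, inverting numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        # the backward closures reference their output tensor, forming
        # cycles; break them so batch graphs are freed promptly
        for t in topo:
            t._backward = None
            t._parents = ()

    # ---- construction helpers -------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ---- elementwise arithmetic -----------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def back():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.shape))

        out = self._make(out_data, (self, other), back)
        return out

    __radd__ = __add__

    def __neg__(self):
        def back():
            if self.requires_grad:
                self._accumulate(-out.grad)

        out = self._make(-self.data, (self,), back)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def back():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

        out = self._make(out_data, (self, other), back)
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def back():
            if self.requires_grad:
                self._accumulate(out.grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ out.grad)

        out = self._make(out_data, (self, other), back)
        return out

    # ---- nonlinearities --------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def back():
            if self.requires_grad:
                self._accumulate(out.grad * mask)

        out = self._make(self.data * mask, (self,), back)
        return out

    def leaky_relu(self, negative_slope: float = 0.2):
        slope = np.where(self.data > 0, 1.0, negative_slope)

        def back():
            if self.requires_grad:
                self._accumulate(out.grad * slope)

        out = self._make(self.data * slope, (self,), back)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def back():
            if self.requires_grad:
                self._accumulate(out.grad * s * (1.0 - s))

        out = self._make(s, (self,), back)
        return out

    def exp(self):
        e = np.exp(self.data)

        def back():
            if self.requires_grad:
                self._accumulate(out.grad * e)

        out = self._make(e, (self,), back)
        return out

    def log(self):
        def back():
            if self.requires_grad:
                self._accumulate(out.grad / self.data)

        out = self._make(np.log(self.data), (self,), back)
        return out

    # ---- shape ops -------------------------------------------------------

    def concat(self, others: list["Tensor"], axis: int = -1) -> "Tensor":
        parts = [self] + list(others)
        sizes = [p.data.shape[axis] for p in parts]
        out_data = np.concatenate([p.data for p in parts], axis=axis)
        offsets = np.cumsum([0] + sizes)

        def back():
            for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
                if p.requires_grad:
                    sl = [slice(None)] * out_data.ndim
                    sl[axis] = slice(lo, hi)
                    p._accumulate(out.grad[tuple(sl)])

        out = self._make(out_data, tuple(parts), back)
        return out

    def gather_rows(self, index: np.ndarray) -> "Tensor":
        """Rows ``self[index]``; backward scatter-adds into the source rows."""
        index = np.asarray(index, dtype=np.int64)

        def back():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, index, out.grad)
                self._accumulate(g)

        out = self._make(self.data[index], (self,), back)
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())

        out = self._make(out_data, (self,), back)
        return out

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    # ---- segment ops (sparse attention primitives) -----------------------

    def segment_sum(self, seg: np.ndarray, n_segments: int) -> "Tensor":
        """Sum rows sharing a segment id: out[s] = sum_{e: seg[e]=s} self[e]."""
        seg = np.asarray(seg, dtype=np.int64)
        out_data = np.zeros((n_segments,) + self.data.shape[1:])
        np.add.at(out_data, seg, self.data)

        def back():
            if self.requires_grad:
                self._accumulate(out.grad[seg])

        out = self._make(out_data, (self,), back)
        return out

    def segment_softmax(self, seg: np.ndarray, n_segments: int) -> "Tensor":
        """Softmax over rows sharing a segment id (numerically stabilized).

        Works on (E,) or (E, K) data; the softmax is per segment, per
        trailing column.
        """
        seg = np.asarray(seg, dtype=np.int64)
        x = self.data
        mx = np.full((n_segments,) + x.shape[1:], -np.inf)
        np.maximum.at(mx, seg, x)
        ex = np.exp(x - mx[seg])
        z = np.zeros((n_segments,) + x.shape[1:])
        np.add.at(z, seg, ex)
        y = ex / z[seg]

        def back():
            if self.requires_grad:
                dot = np.zeros((n_segments,) + x.shape[1:])
                np.add.at(dot, seg, out.grad * y)
                self._accumulate(y * (out.grad - dot[seg]))

        out = self._make(y, (self,), back)
        return out

    def segment_max(self, seg: np.ndarray, n_segments: int) -> "Tensor":
        """Per-segment elementwise max; gradient routes to the arg-max rows."""
        seg = np.asarray(seg, dtype=np.int64)
        out_data = np.full((n_segments,) + self.data.shape[1:], -np.inf)
        np.maximum.at(out_data, seg, self.data)
        winner = self.data == out_data[seg]
        # split gradient equally among ties so backward remains a linear map
        counts = np.zeros_like(out_data)
        np.add.at(counts, seg, winner.astype(np.float64))

        def back():
            if self.requires_grad:
                self._accumulate(winner * (out.grad / counts)[seg])

        out = self._make(out_data, (self,), back)
        return out


def parameter(rng: np.random.Generator, shape: tuple[int, ...],
              scale: float | None = None) -> Tensor:
    """Glorot-style initialized trainable tensor."""
    if scale is None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        fan_out = shape[-1]
        scale = np.sqrt(2.0 / (fan_in + fan_out))
    t = Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)
    return t


def zeros_parameter(shape: tuple[int, ...]) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from raw scores.

    Equivalent to BCE on sigmoid outputs but evaluated via the softplus
    identity ``softplus(z) - t*z`` for numerical stability.
    """
    t = np.asarray(targets, dtype=np.float64)
    z = logits
    # softplus(z) = max(z,0) + log1p(exp(-|z|)), built from primitives
    abs_mask = Tensor(np.where(z.data >= 0, 1.0, 0.0))
    relu_z = z.relu()
    neg_abs = z * (2.0 * abs_mask - 1.0) * (-1.0)
    softplus = relu_z + (neg_abs.exp() + 1.0).log()
    loss = softplus - z * t
    return loss.mean()


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = params
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)
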