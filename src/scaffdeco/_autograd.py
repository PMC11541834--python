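"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for gated recurrent networks with attention: broadcast
add/mul, (batched) matmul, tanh/sigmoid, reshape/concat/slice/stack, embedding
lookup, softmax and a fused masked cross-entropy.  Gradients accumulate into
``Tensor.grad``; ``backward()`` runs a topological sweep from a scalar loss.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, parents=(), backward_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # ------------------------------------------------------------- ops
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        out.backward_fn = backward
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        out.backward_fn = backward
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, (self, other))
        a, b = self.data, other.data

        def backward(g):
            if a.ndim == 1 or b.ndim == 1:
                raise NotImplementedError("matmul backward needs >=2-D operands")
            ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), self.shape)
            gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, other.shape)
            return ga, gb

        out.backward_fn = backward
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, (self,))
        out.backward_fn = lambda g: (g * (1.0 - y * y),)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, (self,))
        out.backward_fn = lambda g: (g * y * (1.0 - y),)
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out.backward_fn = lambda g: (g.reshape(self.shape),)
        return out

    def slice_last(self, start: int, stop: int):
        """Static slice along the last axis."""
        out = Tensor(self.data[..., start:stop], (self,))

        def backward(g):
            full = np.zeros(self.shape)
            full[..., start:stop] = g
            return (full,)

        out.backward_fn = backward
        return out

    def sum(self):
        out = Tensor(self.data.sum(), (self,))
        out.backward_fn = lambda g: (np.full(self.shape, g),)
        return out

    # ---------------------------------------------------------- backward
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() starts from a scalar")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node.backward_fn is None or node.grad is None:
                continue
            for parent, g in zip(node.parents, node.backward_fn(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


def parameter(shape, rng: np.random.Generator, scale: float | None = None) -> Tensor:
    """Trainable tensor with uniform Glorot-style init."""
    if scale is None:
        fan = sum(shape[-2:]) if len(shape) > 1 else shape[0]
        scale = np.sqrt(6.0 / fan)
    return Tensor(rng.uniform(-scale, scale, shape), requires_grad=True)


def concat_last(tensors: list[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=-1), tuple(tensors))
    widths = [t.shape[-1] for t in tensors]

    def backward(g):
        grads, at = [], 0
        for w in widths:
            grads.append(g[..., at:at + w])
            at += w
        return tuple(grads)

    out.backward_fn = backward
    return out


def stack_axis1(tensors: list[Tensor]) -> Tensor:
    """Stack (B, H) tensors into (B, T, H)."""
    out = Tensor(np.stack([t.data for t in tensors], axis=1), tuple(tensors))
    out.backward_fn = lambda g: tuple(g[:, t, :] for t in range(len(tensors)))
    return out


def embedding(weights: Tensor, indices: np.ndarray) -> Tensor:
    """Row gather: (V, E) weights indexed by integer array of any shape."""
    out = Tensor(weights.data[indices], (weights,))

    def backward(g):
        full = np.zeros_like(weights.data)
        np.add.at(full, indices.reshape(-1), g.reshape(-1, weights.shape[-1]))
        return (full,)

    out.backward_fn = backward
    return out


def softmax_last(x: Tensor, additive_mask: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis; ``additive_mask`` (e.g. −1e9 at padding)
    is added to the logits first."""
    z = x.data if additive_mask is None else x.data + additive_mask
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(s, (x,))

    def backward(g):
        dot = (g * s).sum(axis=-1, keepdims=True)
        return ((g - dot) * s,)

    out.backward_fn = backward
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray, weights: np.ndarray) -> tuple[Tensor, float]:
    """Weighted token cross-entropy.

    ``logits`` is (N, V), ``targets`` (N,) ints, ``weights`` (N,) floats
    (0 for padding).  Returns (summed loss Tensor, total weight) so the
    caller can form a per-token mean.
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1))
    n = np.arange(targets.size)
    nll = logsumexp - z[n, targets]
    total = float((nll * weights).sum())
    out = Tensor(total, (logits,))
    softmax = np.exp(z) / np.exp(z).sum(axis=-1, keepdims=True)

    def backward(g):
        grad = softmax.copy()
        grad[n, targets] -= 1.0
        return (g * grad * weights[:, None],)

    out.backward_fn = backward
    return out, float(weights.sum())


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
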