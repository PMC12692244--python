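"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
``backward()`` propagates gradients through the recorded graph in reverse
topological order.  The op set is exactly what the spectral network needs:
broadcast arithmetic, (batched) matmul, ReLU/sigmoid, softmax/log-softmax,
layer normalisation, same-padded 1-D convolution, dropout, reshape/transpose
and axis reductions.  Everything runs in float64 so analytic gradients can be
checked against central finite differences to tight tolerances.

The :class:`AdamW` optimiser implements decoupled weight decay; parameters can
opt out of decay (biases, layer-norm affines).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "AdamW", "set_default_dtype", "get_default_dtype"]

_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the dtype new Tensors coerce to (float64 default, float32 for speed)."""
    global _DTYPE
    dtype = np.dtype(dtype)
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be float32 or float64")
    _DTYPE = dtype.type


def get_default_dtype():
    return _DTYPE


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reverse NumPy broadcasting: reduce grad down to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum away leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "no_decay")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.no_decay = False

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        # grad buffers are only ever rebound, never mutated in place, so
        # storing a view/alias of an upstream grad is safe and avoids copies
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)
        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division only by python scalars")
        return self * (1.0 / scalar)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, other.data.swapaxes(-1, -2))
                self._accumulate(_sum_to_shape(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(self.data.swapaxes(-1, -2), g)
                other._accumulate(_sum_to_shape(gb, other.data.shape))
        out._backward = bw
        return out

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def transpose(self, axes) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(int(i) for i in np.argsort(axes))
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))
        out._backward = bw
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))
        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))
        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)
        out._backward = bw
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, parents=(self,))

        def bw(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accumulate(s * (g - dot))
        out._backward = bw
        return out

    def log_softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        logp = z - lse
        out = Tensor(logp, parents=(self,))

        def bw(g):
            if self.requires_grad:
                p = np.exp(logp)
                self._accumulate(g - p * g.sum(axis=axis, keepdims=True))
        out._backward = bw
        return out

    # -- fused layers ------------------------------------------------------

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Normalise over the last axis, then affine (gamma, beta)."""
        d = self.data.shape[-1]
        lead = self.data.shape[:-1]
        x2 = self.data.reshape(-1, d)
        mu = np.einsum("ij->i", x2) / d
        cx = x2 - mu[:, None]
        var = np.einsum("ij,ij->i", cx, cx) / d
        inv = (1.0 / np.sqrt(var + eps))[:, None]
        xhat2 = cx * inv
        xhat = xhat2.reshape(self.data.shape)
        out = Tensor(xhat * gamma.data + beta.data, parents=(self, gamma, beta))

        def bw(g):
            g2 = g.reshape(-1, d)
            if gamma.requires_grad:
                gamma._accumulate(np.einsum("ij,ij->j", g2, xhat2))
            if beta.requires_grad:
                beta._accumulate(g2.sum(axis=0))
            if self.requires_grad:
                dxhat = g2 * gamma.data
                m1 = (np.einsum("ij->i", dxhat) / d)[:, None]
                m2 = (np.einsum("ij,ij->i", dxhat, xhat2) / d)[:, None]
                gx = inv * (dxhat - m1 - xhat2 * m2)
                self._accumulate(gx.reshape(self.data.shape))
        out._backward = bw
        return out

    def dropout(self, p: float, rng: np.random.Generator | None,
                training: bool) -> "Tensor":
        """Inverted dropout; identity when not training or p == 0."""
        if not training or p <= 0.0:
            return self
        mask = ((rng.random(self.data.shape) >= p).astype(self.data.dtype)
                / self.data.dtype.type(1.0 - p))
        out = Tensor(self.data * mask, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)
        out._backward = bw
        return out

    def affine(self, W: "Tensor", b: "Tensor") -> "Tensor":
        """x @ W + b with leading axes flattened into one GEMM."""
        lead = self.data.shape[:-1]
        x2 = self.data.reshape(-1, self.data.shape[-1])
        y = x2 @ W.data + b.data
        out = Tensor(y.reshape(*lead, W.data.shape[1]), parents=(self, W, b))

        def bw(g):
            g2 = g.reshape(-1, W.data.shape[1])
            if W.requires_grad:
                W._accumulate(x2.T @ g2)
            if b.requires_grad:
                b._accumulate(g2.sum(axis=0))
            if self.requires_grad:
                self._accumulate((g2 @ W.data.T).reshape(self.data.shape))
        out._backward = bw
        return out

    def conv1d_same(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """Same-padded 1-D convolution.

        input (B, L, C_in), weight (K, C_in, C_out) with K odd, bias (C_out).
        """
        x = self.data
        K, c_in, c_out = weight.data.shape
        if K % 2 == 0:
            raise ValueError("kernel width must be odd for same padding")
        B, L, _ = x.shape
        pad = K // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        # im2col: one large GEMM instead of K batched small ones
        cols = np.empty((B, L, K * c_in), dtype=x.dtype)
        for k in range(K):
            cols[:, :, k * c_in:(k + 1) * c_in] = xp[:, k:k + L, :]
        w2 = weight.data.reshape(K * c_in, c_out)
        y = (cols.reshape(B * L, K * c_in) @ w2).reshape(B, L, c_out) + bias.data
        out = Tensor(y, parents=(self, weight, bias))

        def bw(g):
            g2 = g.reshape(B * L, c_out)
            if bias.requires_grad:
                bias._accumulate(g2.sum(axis=0))
            if weight.requires_grad:
                gw = cols.reshape(B * L, K * c_in).T @ g2
                weight._accumulate(gw.reshape(K, c_in, c_out))
            if self.requires_grad:
                gcols = (g2 @ w2.T).reshape(B, L, K * c_in)
                gxp = np.zeros_like(xp)
                for k in range(K):
                    gxp[:, k:k + L, :] += gcols[:, :, k * c_in:(k + 1) * c_in]
                self._accumulate(gxp[:, pad:pad + L, :])
        out._backward = bw
        return out


def scaled_dot_attention(Q: Tensor, K: Tensor, V: Tensor) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V as one fused node (batched over leading axes)."""
    d_k = Q.data.shape[-1]
    scale = 1.0 / np.sqrt(d_k)
    s = np.matmul(Q.data, K.data.swapaxes(-1, -2)) * scale
    shape = s.shape
    L = shape[-1]
    n_mat = int(np.prod(shape[:-2])) if len(shape) > 2 else 1
    # stability shift per attention matrix: subtracting any constant from a
    # row leaves softmax exact, and one long contiguous max per matrix is far
    # cheaper than many short-axis reductions
    flat = s.reshape(n_mat, -1)
    flat -= flat.max(axis=1, keepdims=True)
    e2 = np.exp(s.reshape(-1, L))
    a2 = e2 * (1.0 / np.einsum("ij->i", e2))[:, None]
    a = a2.reshape(shape)
    out = Tensor(np.matmul(a, V.data), parents=(Q, K, V))

    def bw(g):
        if V.requires_grad:
            V._accumulate(np.matmul(a.swapaxes(-1, -2), g))
        if Q.requires_grad or K.requires_grad:
            ga = np.matmul(g, V.data.swapaxes(-1, -2))
            dot = np.einsum("ij,ij->i", ga.reshape(-1, L), a2)
            gs = a * (ga - dot.reshape(shape[:-1] + (1,)))
            if Q.requires_grad:
                Q._accumulate(np.matmul(gs, K.data) * scale)
            if K.requires_grad:
                K._accumulate(np.matmul(gs.swapaxes(-1, -2), Q.data) * scale)
    out._backward = bw
    return out


def Parameter(data, no_decay: bool = False) -> Tensor:
    t = Tensor(np.array(data, dtype=float), requires_grad=True)
    t.no_decay = no_decay
    return t


class AdamW:
    """Adam with decoupled weight decay.

    Decay multiplies the parameter by ``(1 - lr*weight_decay)`` before the
    Adam step; parameters flagged ``no_decay`` (biases, norm affines) skip it.
    """

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            if self.weight_decay and not p.no_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * p.grad ** 2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
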