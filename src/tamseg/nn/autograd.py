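"""A compact reverse-mode automatic-differentiation engine on NumPy arrays.

Provides exactly the operations the segmentation networks and losses need:
broadcasting arithmetic, matmul, reductions, indexing with scatter-add
backward, 2-D convolution (stride / dilation / groups) via im2col, 2×2 max
pooling, nearest-neighbour upsampling and a fused, numerically stable
weighted softmax cross-entropy.  Gradients are accumulated by topological
backward traversal from a scalar loss.

Arrays are float32 by default; the graph is rebuilt every forward pass
(define-by-run), so Python control flow works naturally.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "maxpool2x2", "upsample_nearest",
           "weighted_softmax_ce", "pad2d", "stack"]

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(DTYPE, copy=False)
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- autodiff ---------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        grad = grad.astype(DTYPE, copy=False)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)

        return self._make(out_data, (self, other), backward)

    # -- elementwise ------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / np.maximum(out_data, 1e-12))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    # -- reductions / shaping --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(out_data, (self,), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(g):
            pieces = np.split(g, len(tensors), axis=axis)
            for t, piece in zip(tensors, pieces):
                if t.requires_grad:
                    t._accum(np.squeeze(piece, axis=axis))

        out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])

        out._backward = backward
    return out


def pad2d(x: Tensor, pad: int) -> Tensor:
    """Zero-pad the two trailing spatial axes of an (N,C,H,W) tensor."""
    if pad == 0:
        return x
    out_data = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = Tensor(out_data)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def backward(g):
            x._accum(g[:, :, pad:-pad, pad:-pad])

        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# Convolution via im2col


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int):
    """(N,C,Hp,Wp) → windows (N, C, Ho, Wo, kh, kw), a strided view."""
    n, c, hp, wp = xp.shape
    eff_h = (kh - 1) * dilation + 1
    eff_w = (kw - 1) * dilation + 1
    ho = (hp - eff_h) // stride + 1
    wo = (wp - eff_w) // stride + 1
    sn, sc, sh, sw = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, ho, wo, kh, kw),
        strides=(sn, sc, sh * stride, sw * stride, sh * dilation, sw * dilation),
        writeable=False,
    )
    return view, ho, wo


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) on (N,C,H,W)."""
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    n, cin, hp, wp = xp.shape
    cout, cin_g, kh, kw = weight.shape
    assert cin == cin_g * groups, "channel/group mismatch"
    cols, ho, wo = _im2col(xp, kh, kw, stride, dilation)

    if groups == 1:
        mat = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cin * kh * kw)
        w2 = weight.data.reshape(cout, -1)
        out = (mat @ w2.T).reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    else:
        og = cout // groups
        outs = []
        for g in range(groups):
            cg = cols[:, g * cin_g:(g + 1) * cin_g]
            matg = cg.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cin_g * kh * kw)
            wg = weight.data[g * og:(g + 1) * og].reshape(og, -1)
            outs.append((matg @ wg.T).reshape(n, ho, wo, og))
        out = np.concatenate(outs, axis=-1).transpose(0, 3, 1, 2)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    result = Tensor(out)
    parents = [p for p in (x, weight, bias) if p is not None]
    if any(p.requires_grad for p in parents):
        result.requires_grad = True
        result._parents = tuple(parents)

        def backward(g):
            # g: (N, cout, Ho, Wo)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            g2 = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
            need_x = x.requires_grad
            grad_xp = np.zeros((n, cin, hp, wp), dtype=DTYPE) if need_x else None
            og = cout // groups
            for gi in range(groups):
                cg = cols[:, gi * cin_g:(gi + 1) * cin_g]
                matg = cg.transpose(0, 2, 3, 1, 4, 5).reshape(
                    n * ho * wo, cin_g * kh * kw)
                g2g = g2[:, gi * og:(gi + 1) * og]
                if weight.requires_grad:
                    gw = (g2g.T @ matg).reshape(og, cin_g, kh, kw)
                    if weight.grad is None:
                        weight.grad = np.zeros_like(weight.data)
                    weight.grad[gi * og:(gi + 1) * og] += gw
                if need_x:
                    gcols = (g2g @ weight.data[gi * og:(gi + 1) * og]
                             .reshape(og, -1)).reshape(n, ho, wo, cin_g, kh, kw)
                    sl = grad_xp[:, gi * cin_g:(gi + 1) * cin_g]
                    for i in range(kh):
                        for j in range(kw):
                            sl[:, :,
                               i * dilation:i * dilation + ho * stride:stride,
                               j * dilation:j * dilation + wo * stride:stride,
                               ] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if need_x:
                if padding:
                    x._accum(grad_xp[:, :, padding:-padding, padding:-padding])
                else:
                    x._accum(grad_xp)

        result._backward = backward
    return result


def maxpool2x2(x: Tensor) -> Tensor:
    """2×2 max pooling with stride 2; spatial dims must be even."""
    n, c, h, w = x.shape
    assert h % 2 == 0 and w % 2 == 0, "maxpool2x2 needs even spatial dims"
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    result = Tensor(out_data)
    if x.requires_grad:
        result.requires_grad = True
        result._parents = (x,)

        def backward(g):
            gwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
            np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
            gx = gwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
                0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
            x._accum(gx)

        result._backward = backward
    return result


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour spatial upsampling by an integer factor."""
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    result = Tensor(out_data)
    if x.requires_grad:
        result.requires_grad = True
        result._parents = (x,)
        n, c, h, w = x.shape

        def backward(g):
            gx = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
            x._accum(gx)

        result._backward = backward
    return result


def weighted_softmax_ce(logits: Tensor, target: np.ndarray,
                        weights: np.ndarray | None = None) -> Tensor:
    """Weighted pixel softmax cross-entropy, averaged over all pixels.

    ``logits``: (N, K, H, W); ``target``: (N, H, W) integer class indices;
    ``weights``: (N, H, W) positive multipliers (ones if omitted).  The
    average divides by pixel count, not by the weight total, so scaling all
    weights scales the loss.
    """
    z = logits.data
    n, k, h, w = z.shape
    t = np.asarray(target)
    if t.shape != (n, h, w):
        raise ValueError(f"target shape {t.shape} != {(n, h, w)}")
    wt = np.ones((n, h, w), dtype=DTYPE) if weights is None \
        else np.asarray(weights, dtype=DTYPE)
    if wt.shape != (n, h, w):
        raise ValueError(f"weight shape {wt.shape} != {(n, h, w)}")
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite logits in cross-entropy")

    zs = z - z.max(axis=1, keepdims=True)
    ez = np.exp(zs)
    sez = ez.sum(axis=1, keepdims=True)
    logp = zs - np.log(sez)
    ni, hi, wi = np.ogrid[:n, :h, :w]
    ce = -logp[ni, t, hi, wi]
    total = float((wt * ce).mean())

    result = Tensor(np.array(total, dtype=DTYPE))
    if logits.requires_grad:
        result.requires_grad = True
        result._parents = (logits,)

        def backward(g):
            p = ez / sez
            onehot = np.zeros_like(p)
            onehot[ni, t, hi, wi] = 1.0
            gx = (p - onehot) * wt[:, None] * (float(g) / (n * h * w))
            logits._accum(gx.astype(DTYPE))

        result._backward = backward
    return result
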