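"""Minimal reverse-mode automatic differentiation over numpy arrays.

Single-precision, define-by-run, eager tape.  Only the operations the
operator architectures need are provided: broadcasting arithmetic, matmul,
elementwise transcendentals, reductions, shape surgery, stride-1 2-D
convolution (via im2col + BLAS), 2x2 transposed convolution and max
pooling.  Gradients accumulate into ``Tensor.grad`` after ``backward()``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "conv_transpose2x2", "maxpool2x2",
           "pad2d"]

_DT = np.float32


def _asdata(x) -> np.ndarray:
    a = np.asarray(x)
    return a.astype(_DT) if a.dtype != _DT else a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over the axes broadcasting expanded."""
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
        self.data = _asdata(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents, backward) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out.requires_grad = any(p.requires_grad or p._parents for p in parents)
        out._backward = backward if out.requires_grad else None
        out._parents = tuple(parents) if out.requires_grad else ()
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_DT, copy=True) if g.dtype != _DT else g.copy()
        else:
            self.grad += g

    # -- properties -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    # -- autodiff driver ------------------------------------------------------
    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free graph references
        for node in topo:
            node._backward = None
            node._parents = ()

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))
        return Tensor._op(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)
        return Tensor._op(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))
        return Tensor._op(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        inv = 1.0 / other.data
        out_data = self.data * inv

        def bw(g):
            self._accum(_unbroadcast(g * inv, self.data.shape))
            other._accum(_unbroadcast(-g * out_data * inv, other.data.shape))
        return Tensor._op(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1.0))
        return Tensor._op(out_data, (self,), bw)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.data.ndim == 2 and other.data.ndim == 2:
                self._accum(g @ other.data.T)
                other._accum(self.data.T @ g)
            else:  # batched: rely on swapaxes + unbroadcast
                self._accum(_unbroadcast(g @ other.data.swapaxes(-1, -2),
                                         self.data.shape))
                other._accum(_unbroadcast(self.data.swapaxes(-1, -2) @ g,
                                          other.data.shape))
        return Tensor._op(out_data, (self, other), bw)

    # -- elementwise transcendentals -----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)
        return Tensor._op(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)
        return Tensor._op(np.log(self.data), (self,), bw)

    def sin(self):
        def bw(g):
            self._accum(g * np.cos(self.data))
        return Tensor._op(np.sin(self.data), (self,), bw)

    def cos(self):
        def bw(g):
            self._accum(-g * np.sin(self.data))
        return Tensor._op(np.cos(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data * out_data))
        return Tensor._op(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))
        return Tensor._op(out_data, (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / out_data)
        return Tensor._op(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)
        return Tensor._op(self.data * mask, (self,), bw)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data).astype(_DT)

        def bw(g):
            self._accum(g / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0))))
        return Tensor._op(out_data, (self,), bw)

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out_data = self.data * sig

        def bw(g):
            self._accum(g * sig * (1.0 + self.data * (1.0 - sig)))
        return Tensor._op(out_data, (self,), bw)

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        c = np.float32(np.sqrt(2.0 / np.pi))
        x = self.data
        inner = c * (x + 0.044715 * (x * x * x))
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def bw(g):
            dinner = c * (1.0 + 3 * 0.044715 * x * x)
            d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
            self._accum(g * d)
        return Tensor._op(out_data.astype(_DT), (self,), bw)

    # -- reductions and shape surgery ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))
        return Tensor._op(np.asarray(out_data, dtype=_DT), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))
        return Tensor._op(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(np.ascontiguousarray(g.transpose(inv)))
        return Tensor._op(np.ascontiguousarray(self.data.transpose(axes)),
                          (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)
        return Tensor._op(np.ascontiguousarray(out_data), (self,), bw)


# ----------------------------------------------------------------------------
# structural ops
# ----------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(np.ascontiguousarray(g[tuple(sl)]))
    return Tensor._op(out_data, tuple(tensors), bw)


def pad2d(x: Tensor, pad: tuple[int, int, int, int],
          mode: str = "reflect") -> Tensor:
    """Pad the last two axes of an NCHW tensor by (top, bottom, left, right)."""
    t, b, l, r = pad
    width = ((0, 0), (0, 0), (t, b), (l, r))
    out_data = np.pad(x.data, width, mode=mode)
    H, W = x.data.shape[2], x.data.shape[3]
    # The pad map is separable, so its adjoint is a pair of fold matrices.
    if mode == "reflect":
        ridx = np.pad(np.arange(H), (t, b), mode="reflect")
        cidx = np.pad(np.arange(W), (l, r), mode="reflect")
    else:
        ridx = np.pad(np.arange(H), (t, b), mode="constant", constant_values=-1)
        cidx = np.pad(np.arange(W), (l, r), mode="constant", constant_values=-1)
    rfold = np.zeros((H, H + t + b), dtype=_DT)
    for i, s in enumerate(ridx):
        if s >= 0:
            rfold[s, i] = 1.0
    cfold = np.zeros((W, W + l + r), dtype=_DT)
    for j, s in enumerate(cidx):
        if s >= 0:
            cfold[s, j] = 1.0

    def bw(g):
        x._accum(np.einsum("hi,ncij,wj->nchw", rfold, g, cfold,
                           optimize=True))
    return Tensor._op(out_data, (x,), bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NCHW layout."""
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    N, C, H, W = xp.shape
    F, _, kh, kw = w.data.shape
    Ho, Wo = H - kh + 1, W - kw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                ).reshape(N * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(F, -1).T
    out = cols @ wmat
    out_data = np.ascontiguousarray(
        out.reshape(N, Ho, Wo, F).transpose(0, 3, 1, 2))
    if b is not None:
        out_data += b.data.reshape(1, F, 1, 1)

    def bw(g):
        gy_mat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)
                                      ).reshape(N * Ho * Wo, F)
        gw = (cols.T @ gy_mat).T.reshape(F, C, kh, kw)
        w._accum(gw)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        # full correlation of g with the rotated kernel gives dx
        gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
        gwin = np.lib.stride_tricks.sliding_window_view(gp, (kh, kw),
                                                        axis=(2, 3))
        gcols = np.ascontiguousarray(gwin.transpose(0, 2, 3, 1, 4, 5)
                                     ).reshape(N * H * W, F * kh * kw)
        wrot = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # C,F,kh,kw
        wrot_mat = wrot.reshape(C, -1).T  # (F*kh*kw, C)
        gx = (gcols @ np.ascontiguousarray(wrot_mat)).reshape(N, H, W, C)
        gx = np.ascontiguousarray(gx.transpose(0, 3, 1, 2))
        if p:
            gx = np.ascontiguousarray(gx[:, :, p:-p, p:-p])
        x._accum(gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._op(out_data, parents, bw)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (exact 2x upsampling).

    ``w`` has shape (C_in, C_out, 2, 2); output spatial size doubles.
    """
    N, C, H, W = x.data.shape
    _, F, _, _ = w.data.shape
    tmp = np.tensordot(x.data, w.data, axes=([1], [0]))  # N,H,W,F,2,2
    out_data = np.ascontiguousarray(
        tmp.transpose(0, 3, 1, 4, 2, 5)).reshape(N, F, 2 * H, 2 * W)
    if b is not None:
        out_data += b.data.reshape(1, F, 1, 1)

    def bw(g):
        gblk = g.reshape(N, F, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5)
        # gblk: N,H,W,F,2,2
        gw = np.tensordot(x.data, gblk, axes=([0, 2, 3], [0, 1, 2]))
        w._accum(gw)  # C,F,2,2
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        gx = np.tensordot(gblk, w.data, axes=([3, 4, 5], [1, 2, 3]))
        x._accum(np.ascontiguousarray(gx.transpose(0, 3, 1, 2)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._op(out_data, parents, bw)


def maxpool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    assert H % 2 == 0 and W % 2 == 0, "maxpool2x2 needs even spatial dims"
    win = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    flat = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 3, 5)
                                ).reshape(N, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
        x._accum(np.ascontiguousarray(gx))
    return Tensor._op(np.ascontiguousarray(out_data), (x,), bw)
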