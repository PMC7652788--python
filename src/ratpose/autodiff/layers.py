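"""Neural-network layers with hand-derived backward passes.

Feature maps flow channels-last (``N, H, W, C``): the innermost axis is then
the GEMM contraction axis, so 3x3 stride-1 convolutions can be lowered onto
the *flattened padded image*: with rows padded left/right, shifting the flat
index by ``i * W_padded + j`` realises the (i, j) kernel tap, and each tap
becomes one GEMM on a contiguous slice — no im2col copies.  Wrap-around
artefacts land in the padding columns, which are cropped.  The backward pass
reuses the same layout for both the input and the weight gradients.

Weight initialisation is He-uniform from an explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

import contextlib
import math

import numpy as np

from .tensor import Tensor

# ---------------------------------------------------------------------------
# multiply-add accounting (analytic op cost, filled in during a forward pass)
# ---------------------------------------------------------------------------

_mac_counter: list[int] | None = None


@contextlib.contextmanager
def count_macs():
    """Context manager: yields a one-element list accumulating multiply-adds
    of every conv/linear executed inside."""
    global _mac_counter
    prev = _mac_counter
    _mac_counter = [0]
    try:
        yield _mac_counter
    finally:
        _mac_counter = prev


def _add_macs(n: int) -> None:
    if _mac_counter is not None:
        _mac_counter[0] += int(n)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Minimal module base: parameter / buffer registry and train-eval mode."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = value
        return value

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, t in self._params.items():
            yield prefix + name, t
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for cname, child in self._children.items():
            yield from child.named_buffers(prefix + cname + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: t.data.copy() for name, t in self.named_parameters()}
        out.update({"buf::" + name: b.copy() for name, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, t in params.items():
            t.data = np.asarray(state[name]).astype(t.data.dtype).reshape(t.data.shape)
        for name, _ in list(self.named_buffers()):
            self._assign_buffer(name, state["buf::" + name])

    def _assign_buffer(self, dotted: str, value: np.ndarray) -> None:
        mod: Module = self
        parts = dotted.split(".")
        for p in parts[:-1]:
            mod = mod._children[p]
        mod._buffers[parts[-1]][...] = value

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._children[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


# ---------------------------------------------------------------------------
# convolution (channels-last)
# ---------------------------------------------------------------------------

def _conv_1x1(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    xd, wd = x.data, weight.data  # (N,H,W,Ci), (1,1,Ci,Co)
    n, h, w, ci = xd.shape
    co = wd.shape[3]
    wm = wd.reshape(ci, co)
    flat = xd.reshape(-1, ci)
    out = (flat @ wm + bias.data).reshape(n, h, w, co)
    _add_macs(n * h * w * ci * co)

    def grad_x(g):
        return (g.reshape(-1, co) @ wm.T).reshape(xd.shape)

    def grad_w(g):
        return (flat.T @ g.reshape(-1, co)).reshape(wd.shape)

    def grad_b(g):
        return g.sum(axis=(0, 1, 2))

    return Tensor._make(out, [(x, grad_x), (weight, grad_w), (bias, grad_b)])


def _conv_3x3_s1(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-size 3x3 convolution via the flattened-padded-image lowering."""
    xd, wd = x.data, weight.data  # (N,H,W,Ci), (3,3,Ci,Co)
    n, h, w, ci = xd.shape
    co = wd.shape[3]
    # one genuine pad row/col plus two headroom rows at the bottom so every
    # tap's shifted slice stays in bounds
    xp = np.pad(xd, ((0, 0), (1, 3), (1, 1), (0, 0)))
    hp, wp = h + 4, w + 2
    big = xp.reshape(n * hp * wp, ci)
    lrows = n * hp * wp - 2 * wp - 2
    acc = np.empty((n * hp * wp, co), dtype=xd.dtype)
    tmp = np.empty((lrows, co), dtype=xd.dtype)
    first = True
    for i in range(3):
        for j in range(3):
            off = i * wp + j
            np.matmul(big[off : off + lrows], wd[i, j], out=tmp)
            if first:
                acc[:lrows] = tmp
                first = False
            else:
                acc[:lrows] += tmp
    out = acc.reshape(n, hp, wp, co)[:, :h, :w, :] + bias.data
    _add_macs(n * h * w * ci * co * 9)

    def grad_x(g):
        gp = np.zeros((n * hp * wp, co), dtype=g.dtype)
        gp.reshape(n, hp, wp, co)[:, :h, :w, :] = g
        gl = gp[:lrows]
        dbig = np.zeros((n * hp * wp, ci), dtype=g.dtype)
        buf = np.empty((lrows, ci), dtype=g.dtype)
        for i in range(3):
            for j in range(3):
                off = i * wp + j
                np.matmul(gl, wd[i, j].T, out=buf)
                dbig[off : off + lrows] += buf
        return dbig.reshape(n, hp, wp, ci)[:, 1 : 1 + h, 1 : 1 + w, :]

    def grad_w(g):
        gp = np.zeros((n * hp * wp, co), dtype=g.dtype)
        gp.reshape(n, hp, wp, co)[:, :h, :w, :] = g
        gl = gp[:lrows]
        dw = np.empty_like(wd)
        for i in range(3):
            for j in range(3):
                off = i * wp + j
                dw[i, j] = big[off : off + lrows].T @ gl
        return dw

    def grad_b(g):
        return g.sum(axis=(0, 1, 2))

    return Tensor._make(out, [(x, grad_x), (weight, grad_w), (bias, grad_b)])


def _conv_3x3_s2(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Downsampling 3x3 stride-2 convolution (even input dims, pad 1)."""
    xd, wd = x.data, weight.data
    n, h, w, ci = xd.shape
    co = wd.shape[3]
    if h % 2 or w % 2:
        raise ValueError(f"stride-2 conv needs even spatial dims, got {h}x{w}")
    ho, wo = h // 2, w // 2
    xp = np.pad(xd, ((0, 0), (1, 1), (1, 1), (0, 0)))
    views = {}
    out = np.zeros((n, ho, wo, co), dtype=xd.dtype)
    for i in range(3):
        for j in range(3):
            v = xp[:, i : i + 2 * ho - 1 : 2, j : j + 2 * wo - 1 : 2, :]
            views[(i, j)] = v
            out += v @ wd[i, j]
    out += bias.data
    _add_macs(n * ho * wo * ci * co * 9)

    def grad_x(g):
        dxp = np.zeros_like(xp)
        for i in range(3):
            for j in range(3):
                dxp[:, i : i + 2 * ho - 1 : 2, j : j + 2 * wo - 1 : 2, :] += (
                    g @ wd[i, j].T
                )
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]

    def grad_w(g):
        dw = np.empty_like(wd)
        for i in range(3):
            for j in range(3):
                dw[i, j] = np.tensordot(views[(i, j)], g, axes=([0, 1, 2], [0, 1, 2]))
        return dw

    def grad_b(g):
        return g.sum(axis=(0, 1, 2))

    return Tensor._make(out, [(x, grad_x), (weight, grad_w), (bias, grad_b)])


class Conv2d(Module):
    """2-D convolution, channels-last, kernel 1x1 (pad 0) or 3x3 (pad 1),
    stride 1 or 2.  Weight layout ``(kh, kw, C_in, C_out)``."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: int | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        if kernel_size not in (1, 3):
            raise ValueError("kernel_size must be 1 or 3")
        if padding is None:
            padding = kernel_size // 2
        if padding != kernel_size // 2:
            raise ValueError("padding must keep 'same' geometry (k // 2)")
        if stride not in (1, 2) or (kernel_size == 1 and stride != 1):
            raise ValueError("unsupported stride for this kernel size")
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        bound = math.sqrt(6.0 / fan_in)
        w = rng.uniform(
            -bound, bound, (kernel_size, kernel_size, in_channels, out_channels)
        )
        self.weight = self.register_parameter("weight", w.astype(dtype))
        self.bias = self.register_parameter("bias", np.zeros(out_channels, dtype=dtype))
        self.stride = stride
        self.padding = padding
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_channels:
            raise ValueError(
                f"conv expects {self.in_channels} input channels, got {x.shape[-1]}"
            )
        if self.kernel_size == 1:
            return _conv_1x1(x, self.weight, self.bias)
        if self.stride == 1:
            return _conv_3x3_s1(x, self.weight, self.bias)
        return _conv_3x3_s2(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = math.sqrt(6.0 / in_features)
        w = rng.uniform(-bound, bound, (out_features, in_features))
        self.weight = self.register_parameter("weight", w.astype(dtype))
        self.bias = self.register_parameter("bias", np.zeros(out_features, dtype=dtype))
        self.in_features = in_features
        self.out_features = out_features

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        _add_macs(n * self.in_features * self.out_features)
        wt = Tensor._make(self.weight.data.T, [(self.weight, lambda g: g.T)])
        return x @ wt + self.bias


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel (channels-last)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.gamma = self.register_parameter("gamma", np.ones(channels, dtype=dtype))
        self.beta = self.register_parameter("beta", np.zeros(channels, dtype=dtype))
        self.running_mean = self.register_buffer(
            "running_mean", np.zeros(channels, dtype=dtype)
        )
        self.running_var = self.register_buffer(
            "running_var", np.ones(channels, dtype=dtype)
        )
        self.eps = eps
        self.momentum = momentum
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        gamma, beta = self.gamma, self.beta
        if self.training:
            mean = xd.mean(axis=(0, 1, 2))
            var = xd.var(axis=(0, 1, 2))
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mean
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * var
        else:
            mean = self.running_mean
            var = self.running_var
        istd = (1.0 / np.sqrt(var + self.eps)).astype(xd.dtype)
        xhat = (xd - mean) * istd
        out = gamma.data * xhat + beta.data
        m = xd.shape[0] * xd.shape[1] * xd.shape[2]
        training = self.training

        def grad_x(g):
            gi = gamma.data * istd
            if not training:
                return g * gi
            gsum = g.sum(axis=(0, 1, 2))
            gx_sum = (g * xhat).sum(axis=(0, 1, 2))
            return gi / m * (m * g - gsum - xhat * gx_sum)

        def grad_gamma(g):
            return (g * xhat).sum(axis=(0, 1, 2))

        def grad_beta(g):
            return g.sum(axis=(0, 1, 2))

        return Tensor._make(out, [(x, grad_x), (gamma, grad_gamma), (beta, grad_beta)])


class MaxPool2d(Module):
    """2x2 max pooling with stride 2 (ties: first window element)."""

    def __init__(self, size: int = 2):
        super().__init__()
        if size != 2:
            raise ValueError("only 2x2 pooling is supported")

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"pooling needs even spatial dims, got {h}x{w}")
        win = (
            x.data.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h // 2, w // 2, 4, c)
        )
        idx = win.argmax(axis=3)
        out = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

        def grad_x(g):
            buf = np.zeros_like(win)
            np.put_along_axis(buf, idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
            return (
                buf.reshape(n, h // 2, w // 2, 2, 2, c)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(n, h, w, c)
            )

        return Tensor._make(out, [(x, grad_x)])


class UpsampleNearest2d(Module):
    """Nearest-neighbour spatial upsampling (channels-last)."""

    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        f = self.factor
        n, h, w, c = x.shape
        out = x.data.repeat(f, axis=1).repeat(f, axis=2)

        def grad_x(g):
            return g.reshape(n, h, f, w, f, c).sum(axis=(2, 4))

        return Tensor._make(out, [(x, grad_x)])


def smooth_l1_tensor(x: Tensor) -> Tensor:
    """Elementwise smooth-L1: ``0.5 x^2`` for ``|x| < 1`` else ``|x| - 0.5``."""
    xd = x.data
    inner = np.abs(xd) < 1
    out = np.where(inner, 0.5 * xd**2, np.abs(xd) - 0.5)

    def grad_x(g):
        return g * np.clip(xd, -1.0, 1.0)

    return Tensor._make(out, [(x, grad_x)])
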