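"""A compact 3D neural-network engine on numpy with manual backpropagation.

Provides exactly the pieces the age-regression backbones need: 3D
convolution (with strides, padding and channel groups), batch
normalization, ReLU, max and global-average pooling, fully connected
layers, and an Adam optimizer. Everything is float32, single device,
and deterministic given the ``numpy.random.Generator`` used at build time.

Convolutions are evaluated by looping over the (at most ``k^3``) kernel
offsets and contracting each strided input slice against the matching
kernel slab with ``einsum``; the backward pass reuses the same views, so
no im2col buffer of size ``N * D * H * W * C * k^3`` is ever materialized.

Modules cache their forward inputs, so the calling pattern is strictly
``forward`` then (optionally) ``backward`` on the same data.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool3d",
    "GlobalAvgPool3d",
    "Linear",
    "Sequential",
    "Adam",
    "state_dict",
    "load_state_dict",
    "transfer_parameters",
]


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: tracks named parameters, buffers and child modules."""

    def __init__(self) -> None:
        self._params: dict[str, Param] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}

    def add_param(self, name: str, value: np.ndarray) -> Param:
        p = Param(value)
        self._params[name] = p
        return p

    def add_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        return self._buffers[name]

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def named_buffers(self, prefix: str = ""):
        for name, _ in self._buffers.items():
            yield prefix + name, self
        for cname, child in self._children.items():
            yield from child.named_buffers(prefix + cname + ".")

    def parameters(self) -> list[Param]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    # subclasses implement forward(x, train=False) / backward(gy)


def state_dict(module: Module) -> dict[str, np.ndarray]:
    """Flat name -> array snapshot of parameters and buffers (copies)."""
    out = {name: p.value.copy() for name, p in module.named_parameters()}
    for name, owner in module.named_buffers():
        leaf = name.rsplit(".", 1)[-1] if "." in name else name
        out[name] = owner._buffers[leaf].copy()
    return out


def load_state_dict(module: Module, state: dict[str, np.ndarray], strict: bool = True) -> None:
    params = dict(module.named_parameters())
    buffers = {name: owner for name, owner in module.named_buffers()}
    for name, value in state.items():
        if name in params:
            if params[name].value.shape != value.shape:
                raise ValueError(f"shape mismatch for {name}")
            params[name].value[...] = value
        elif name in buffers:
            leaf = name.rsplit(".", 1)[-1] if "." in name else name
            buffers[name]._buffers[leaf][...] = value
        elif strict:
            raise KeyError(f"unexpected entry {name}")
    if strict:
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"missing entries {sorted(missing)}")


def transfer_parameters(
    source: dict[str, np.ndarray], target: Module
) -> tuple[list[str], list[str]]:
    """Copy every source entry whose name *and* shape match the target.

    Returns (transferred, skipped) name lists. This is the parameter-matching
    rule behind progressive input-size transfer: convolutions and norms carry
    over between input scales, while any layer whose shape changed (e.g. a
    re-sized head) keeps its fresh initialization.
    """
    params = dict(target.named_parameters())
    buffers = {name: owner for name, owner in target.named_buffers()}
    transferred, skipped = [], []
    for name, value in source.items():
        if name in params and params[name].value.shape == value.shape:
            params[name].value[...] = value
            transferred.append(name)
        elif name in buffers:
            leaf = name.rsplit(".", 1)[-1] if "." in name else name
            if buffers[name]._buffers[leaf].shape == value.shape:
                buffers[name]._buffers[leaf][...] = value
                transferred.append(name)
            else:
                skipped.append(name)
        else:
            skipped.append(name)
    return transferred, skipped


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, (tuple, list)):
        if len(v) != 3:
            raise ValueError("expected a length-3 tuple")
        return tuple(int(x) for x in v)  # type: ignore[return-value]
    return (int(v),) * 3


class Conv3d(Module):
    """3D convolution with 'same'-style default padding and channel groups."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel=3,
        stride=1,
        pad=None,
        groups: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.cin, self.cout, self.groups = in_channels, out_channels, groups
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must divide groups")
        self.k = _triple(kernel)
        self.s = _triple(stride)
        self.p = tuple(k // 2 for k in self.k) if pad is None else _triple(pad)
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * int(np.prod(self.k))
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels // groups, *self.k))
        self.weight = self.add_param("weight", w)
        self.b = self.add_param("bias", np.zeros(out_channels)) if bias else None

    def out_spatial(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        return tuple(
            (d + 2 * p - k) // s + 1 for d, k, s, p in zip(spatial, self.k, self.s, self.p)
        )  # type: ignore[return-value]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.cin:
            raise ValueError(f"shape mismatch: expected {self.cin} channels, got {x.shape[1]}")
        n = x.shape[0]
        pd, ph, pw = self.p
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        g, cg, og = self.groups, self.cin // self.groups, self.cout // self.groups
        xg = xp.reshape(n, g, cg, *xp.shape[2:])
        do, ho, wo = self.out_spatial(x.shape[2:])
        sd, sh, sw = self.s
        wg = self.weight.value.reshape(g, og, cg, *self.k)
        out = np.zeros((n, g, og, do, ho, wo), dtype=np.float32)
        for i in range(self.k[0]):
            for j in range(self.k[1]):
                for l in range(self.k[2]):
                    xs = xg[
                        :, :, :,
                        i : i + sd * (do - 1) + 1 : sd,
                        j : j + sh * (ho - 1) + 1 : sh,
                        l : l + sw * (wo - 1) + 1 : sw,
                    ]
                    out += np.einsum("goc,ngcdhw->ngodhw", wg[:, :, :, i, j, l], xs, optimize=True)
        self._cache = (xg, x.shape)
        out = out.reshape(n, self.cout, do, ho, wo)
        if self.b is not None:
            out += self.b.value[None, :, None, None, None]
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xg, x_shape = self._cache
        n = gy.shape[0]
        g, cg, og = self.groups, self.cin // self.groups, self.cout // self.groups
        do, ho, wo = gy.shape[2:]
        sd, sh, sw = self.s
        gyg = gy.reshape(n, g, og, do, ho, wo)
        wg = self.weight.value.reshape(g, og, cg, *self.k)
        gw = np.zeros_like(wg)
        gxg = np.zeros_like(xg)
        for i in range(self.k[0]):
            for j in range(self.k[1]):
                for l in range(self.k[2]):
                    sl = (
                        slice(None), slice(None), slice(None),
                        slice(i, i + sd * (do - 1) + 1, sd),
                        slice(j, j + sh * (ho - 1) + 1, sh),
                        slice(l, l + sw * (wo - 1) + 1, sw),
                    )
                    gw[:, :, :, i, j, l] = np.einsum(
                        "ngodhw,ngcdhw->goc", gyg, xg[sl], optimize=True
                    )
                    gxg[sl] += np.einsum(
                        "goc,ngodhw->ngcdhw", wg[:, :, :, i, j, l], gyg, optimize=True
                    )
        self.weight.grad += gw.reshape(self.weight.value.shape)
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 2, 3, 4))
        pd, ph, pw = self.p
        gxp = gxg.reshape(n, self.cin, *xg.shape[3:])
        d, h, w = x_shape[2:]
        return gxp[:, :, pd : pd + d, ph : ph + h, pw : pw + w]


class BatchNorm3d(Module):
    """Per-channel batch normalization over (N, D, H, W) with running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = self.add_param("weight", np.ones(channels))
        self.beta = self.add_param("bias", np.zeros(channels))
        self.add_buffer("running_mean", np.zeros(channels))
        self.add_buffer("running_var", np.ones(channels))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self._buffers["running_mean"] *= 1 - self.momentum
            self._buffers["running_mean"] += self.momentum * mean
            self._buffers["running_var"] *= 1 - self.momentum
            self._buffers["running_var"] += self.momentum * var
        else:
            mean = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        self._cache = (xhat, inv_std, train)
        return (self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)).astype(
            np.float32
        )

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std, was_train = self._cache
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        ghat = gy * self.gamma.value.reshape(shape)
        if not was_train:
            return (ghat * inv_std.reshape(shape)).astype(np.float32)
        gmean = ghat.mean(axis=axes).reshape(shape)
        gdot = (ghat * xhat).mean(axis=axes).reshape(shape)
        return (inv_std.reshape(shape) * (ghat - gmean - xhat * gdot)).astype(np.float32)


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0).astype(np.float32)


class MaxPool3d(Module):
    """Max pooling by kernel-offset sweep; ties go to the earliest offset."""

    def __init__(self, kernel=3, stride=2, pad=1) -> None:
        super().__init__()
        self.k, self.s, self.p = _triple(kernel), _triple(stride), _triple(pad)

    def out_spatial(self, spatial):
        return tuple(
            (d + 2 * p - k) // s + 1 for d, k, s, p in zip(spatial, self.k, self.s, self.p)
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pd, ph, pw = self.p
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)), constant_values=-np.inf)
        do, ho, wo = self.out_spatial(x.shape[2:])
        sd, sh, sw = self.s
        out = np.full(x.shape[:2] + (do, ho, wo), -np.inf, dtype=np.float32)
        arg = np.zeros_like(out, dtype=np.int16)
        idx = 0
        for i in range(self.k[0]):
            for j in range(self.k[1]):
                for l in range(self.k[2]):
                    xs = xp[
                        :, :,
                        i : i + sd * (do - 1) + 1 : sd,
                        j : j + sh * (ho - 1) + 1 : sh,
                        l : l + sw * (wo - 1) + 1 : sw,
                    ]
                    better = xs > out
                    out[better] = xs[better]
                    arg[better] = idx
                    idx += 1
        self._cache = (arg, x.shape, xp.shape)
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        arg, x_shape, xp_shape = self._cache
        gxp = np.zeros(xp_shape, dtype=np.float32)
        do, ho, wo = gy.shape[2:]
        sd, sh, sw = self.s
        idx = 0
        for i in range(self.k[0]):
            for j in range(self.k[1]):
                for l in range(self.k[2]):
                    sl = (
                        slice(None), slice(None),
                        slice(i, i + sd * (do - 1) + 1, sd),
                        slice(j, j + sh * (ho - 1) + 1, sh),
                        slice(l, l + sw * (wo - 1) + 1, sw),
                    )
                    gxp[sl] += np.where(arg == idx, gy, 0.0)
                    idx += 1
        pd, ph, pw = self.p
        d, h, w = x_shape[2:]
        return gxp[:, :, pd : pd + d, ph : ph + h, pw : pw + w]


class GlobalAvgPool3d(Module):
    """(N, C, D, H, W) -> (N, C) mean over the spatial axes."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4)).astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._shape
        return np.broadcast_to(gy[:, :, None, None, None] / (d * h * w), self._shape).astype(
            np.float32
        )


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        init_scale: float | None = None,
    ) -> None:
        super().__init__()
        self.fin, self.fout = in_features, out_features
        rng = rng or np.random.default_rng(0)
        std = init_scale if init_scale is not None else np.sqrt(2.0 / in_features)
        self.weight = self.add_param("weight", rng.normal(0.0, std, size=(out_features, in_features)))
        self.b = self.add_param("bias", np.zeros(out_features)) if bias else None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.fin:
            raise ValueError(f"shape mismatch: expected {self.fin} features, got {x.shape[1]}")
        self._x = x
        out = x @ self.weight.value.T
        if self.b is not None:
            out += self.b.value
        return out.astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.weight.grad += gy.T @ self._x
        if self.b is not None:
            self.b.grad += gy.sum(axis=0)
        return (gy @ self.weight.value).astype(np.float32)


class Sequential(Module):
    def __init__(self, layers: list[Module]) -> None:
        super().__init__()
        self.layers = layers
        for i, layer in enumerate(layers):
            self.add_child(str(i), layer)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class Adam:
    """Adam with classic L2 weight decay folded into the gradient.

    ``beta1`` is the first-moment coefficient (the "momentum" of the
    optimizer); ``lr`` may be rebound between steps by a scheduler.
    """

    def __init__(
        self,
        params: list[Param],
        lr: float = 3e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
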