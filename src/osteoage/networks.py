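"""3D CNN age regressors, the sex branch, and the three fusion strategies.

The regression model is ``age_hat = fc(concat(F_theta(X), g(sex)))`` where
``F_theta`` is a 3D convolutional backbone ending in global average pooling
and ``g`` embeds the binary sex code (0 = male, 1 = female) through a
32-wide fully connected layer. Four backbones are provided:

* ``resnet34_3d`` — basic residual blocks (two 3x3x3 convs + identity
  shortcut), stage layout [3, 4, 6, 3]; the mandible default.
* ``resnet50_3d`` — bottleneck blocks (1-3-1 convs, expansion 4), stage
  layout [3, 4, 6, 3]; the femur default.
* ``mobilenet_3d`` — depthwise-separable convolutions, depth-inflated from
  the MobileNet-V1 layout.
* ``squeezenet_3d`` — fire modules (squeeze 1x1x1, expand 1x1x1 + 3x3x3),
  depth-inflated from SqueezeNet v1.1.

Modalities are combined by **late** fusion (average the two single-modality
predictions), **middle** fusion (concatenate the two pooled feature vectors
with the sex embedding before one regression head; gradients flow into both
backbones), or **early** fusion (resample both voxels onto a shared grid
and stack them as two input channels of a single backbone).

Downsampling strides adapt per axis to the input shape (an axis shorter
than 4 voxels is no longer strided), so the same architectures run on
desk-scale grids; a ``scale`` factor shrinks all channel widths
proportionally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn

__all__ = [
    "NetworkConfig",
    "GenderBranch",
    "SingleModalityModel",
    "MiddleFusionModel",
    "LateFusionEnsemble",
    "build_backbone",
    "build_model",
    "gender_branch",
    "predict_single",
    "fuse_late",
    "resize_volume",
    "save_checkpoint",
    "load_checkpoint",
    "BACKBONES",
]

GENDER_WIDTH = 32


def _adaptive_stride(dims: tuple[int, int, int]) -> tuple[int, int, int]:
    return tuple(2 if d >= 4 else 1 for d in dims)  # type: ignore[return-value]


def _strided(dims, stride):
    return tuple((d + s - 1) // s for d, s in zip(dims, stride))


def _width(base: int, scale: float) -> int:
    return max(2, int(round(base * scale)))


class _Residual(nn.Module):
    """Shared forward/backward plumbing for basic and bottleneck blocks."""

    def __init__(self) -> None:
        super().__init__()
        self.body: nn.Sequential
        self.shortcut: nn.Sequential | None
        self.out_relu = nn.ReLU()

    def forward(self, x, train=False):
        out = self.body.forward(x, train)
        sc = self.shortcut.forward(x, train) if self.shortcut is not None else x
        return self.out_relu.forward(out + sc, train)

    def backward(self, gy):
        g = self.out_relu.backward(gy)
        gx = self.body.backward(g)
        if self.shortcut is not None:
            gx = gx + self.shortcut.backward(g)
        else:
            gx = gx + g
        return gx


class BasicBlock3d(_Residual):
    expansion = 1

    def __init__(self, cin, width, stride, rng):
        super().__init__()
        cout = width * self.expansion
        self.body = self.add_child(
            "body",
            nn.Sequential(
                [
                    nn.Conv3d(cin, width, 3, stride, rng=rng),
                    nn.BatchNorm3d(width),
                    nn.ReLU(),
                    nn.Conv3d(width, cout, 3, 1, rng=rng),
                    nn.BatchNorm3d(cout),
                ]
            ),
        )
        self.shortcut = None
        if stride != (1, 1, 1) or cin != cout:
            self.shortcut = self.add_child(
                "shortcut",
                nn.Sequential(
                    [nn.Conv3d(cin, cout, 1, stride, pad=0, rng=rng), nn.BatchNorm3d(cout)]
                ),
            )
        self.add_child("out_relu", self.out_relu)


class Bottleneck3d(_Residual):
    expansion = 4

    def __init__(self, cin, width, stride, rng):
        super().__init__()
        cout = width * self.expansion
        self.body = self.add_child(
            "body",
            nn.Sequential(
                [
                    nn.Conv3d(cin, width, 1, 1, pad=0, rng=rng),
                    nn.BatchNorm3d(width),
                    nn.ReLU(),
                    nn.Conv3d(width, width, 3, stride, rng=rng),
                    nn.BatchNorm3d(width),
                    nn.ReLU(),
                    nn.Conv3d(width, cout, 1, 1, pad=0, rng=rng),
                    nn.BatchNorm3d(cout),
                ]
            ),
        )
        self.shortcut = None
        if stride != (1, 1, 1) or cin != cout:
            self.shortcut = self.add_child(
                "shortcut",
                nn.Sequential(
                    [nn.Conv3d(cin, cout, 1, stride, pad=0, rng=rng), nn.BatchNorm3d(cout)]
                ),
            )
        self.add_child("out_relu", self.out_relu)


class ResNet3D(nn.Module):
    def __init__(self, block, layers, input_shape, in_channels=1, scale=1.0, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        dims = tuple(int(d) for d in input_shape)
        if min(dims) < 2:
            raise ValueError("input too small for the downsampling ladder")
        self.input_shape = dims
        self.in_channels = in_channels
        base = _width(64, scale)

        stem_stride = _adaptive_stride(dims)
        dims = _strided(dims, stem_stride)
        pool_stride = _adaptive_stride(dims)
        stem = [
            nn.Conv3d(in_channels, base, 7, stem_stride, pad=3, rng=rng),
            nn.BatchNorm3d(base),
            nn.ReLU(),
            nn.MaxPool3d(3, pool_stride, 1),
        ]
        dims = _strided(dims, pool_stride)

        blocks: list[nn.Module] = []
        cin = base
        for stage, n_blocks in enumerate(layers):
            width = base * (2**stage)
            stride = (1, 1, 1) if stage == 0 else _adaptive_stride(dims)
            dims = _strided(dims, stride)
            for b in range(n_blocks):
                blocks.append(block(cin, width, stride if b == 0 else (1, 1, 1), rng))
                cin = width * block.expansion
        self.feature_width = cin
        self.net = self.add_child("net", nn.Sequential(stem + blocks + [nn.GlobalAvgPool3d()]))

    def forward(self, x, train=False):
        if x.shape[2:] != self.input_shape:
            raise ValueError(
                f"shape mismatch: expected spatial {self.input_shape}, got {x.shape[2:]}"
            )
        return self.net.forward(x, train)

    def backward(self, gy):
        return self.net.backward(gy)


class _DepthwiseSeparable(nn.Module):
    def __init__(self, cin, cout, stride, rng):
        super().__init__()
        self.seq = self.add_child(
            "seq",
            nn.Sequential(
                [
                    nn.Conv3d(cin, cin, 3, stride, groups=cin, rng=rng),
                    nn.BatchNorm3d(cin),
                    nn.ReLU(),
                    nn.Conv3d(cin, cout, 1, 1, pad=0, rng=rng),
                    nn.BatchNorm3d(cout),
                    nn.ReLU(),
                ]
            ),
        )

    def forward(self, x, train=False):
        return self.seq.forward(x, train)

    def backward(self, gy):
        return self.seq.backward(gy)


class MobileNet3D(nn.Module):
    CFG = [(64, 1), (128, 2), (128, 1), (256, 2), (256, 1), (512, 2),
           (512, 1), (512, 1), (512, 1), (512, 1), (512, 1), (1024, 2), (1024, 1)]

    def __init__(self, input_shape, in_channels=1, scale=1.0, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        dims = tuple(int(d) for d in input_shape)
        if min(dims) < 2:
            raise ValueError("input too small for the downsampling ladder")
        self.input_shape = dims
        self.in_channels = in_channels
        cin = _width(32, scale)
        stem_stride = _adaptive_stride(dims)
        dims = _strided(dims, stem_stride)
        layers: list[nn.Module] = [
            nn.Conv3d(in_channels, cin, 3, stem_stride, rng=rng),
            nn.BatchNorm3d(cin),
            nn.ReLU(),
        ]
        for cout_base, s in self.CFG:
            stride = _adaptive_stride(dims) if s == 2 else (1, 1, 1)
            dims = _strided(dims, stride)
            cout = _width(cout_base, scale)
            layers.append(_DepthwiseSeparable(cin, cout, stride, rng))
            cin = cout
        layers.append(nn.GlobalAvgPool3d())
        self.feature_width = cin
        self.net = self.add_child("net", nn.Sequential(layers))

    def forward(self, x, train=False):
        if x.shape[2:] != self.input_shape:
            raise ValueError(
                f"shape mismatch: expected spatial {self.input_shape}, got {x.shape[2:]}"
            )
        return self.net.forward(x, train)

    def backward(self, gy):
        return self.net.backward(gy)


class _Fire(nn.Module):
    def __init__(self, cin, squeeze, expand1, expand3, rng):
        super().__init__()
        self.squeeze = self.add_child(
            "squeeze",
            nn.Sequential([nn.Conv3d(cin, squeeze, 1, 1, pad=0, rng=rng), nn.ReLU()]),
        )
        self.e1 = self.add_child("e1", nn.Conv3d(squeeze, expand1, 1, 1, pad=0, rng=rng))
        self.e3 = self.add_child("e3", nn.Conv3d(squeeze, expand3, 3, 1, rng=rng))
        self.relu = self.add_child("relu", nn.ReLU())
        self.split = expand1

    def forward(self, x, train=False):
        s = self.squeeze.forward(x, train)
        out = np.concatenate([self.e1.forward(s, train), self.e3.forward(s, train)], axis=1)
        return self.relu.forward(out, train)

    def backward(self, gy):
        g = self.relu.backward(gy)
        gs = self.e1.backward(g[:, : self.split]) + self.e3.backward(g[:, self.split :])
        return self.squeeze.backward(gs)


class SqueezeNet3D(nn.Module):
    def __init__(self, input_shape, in_channels=1, scale=1.0, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        dims = tuple(int(d) for d in input_shape)
        if min(dims) < 2:
            raise ValueError("input too small for the downsampling ladder")
        self.input_shape = dims
        self.in_channels = in_channels
        w = lambda c: _width(c, scale)
        stem_stride = _adaptive_stride(dims)
        dims = _strided(dims, stem_stride)
        layers: list[nn.Module] = [
            nn.Conv3d(in_channels, w(64), 3, stem_stride, rng=rng),
            nn.ReLU(),
        ]
        cin = w(64)
        plan = [
            [(16, 64), (16, 64)],
            [(32, 128), (32, 128)],
            [(48, 192), (48, 192), (64, 256), (64, 256)],
        ]
        for gi, group in enumerate(plan):
            pool_stride = _adaptive_stride(dims)
            layers.append(nn.MaxPool3d(3, pool_stride, 1))
            dims = _strided(dims, pool_stride)
            for squeeze, expand in group:
                layers.append(_Fire(cin, w(squeeze), w(expand), w(expand), rng))
                cin = 2 * w(expand)
        layers.append(nn.GlobalAvgPool3d())
        self.feature_width = cin
        self.net = self.add_child("net", nn.Sequential(layers))

    def forward(self, x, train=False):
        if x.shape[2:] != self.input_shape:
            raise ValueError(
                f"shape mismatch: expected spatial {self.input_shape}, got {x.shape[2:]}"
            )
        return self.net.forward(x, train)

    def backward(self, gy):
        return self.net.backward(gy)


BACKBONES = {
    "resnet34_3d": lambda shape, cin, scale, rng: ResNet3D(
        BasicBlock3d, [3, 4, 6, 3], shape, cin, scale, rng
    ),
    "resnet50_3d": lambda shape, cin, scale, rng: ResNet3D(
        Bottleneck3d, [3, 4, 6, 3], shape, cin, scale, rng
    ),
    "mobilenet_3d": lambda shape, cin, scale, rng: MobileNet3D(shape, cin, scale, rng),
    "squeezenet_3d": lambda shape, cin, scale, rng: SqueezeNet3D(shape, cin, scale, rng),
}


def build_backbone(
    name: str,
    input_shape: tuple[int, int, int],
    in_channels: int = 1,
    scale: float = 1.0,
    seed: int = 0,
) -> nn.Module:
    """Build a named backbone with deterministic, seeded initialization."""
    if name not in BACKBONES:
        raise ValueError(f"unknown backbone {name!r}; choose from {sorted(BACKBONES)}")
    rng = np.random.default_rng(seed)
    return BACKBONES[name](tuple(input_shape), in_channels, scale, rng)


class GenderBranch(nn.Module):
    """Binary sex code -> 32-wide embedding through one fc layer + ReLU."""

    width = GENDER_WIDTH

    def __init__(self, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.fc = self.add_child("fc", nn.Linear(1, self.width, rng=rng))
        self.relu = self.add_child("relu", nn.ReLU())

    def forward(self, sex: np.ndarray, train: bool = False) -> np.ndarray:
        sex = np.asarray(sex)
        if not np.isin(sex, (0, 1)).all():
            raise ValueError("invalid sex code: expected 0 (male) or 1 (female)")
        x = sex.reshape(-1, 1).astype(np.float32)
        return self.relu.forward(self.fc.forward(x, train), train)

    def backward(self, gy: np.ndarray) -> None:
        self.fc.backward(self.relu.backward(gy))


def gender_branch(sex, model: GenderBranch | None = None) -> np.ndarray:
    """Embed sex codes; a fresh seeded branch is used when none is given."""
    model = model or GenderBranch(np.random.default_rng(0))
    out = model.forward(np.atleast_1d(np.asarray(sex)))
    return out[0] if np.isscalar(sex) or np.ndim(sex) == 0 else out


@dataclass
class NetworkConfig:
    """Which model to build and at what size.

    ``fusion`` is one of none / early / middle / late; ``modality`` applies
    only to ``fusion='none'``. ``input_shapes`` are the (z, y, x) crop shapes
    the model consumes; ``scale`` multiplies all channel widths.
    """

    fusion: str = "none"
    modality: str = "femur"
    backbones: dict = field(
        default_factory=lambda: {
            "mandible": "resnet34_3d",
            "femur": "resnet50_3d",
            "early": "resnet50_3d",
        }
    )
    input_shapes: dict = field(
        default_factory=lambda: {
            "mandible": (20, 224, 224),
            "femur": (112, 112, 112),
            "early": (64, 112, 112),
        }
    )
    use_gender: bool = True
    scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.fusion not in ("none", "early", "middle", "late"):
            raise ValueError(f"unknown fusion {self.fusion!r}")
        if self.fusion == "none" and self.modality not in ("mandible", "femur"):
            raise ValueError("fusion='none' requires modality 'mandible' or 'femur'")
        for m in ("mandible", "femur"):
            if m not in self.input_shapes and self.fusion in ("middle", "late"):
                raise ValueError(f"{self.fusion} fusion requires an input shape for {m}")

    def to_json(self) -> str:
        d = vars(self).copy()
        d["input_shapes"] = {k: list(v) for k, v in d["input_shapes"].items()}
        return json.dumps(d, indent=2, sort_keys=True)


class _HeadedModel(nn.Module):
    """Backbone(s) + optional sex branch + linear regression head."""

    def predict(self, batch: dict) -> np.ndarray:
        return self.forward_batch(batch, train=False)

    def set_head_bias(self, value: float) -> None:
        if self.head.b is not None:
            self.head.b.value[...] = value


class SingleModalityModel(_HeadedModel):
    def __init__(self, backbone: nn.Module, modality: str, use_gender: bool, rng) -> None:
        super().__init__()
        self.modality = modality
        self.modalities = (modality,)
        self.use_gender = use_gender
        self.backbone = self.add_child("backbone", backbone)
        head_in = backbone.feature_width
        if use_gender:
            self.gender = self.add_child("gender", GenderBranch(rng))
            head_in += GENDER_WIDTH
        self.head = self.add_child("head", nn.Linear(head_in, 1, rng=rng, init_scale=0.01))

    def forward_batch(self, batch: dict, train: bool = False) -> np.ndarray:
        feats = self.backbone.forward(batch[self.modality], train)
        if self.use_gender:
            feats = np.concatenate([feats, self.gender.forward(batch["sex"], train)], axis=1)
        self._fw = feats.shape[1]
        return self.head.forward(feats, train)[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        g = self.head.backward(dy[:, None])
        split = self.backbone.feature_width
        self.backbone.backward(g[:, :split])
        if self.use_gender:
            self.gender.backward(g[:, split:])


class MiddleFusionModel(_HeadedModel):
    """Joint model: both backbones feed one regression head."""

    modalities = ("mandible", "femur")

    def __init__(self, backbone_mandible, backbone_femur, use_gender: bool, rng) -> None:
        super().__init__()
        self.use_gender = use_gender
        self.bb_m = self.add_child("backbone_mandible", backbone_mandible)
        self.bb_f = self.add_child("backbone_femur", backbone_femur)
        head_in = backbone_mandible.feature_width + backbone_femur.feature_width
        if use_gender:
            self.gender = self.add_child("gender", GenderBranch(rng))
            head_in += GENDER_WIDTH
        self.head = self.add_child("head", nn.Linear(head_in, 1, rng=rng, init_scale=0.01))

    def forward_batch(self, batch: dict, train: bool = False) -> np.ndarray:
        parts = [
            self.bb_m.forward(batch["mandible"], train),
            self.bb_f.forward(batch["femur"], train),
        ]
        if self.use_gender:
            parts.append(self.gender.forward(batch["sex"], train))
        return self.head.forward(np.concatenate(parts, axis=1), train)[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        g = self.head.backward(dy[:, None])
        wm, wf = self.bb_m.feature_width, self.bb_f.feature_width
        self.bb_m.backward(g[:, :wm])
        self.bb_f.backward(g[:, wm : wm + wf])
        if self.use_gender:
            self.gender.backward(g[:, wm + wf :])


class LateFusionEnsemble:
    """Two independently trained single-modality models, averaged at predict.

    The average itself involves no learned parameters (``fuse_late``).
    """

    modalities = ("mandible", "femur")

    def __init__(self, model_mandible: SingleModalityModel, model_femur: SingleModalityModel):
        self.submodels = {"mandible": model_mandible, "femur": model_femur}

    def predict(self, batch: dict) -> np.ndarray:
        return fuse_late(
            self.submodels["mandible"].predict(batch),
            self.submodels["femur"].predict(batch),
        )


def fuse_late(pred_mandible: np.ndarray, pred_femur: np.ndarray) -> np.ndarray:
    """Late fusion: the exact arithmetic mean of the two predictions."""
    a = np.asarray(pred_mandible, dtype=np.float64)
    b = np.asarray(pred_femur, dtype=np.float64)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("late fusion requires finite predictions")
    return (a + b) / 2.0


def predict_single(model: SingleModalityModel, voxel: np.ndarray, sex: int) -> float:
    """Predict one subject's age from one modality voxel and sex code."""
    v = np.asarray(voxel, dtype=np.float32)  # (D,H,W) or (C,D,H,W) -> (1,C,D,H,W)
    v = v[None, None] if v.ndim == 3 else v[None]
    batch = {model.modality: v, "sex": np.array([sex])}
    return float(model.predict(batch)[0])


def resize_volume(values: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Trilinearly resize a rank-3 array onto ``shape`` (early-fusion grid)."""
    values = np.asarray(values, dtype=np.float32)
    factors = tuple(t / s for t, s in zip(shape, values.shape))
    out = ndimage.zoom(values, factors, order=1, mode="nearest", grid_mode=True)
    # zoom rounds sizes; guard against off-by-one
    if out.shape != tuple(shape):
        from .preprocessing import fit_to_shape

        out = fit_to_shape(out, shape)
    return out.astype(np.float32)


def build_model(config: NetworkConfig):
    """Instantiate the model a config describes (seeded, deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    def single(modality: str, in_channels: int = 1, seed_offset: int = 0):
        bb = build_backbone(
            config.backbones[modality],
            config.input_shapes[modality],
            in_channels=in_channels,
            scale=config.scale,
            seed=config.seed + seed_offset,
        )
        return SingleModalityModel(
            bb, modality, config.use_gender, np.random.default_rng(config.seed + seed_offset)
        )

    if config.fusion == "none":
        return single(config.modality)
    if config.fusion == "early":
        return single("early", in_channels=2)
    if config.fusion == "middle":
        bb_m = build_backbone(
            config.backbones["mandible"], config.input_shapes["mandible"],
            scale=config.scale, seed=config.seed,
        )
        bb_f = build_backbone(
            config.backbones["femur"], config.input_shapes["femur"],
            scale=config.scale, seed=config.seed + 1,
        )
        return MiddleFusionModel(bb_m, bb_f, config.use_gender, rng)
    # late
    return LateFusionEnsemble(single("mandible"), single("femur", seed_offset=1))


def save_checkpoint(model, config: NetworkConfig, path: str | Path) -> None:
    """Write parameters as .npz plus a JSON config sidecar."""
    path = Path(path)
    if isinstance(model, LateFusionEnsemble):
        arrays = {}
        for tag, sub in model.submodels.items():
            arrays.update({f"{tag}:{k}": v for k, v in nn.state_dict(sub).items()})
    else:
        arrays = nn.state_dict(model)
    np.savez_compressed(path, **arrays)
    path.with_suffix(".json").write_text(config.to_json())


def load_checkpoint(path: str | Path):
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    path = Path(path)
    raw = json.loads(path.with_suffix(".json").read_text())
    raw["input_shapes"] = {k: tuple(v) for k, v in raw["input_shapes"].items()}
    config = NetworkConfig(**raw)
    model = build_model(config)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        arrays = dict(data)
    if isinstance(model, LateFusionEnsemble):
        for tag, sub in model.submodels.items():
            sub_state = {
                k.split(":", 1)[1]: v for k, v in arrays.items() if k.startswith(tag + ":")
            }
            nn.load_state_dict(sub, sub_state)
    else:
        nn.load_state_dict(model, arrays)
    return model, config
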