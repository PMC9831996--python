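"""Siamese DenseNet force regressor with optional phase-velocity fusion.

Input and reference image (volume or deformation map) pass through a
shared-weight three-layer convolutional stem; the two feature maps are
concatenated along channels and processed by densely connected blocks with
transition layers, global average pooling, and a two-layer fully connected
head producing one scalar force.  When SWEI fusion is enabled, the
standardised shear-wave phase velocity is appended to the pooled feature
vector before the head.

The 3D variant uses three dense blocks of three layers with growth rate 6;
the 2D variant adds a fourth block and raises the growth rate to 8 (plus a
wider stem) to land within 25 % of the 3D parameter count.  Convolution
weights are He-initialised; batch normalisation follows the usual
BN -> ReLU -> conv ordering inside dense layers.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn

__all__ = ["ModelConfig", "DenseBlock", "Transition", "ForceNet",
           "build_model", "save_model", "load_model"]


@dataclass(frozen=True)
class ModelConfig:
    representation: str  # "2d" | "3d"
    with_swei: bool = False
    siamese_layers: int = 3
    dense_blocks: int = 3  # 3 for 3d, 4 for 2d
    layers_per_block: int = 3
    growth_rate: int = 6  # 6 for 3d, 8 for 2d
    transition_compression: float = 0.5
    stem_channels: int = 16
    stem_strides: tuple[int, ...] = (1, 1, 1)
    kernel_size: int = 3
    fc_widths: tuple[int, int] = (64, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.representation not in ("2d", "3d"):
            raise ValueError(f"unknown representation {self.representation!r}")
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        if not 0 < self.transition_compression <= 1:
            raise ValueError("transition_compression must be in (0, 1]")
        if len(self.stem_strides) != self.siamese_layers:
            raise ValueError("one stride per Siamese stem layer required")

    @property
    def ndim(self) -> int:
        return 3 if self.representation == "3d" else 2

    @classmethod
    def default_3d(cls, with_swei: bool = False, seed: int = 0) -> "ModelConfig":
        """Full-scale 3D variant for 32^3 volume inputs."""
        return cls(representation="3d", with_swei=with_swei, dense_blocks=3,
                   growth_rate=6, stem_channels=16, seed=seed)

    @classmethod
    def default_2d(cls, with_swei: bool = False, seed: int = 0) -> "ModelConfig":
        """Full-scale 2D variant for 32x32 deformation maps; the extra block,
        growth rate 8 and wider stem bring the parameter count close to 3D."""
        return cls(representation="2d", with_swei=with_swei, dense_blocks=4,
                   growth_rate=8, stem_channels=24, seed=seed)

    @classmethod
    def desk_3d(cls, with_swei: bool = False, seed: int = 0) -> "ModelConfig":
        """Compact 3D variant for 16^3 desk-profile volumes (strided stem)."""
        return cls(representation="3d", with_swei=with_swei, dense_blocks=3,
                   growth_rate=6, stem_channels=8, stem_strides=(2, 2, 2),
                   fc_widths=(48, 1), seed=seed)

    @classmethod
    def desk_2d(cls, with_swei: bool = False, seed: int = 0) -> "ModelConfig":
        """Compact 2D variant for 16x16 desk-profile deformation maps."""
        return cls(representation="2d", with_swei=with_swei, dense_blocks=4,
                   growth_rate=8, stem_channels=10, stem_strides=(2, 1, 1),
                   fc_widths=(48, 1), seed=seed)


class DenseBlock(nn.Module):
    """Densely connected block: each layer sees every earlier feature map.

    Layer l computes BN -> ReLU -> conv(growth) on the concatenation of the
    block input and all previous layer outputs, so the channel count grows
    by ``layers * growth`` across the block.
    """

    def __init__(self, ndim: int, c_in: int, n_layers: int, growth: int,
                 kernel: int, rng: np.random.Generator, name: str) -> None:
        self.growth = growth
        self.layers = []
        ch = c_in
        for i in range(n_layers):
            bn = nn.BatchNorm(ch, name=f"{name}.l{i}.bn")
            relu = nn.ReLU()
            conv = nn.Conv(ndim, ch, growth, kernel, rng=rng, name=f"{name}.l{i}.conv")
            self.layers.append((bn, relu, conv))
            ch += growth
        self.c_out = ch

    def params(self):
        return [p for bn, _, conv in self.layers for p in (*bn.params(), *conv.params())]

    def buffers(self):
        return [b for bn, _, _ in self.layers for b in bn.buffers()]

    def forward(self, x, train: bool = True):
        feats = x
        caches = []
        for bn, relu, conv in self.layers:
            h, c_bn = bn.forward(feats, train)
            h, c_relu = relu.forward(h, train)
            h, c_conv = conv.forward(h, train)
            caches.append((c_bn, c_relu, c_conv))
            feats = np.concatenate([feats, h], axis=-1)
        return feats, caches

    def backward(self, caches, dy):
        g = self.growth
        d_feats = dy
        for (bn, relu, conv), cache in zip(reversed(self.layers), reversed(caches)):
            c_bn, c_relu, c_conv = cache
            d_h = d_feats[..., -g:]
            d_in = d_feats[..., :-g]
            d = conv.backward(c_conv, d_h)
            d = relu.backward(c_relu, d)
            d = bn.backward(c_bn, d)
            d_feats = d_in + d
        return d_feats


class Transition(nn.Module):
    """BN -> ReLU -> 1x1 conv (channel compression) -> stride-2 average pool."""

    def __init__(self, ndim: int, c_in: int, compression: float,
                 rng: np.random.Generator, name: str) -> None:
        self.c_out = max(1, int(np.floor(c_in * compression)))
        self.bn = nn.BatchNorm(c_in, name=f"{name}.bn")
        self.relu = nn.ReLU()
        self.conv = nn.Conv(ndim, c_in, self.c_out, kernel=1, rng=rng,
                            name=f"{name}.conv")
        self.pool = nn.AvgPool(ndim, 2)
        self._poolable = None  # decided on first forward from spatial size

    def params(self):
        return [*self.bn.params(), *self.conv.params()]

    def buffers(self):
        return self.bn.buffers()

    def forward(self, x, train: bool = True):
        h, c1 = self.bn.forward(x, train)
        h, c2 = self.relu.forward(h, train)
        h, c3 = self.conv.forward(h, train)
        # maps already reduced to a single voxel cannot pool further
        self._poolable = all(s % 2 == 0 for s in h.shape[1:-1])
        c4 = None
        if self._poolable:
            h, c4 = self.pool.forward(h, train)
        return h, (c1, c2, c3, c4)

    def backward(self, cache, dy):
        c1, c2, c3, c4 = cache
        d = self.pool.backward(c4, dy) if c4 is not None else dy
        d = self.conv.backward(c3, d)
        d = self.relu.backward(c2, d)
        return self.bn.backward(c1, d)


class ForceNet(nn.Module):
    """Siamese DenseNet regressor; see module docstring.

    Carries the label/velocity standardisation statistics established
    during training so that :meth:`predict` returns forces in Newton.
    """

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        ndim = config.ndim
        k = config.kernel_size

        stem_layers: list[nn.Module] = []
        c = 1
        for i, stride in enumerate(config.stem_strides):
            stem_layers += [
                nn.Conv(ndim, c, config.stem_channels, k, stride=stride,
                        rng=rng, name=f"stem{i}.conv"),
                nn.BatchNorm(config.stem_channels, name=f"stem{i}.bn"),
                nn.ReLU(),
            ]
            c = config.stem_channels
        self.stem = nn.Sequential(stem_layers)

        ch = 2 * config.stem_channels  # input + reference concatenated
        self.blocks: list[nn.Module] = []
        for b in range(config.dense_blocks):
            block = DenseBlock(ndim, ch, config.layers_per_block,
                               config.growth_rate, k, rng, f"block{b}")
            self.blocks.append(block)
            ch = block.c_out
            if b < config.dense_blocks - 1:
                trans = Transition(ndim, ch, config.transition_compression,
                                   rng, f"trans{b}")
                self.blocks.append(trans)
                ch = trans.c_out
        self.final_bn = nn.BatchNorm(ch, name="final.bn")
        self.final_relu = nn.ReLU()
        self.gap = nn.GlobalAvgPool()
        self.pooled_channels = ch

        feat = ch + (1 if config.with_swei else 0)
        fc1, fc2 = config.fc_widths
        self.head_fc1 = nn.Linear(feat, fc1, rng=rng, name="head.fc1")
        self.head_bn = nn.BatchNorm(fc1, name="head.bn")
        self.head_relu = nn.ReLU()
        self.head_fc2 = nn.Linear(fc1, fc2, rng=rng, name="head.fc2")

        # standardisation statistics (filled in by training)
        self.y_mean = 0.0
        self.y_std = 1.0
        self.v_mean = 0.0
        self.v_std = 1.0

        self._modules: list[nn.Module] = [
            self.stem, *self.blocks, self.final_bn,
            self.head_fc1, self.head_bn, self.head_fc2,
        ]

    # -- state ------------------------------------------------------------
    def params(self) -> list[nn.Param]:
        return [p for m in self._modules for p in m.params()]

    def buffers(self) -> list[np.ndarray]:
        return [b for m in self._modules for b in m.buffers()]

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def get_state(self) -> dict:
        return {
            "params": [p.value.copy() for p in self.params()],
            "buffers": [b.copy() for b in self.buffers()],
            "norm": (self.y_mean, self.y_std, self.v_mean, self.v_std),
        }

    def set_state(self, state: dict) -> None:
        for p, v in zip(self.params(), state["params"]):
            p.value[...] = v
        for b, v in zip(self.buffers(), state["buffers"]):
            b[...] = v
        self.y_mean, self.y_std, self.v_mean, self.v_std = state["norm"]

    # -- forward/backward --------------------------------------------------
    def _check_inputs(self, x, ref, velocity):
        if x.ndim != 2 + self.config.ndim or x.shape[-1] != 1:
            raise ValueError(
                f"{self.config.representation} model expects rank "
                f"{2 + self.config.ndim} input (B, spatial..., 1), got {x.shape}")
        if x.shape != ref.shape:
            raise ValueError("input and reference shapes differ")
        if self.config.with_swei and velocity is None:
            raise ValueError("fusion model needs a phase velocity input")
        if not self.config.with_swei and velocity is not None:
            raise ValueError("non-fusion model given a phase velocity")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(ref))):
            raise ValueError("non-finite image input")

    def forward(self, x: np.ndarray, ref: np.ndarray,
                velocity: np.ndarray | None = None, train: bool = True):
        """Returns ``(output (B,), cache)``; output is in standardised units."""
        self._check_inputs(x, ref, velocity)
        # shared-weight Siamese stage: both branches pass through the stem
        # as one stacked batch so batch-norm statistics are the branch
        # mixture in training, matching the running statistics used at eval
        n = x.shape[0]
        stacked = np.concatenate([x, ref], axis=0).astype(np.float32)
        h_both, c_stem = self.stem.forward(stacked, train)
        h = np.concatenate([h_both[:n], h_both[n:]], axis=-1)
        split = h_both.shape[-1]

        block_caches = []
        for m in self.blocks:
            h, c = m.forward(h, train)
            block_caches.append(c)
        h, c_fbn = self.final_bn.forward(h, train)
        h, c_frelu = self.final_relu.forward(h, train)
        feat, c_gap = self.gap.forward(h, train)

        if self.config.with_swei:
            v_std = ((np.asarray(velocity, dtype=np.float32) - self.v_mean)
                     / self.v_std)
            feat = np.concatenate([feat, v_std[:, None]], axis=1)
        z, c_fc1 = self.head_fc1.forward(feat, train)
        z, c_hbn = self.head_bn.forward(z, train)
        z, c_hrelu = self.head_relu.forward(z, train)
        z, c_fc2 = self.head_fc2.forward(z, train)
        out = z[:, 0]
        cache = (c_stem, split, block_caches, c_fbn, c_frelu, c_gap,
                 c_fc1, c_hbn, c_hrelu, c_fc2)
        return out, cache

    def backward(self, cache, dout: np.ndarray) -> None:
        (c_stem, split, block_caches, c_fbn, c_frelu, c_gap,
         c_fc1, c_hbn, c_hrelu, c_fc2) = cache
        d = self.head_fc2.backward(c_fc2, dout[:, None].astype(np.float32))
        d = self.head_relu.backward(c_hrelu, d)
        d = self.head_bn.backward(c_hbn, d)
        d = self.head_fc1.backward(c_fc1, d)
        if self.config.with_swei:
            d = d[:, :-1]  # velocity input takes no image gradient
        d = self.gap.backward(c_gap, d)
        d = self.final_relu.backward(c_frelu, d)
        d = self.final_bn.backward(c_fbn, d)
        for m, c in zip(reversed(self.blocks), reversed(block_caches)):
            d = m.backward(c, d)
        # shared-weight stem: branch gradients re-stacked along the batch
        d_stacked = np.concatenate([d[..., :split], d[..., split:]], axis=0)
        self.stem.backward(c_stem, d_stacked)

    def predict(self, x: np.ndarray, ref: np.ndarray,
                velocity: np.ndarray | None = None,
                batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode forward pass, de-standardised to Newton."""
        outs = []
        for i in range(0, x.shape[0], batch_size):
            sl = slice(i, i + batch_size)
            v = None if velocity is None else velocity[sl]
            out, _ = self.forward(x[sl], ref[sl], v, train=False)
            outs.append(out)
        z = np.concatenate(outs) if outs else np.zeros(0, dtype=np.float32)
        return z * self.y_std + self.y_mean


def build_model(config: ModelConfig) -> ForceNet:
    return ForceNet(config)


def save_model(model: ForceNet, path: str) -> None:
    """Single-file checkpoint: config JSON + weights + BN statistics."""
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    arrays.update({f"b{i}": b for i, b in enumerate(model.buffers())})
    arrays["norm"] = np.array(
        [model.y_mean, model.y_std, model.v_mean, model.v_std])
    cfg = asdict(model.config)
    cfg["stem_strides"] = list(cfg["stem_strides"])
    cfg["fc_widths"] = list(cfg["fc_widths"])
    arrays["config_json"] = np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str) -> ForceNet:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["config_json"]).decode())
        cfg["stem_strides"] = tuple(cfg["stem_strides"])
        cfg["fc_widths"] = tuple(cfg["fc_widths"])
        model = ForceNet(ModelConfig(**cfg))
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"p{i}"]
        for i, b in enumerate(model.buffers()):
            b[...] = data[f"b{i}"]
        (model.y_mean, model.y_std,
         model.v_mean, model.v_std) = [float(v) for v in data["norm"]]
    return model
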