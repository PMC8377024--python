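"""Encoder-decoder heatmap network.

A fully-convolutional U-Net-style network: a residual encoder (34-layer
preset with strides 2-32, or a 10-layer ``tiny`` preset for CPU-scale tests)
and a decoder of 5 upsampling blocks, each a sub-pixel (pixel-shuffle)
upsample followed by two 3x3 convolutions with batch normalization, with
skip connections from the matching encoder stage. A final 1x1 convolution
and logistic activation emit one heatmap channel per cell class at the full
input resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ..errors import ConfigError, ValidationError
from .layers import (
    BatchNorm2d,
    Conv2d,
    ConvBNAct,
    Layer,
    MaxPool2x2,
    Param,
    PixelShuffle,
    ResBlock,
    Sigmoid,
)

ENCODER_PRESETS = ("resnet34_like", "tiny")


@dataclass
class ModelConfig:
    input_size: int = 256
    n_classes: int = 4
    encoder_preset: str = "resnet34_like"

    def __post_init__(self) -> None:
        if self.input_size % 32 != 0:
            raise ConfigError(f"input_size {self.input_size} not divisible by 32")
        if self.encoder_preset not in ENCODER_PRESETS:
            raise ConfigError(f"unknown encoder preset {self.encoder_preset!r}")
        if self.n_classes < 1:
            raise ConfigError("n_classes must be >= 1")


class _TinyEncoder(Layer):
    """10-layer residual encoder, base width 16, strides 1..32."""

    widths = (16, 16, 32, 48, 64, 64)

    def __init__(self, rng):
        w = self.widths
        self.stem = ConvBNAct(3, w[0], 3, 1, rng=rng)
        self.stages = [ResBlock(w[i], w[i + 1], 2, rng=rng) for i in range(5)]
        # channel counts of skips handed to the decoder, deepest first
        self.skip_channels = [w[4], w[3], w[2], w[1], w[0]]
        self.out_channels = w[5]

    def params(self):
        p = self.stem.params()
        for s in self.stages:
            p += s.params()
        return p

    def forward(self, x, train):
        h = self.stem.forward(x, train)
        feats = [h]
        for stage in self.stages:
            h = stage.forward(h, train)
            feats.append(h)
        # feats strides: 1, 2, 4, 8, 16, 32; bottleneck is last
        skips = feats[-2::-1]  # strides 16, 8, 4, 2, 1
        return h, skips

    def backward(self, dh, dskips):
        g = dh
        for i, stage in enumerate(reversed(self.stages)):
            g = stage.backward(g)
            g = g + dskips[i]
        return self.stem.backward(g)


class _ResNet34Encoder(Layer):
    """34-layer residual encoder (3/4/6/3 blocks, widths 64-512)."""

    def __init__(self, rng):
        self.stem = ConvBNAct(3, 64, 7, 2, pad=3, rng=rng)
        self.pool = MaxPool2x2()

        def stage(n, in_ch, out_ch, stride):
            blocks = [ResBlock(in_ch, out_ch, stride, rng=rng)]
            blocks += [ResBlock(out_ch, out_ch, 1, rng=rng) for _ in range(n - 1)]
            return blocks

        self.layer1 = stage(3, 64, 64, 1)
        self.layer2 = stage(4, 64, 128, 2)
        self.layer3 = stage(6, 128, 256, 2)
        self.layer4 = stage(3, 256, 512, 2)
        # deepest-first skips: layer3 (s16), layer2 (s8), layer1 (s4),
        # stem (s2), raw input (s1)
        self.skip_channels = [256, 128, 64, 64, 3]
        self.out_channels = 512

    def params(self):
        p = self.stem.params()
        for blocks in (self.layer1, self.layer2, self.layer3, self.layer4):
            for b in blocks:
                p += b.params()
        return p

    @staticmethod
    def _run(blocks, h, train):
        for b in blocks:
            h = b.forward(h, train)
        return h

    @staticmethod
    def _back(blocks, g):
        for b in reversed(blocks):
            g = b.backward(g)
        return g

    def forward(self, x, train):
        s0 = x
        s1 = self.stem.forward(x, train)
        h = self.pool.forward(s1, train)
        s2 = self._run(self.layer1, h, train)
        s3 = self._run(self.layer2, s2, train)
        s4 = self._run(self.layer3, s3, train)
        h = self._run(self.layer4, s4, train)
        return h, [s4, s3, s2, s1, s0]

    def backward(self, dh, dskips):
        g = self._back(self.layer4, dh)
        g = self._back(self.layer3, g + dskips[0])
        g = self._back(self.layer2, g + dskips[1])
        g = self._back(self.layer1, g + dskips[2])
        g = self.pool.backward(g)
        g = self.stem.backward(g + dskips[3])
        return g  # gradient w.r.t. raw input; the input skip grad is dropped


class _DecoderBlock(Layer):
    """Pixel-shuffle x2 upsample, concat skip, then two 3x3 conv+BN+ReLU."""

    def __init__(self, in_ch, skip_ch, out_ch, rng):
        self.pre = ConvBNAct(in_ch, 4 * out_ch, 1, 1, pad=0, rng=rng)
        self.shuffle = PixelShuffle(2)
        self.c1 = ConvBNAct(out_ch + skip_ch, out_ch, 3, 1, rng=rng)
        self.c2 = ConvBNAct(out_ch, out_ch, 3, 1, rng=rng)
        self.up_ch = out_ch

    def params(self):
        return self.pre.params() + self.c1.params() + self.c2.params()

    def forward(self, h, skip, train):
        up = self.shuffle.forward(self.pre.forward(h, train), train)
        cat = np.concatenate([up, skip], axis=1)
        return self.c2.forward(self.c1.forward(cat, train), train)

    def backward(self, dout):
        dcat = self.c1.backward(self.c2.backward(dout))
        dup, dskip = dcat[:, : self.up_ch], dcat[:, self.up_ch :]
        dh = self.pre.backward(self.shuffle.backward(np.ascontiguousarray(dup)))
        return dh, np.ascontiguousarray(dskip)


_DECODER_WIDTHS = {
    "tiny": (48, 32, 24, 16, 16),
    "resnet34_like": (256, 128, 64, 32, 16),
}


class CentreNet:
    """Callable heatmap network: image batch (NHWC, RGB in [0,1]) -> heatmaps."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        if config.encoder_preset == "tiny":
            self.encoder: Layer = _TinyEncoder(rng)
        else:
            self.encoder = _ResNet34Encoder(rng)
        widths = _DECODER_WIDTHS[config.encoder_preset]
        in_ch = self.encoder.out_channels
        self.decoder = []
        for skip_ch, out_ch in zip(self.encoder.skip_channels, widths):
            self.decoder.append(_DecoderBlock(in_ch, skip_ch, out_ch, rng))
            in_ch = out_ch
        self.head = Conv2d(in_ch, config.n_classes, 1, 1, pad=0, rng=rng, bias=True)
        # bias the head towards background so early training is stable on
        # heatmaps that are overwhelmingly zero
        self.head.b.v[...] = -2.19
        self.sigmoid = Sigmoid()

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        p = self.encoder.params()
        for d in self.decoder:
            p += d.params()
        p += self.head.params()
        return p

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.g[...] = 0.0

    # -- forward / backward -------------------------------------------------
    def forward(self, x_nchw: np.ndarray, train: bool = False) -> np.ndarray:
        h, skips = self.encoder.forward(x_nchw.astype(np.float32), train)
        self._skip_shapes = [s.shape for s in skips]
        for block, skip in zip(self.decoder, skips):
            h = block.forward(h, skip, train)
        return self.sigmoid.forward(self.head.forward(h, train), train)

    def backward(self, dout: np.ndarray) -> None:
        g = self.head.backward(self.sigmoid.backward(dout))
        dskips = []
        for block in reversed(self.decoder):
            g, ds = block.backward(g)
            dskips.append(ds)
        # collected shallowest-first; the encoder consumes deepest-first
        self.encoder.backward(g, dskips[::-1])

    def __call__(self, images_nhwc: np.ndarray) -> np.ndarray:
        """Inference on an (n, H, W, 3) batch; returns (n, H, W, C) in (0,1)."""
        images_nhwc = np.asarray(images_nhwc, dtype=np.float32)
        if images_nhwc.ndim != 4 or images_nhwc.shape[3] != 3:
            raise ValidationError("expected an (n, H, W, 3) RGB batch")
        x = normalize_images(images_nhwc).transpose(0, 3, 1, 2)
        out = self.forward(x, train=False)
        return out.transpose(0, 2, 3, 1)


def normalize_images(images_nhwc: np.ndarray) -> np.ndarray:
    """Centre [0,1] RGB values; the exact transform used at train time."""
    return (images_nhwc.astype(np.float32) - 0.5) * 2.0


def build_network(config: ModelConfig, seed: int = 0) -> CentreNet:
    """Construct the encoder-decoder with seeded He-normal initialisation."""
    return CentreNet(config, seed)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_network(net: CentreNet, path: str | Path) -> None:
    """Single-file weights (npz) plus a JSON ModelConfig sidecar."""
    path = Path(path)
    arrays = {}
    for i, p in enumerate(net.params()):
        arrays[f"param_{i}"] = p.v
    for i, bn in enumerate(_batchnorms(net)):
        arrays[f"bn_{i}_mean"] = bn.running_mean
        arrays[f"bn_{i}_var"] = bn.running_var
    np.savez(path, **arrays)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(asdict(net.config)))


def load_network(path: str | Path) -> CentreNet:
    path = Path(path)
    cfg = ModelConfig(**json.loads(path.with_suffix(path.suffix + ".json").read_text()))
    net = CentreNet(cfg)
    with np.load(path) as data:
        for i, p in enumerate(net.params()):
            p.v[...] = data[f"param_{i}"]
        for i, bn in enumerate(_batchnorms(net)):
            bn.running_mean[...] = data[f"bn_{i}_mean"]
            bn.running_var[...] = data[f"bn_{i}_var"]
    return net


def _batchnorms(net: CentreNet) -> list[BatchNorm2d]:
    found: list[BatchNorm2d] = []

    def walk(obj):
        if isinstance(obj, BatchNorm2d):
            found.append(obj)
            return
        for attr in vars(obj).values() if hasattr(obj, "__dict__") else []:
            if isinstance(attr, (Layer, CentreNet)):
                walk(attr)
            elif isinstance(attr, list):
                for item in attr:
                    if isinstance(item, Layer):
                        walk(item)

    walk(net)
    return found
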