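"""MBFFNet: a multi-branch feature-fusion network for polyp segmentation.

The architecture has three parts:

1. a five-stage VGG16-style encoder (3x3 conv + ReLU blocks, 2x2 max
   pooling between stages) producing feature maps at spatial strides
   1, 2, 4, 8, 16 with channel widths 64, 128, 256, 512, 512;
2. a stepwise *multiplicative-fusion* decoder: the deepest features are
   refined by a centre convolution, then fused four times against the
   skip stages.  Each fusion bilinearly up-samples the deep map x2,
   projects it to the skip's channel count, squashes it to [0, 1]
   (pixel-level attention weights) and multiplies it element-wise with
   the skip features before two refinement convolutions — replacing the
   channel concatenation of U-Net, which is what removes most of the
   decoder's multiply count;
3. an hourglass pyramid branch that resizes all five stages to the
   stride-2 reference resolution (1x1 conv + max-pool for the larger
   map, identity for the reference stage, bilinear x2/x4/x8 up-sampling
   for the smaller ones), concatenates them and compresses the stack —
   re-injecting the low-level detail that pure multiplicative fusion
   tends to wash out.

A fusion head up-samples the pyramid output to full resolution,
concatenates it with the decoder output and produces a single-channel
per-pixel polyp probability map through a 1x1 convolution and a logistic
squashing.

The default decoder/pyramid/head widths below are the frozen calibrated
configuration whose closed-form totals reproduce the published parameter
and flop counts; see ``docs/methods.md`` for the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import yaml

from . import nn
from .complexity import ConvLayerSpec
from .nn import Var

__all__ = [
    "DimensionError",
    "ShapeError",
    "ModelConfig",
    "tiny_config",
    "FusionBlock",
    "MBFFNet",
]


class DimensionError(ValueError):
    """Input spatial dimensions violate the network's contract."""


class ShapeError(ValueError):
    """Feature-map shapes are inconsistent with the architecture."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``decoder_widths`` are the channel counts after each of the four
    fusion steps; ``pyramid_channels``/``head_channels`` size the
    hourglass branch and the fusion head.  ``attention`` selects how the
    projected deep features are normalised into [0, 1] weights:
    per-pixel logistic (``"sigmoid"``, default) or a softmax over the
    spatial positions of each channel (``"softmax"``).
    """

    input_size: int = 256
    encoder_widths: Sequence[int] = (64, 128, 256, 512, 512)
    encoder_convs: Sequence[int] = (2, 2, 3, 3, 3)
    decoder_widths: Sequence[int] = (240, 128, 64, 32)
    pyramid_stride: int = 2
    pyramid_channels: int = 96
    head_channels: int = 8
    attention: str = "sigmoid"
    out_classes: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 16:
            raise DimensionError(
                f"input_size {self.input_size} is not divisible by 16"
            )
        if len(self.encoder_widths) != 5 or len(self.encoder_convs) != 5:
            raise ValueError("encoder must have exactly 5 stages")
        if any(
            a > b
            for a, b in zip(self.encoder_widths[:4], self.encoder_widths[1:4])
        ):
            raise ValueError("encoder widths must be non-decreasing through stage 4")
        if len(self.decoder_widths) != 4:
            raise ValueError("decoder must have exactly 4 fusion widths")
        if self.pyramid_stride != 2:
            raise ValueError(
                "the pyramid reference resolution is pinned to the stage-2 "
                "resolution (stride 2)"
            )
        if self.attention not in ("sigmoid", "softmax"):
            raise ValueError("attention must be 'sigmoid' or 'softmax'")

    def to_yaml(self, path=None) -> str:
        payload = {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in self.__dict__.items()
        }
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "ModelConfig":
        try:
            with open(source) as fh:
                payload = yaml.safe_load(fh)
        except (OSError, ValueError):
            payload = yaml.safe_load(source)
        payload = {
            k: (tuple(v) if isinstance(v, list) else v) for k, v in payload.items()
        }
        return cls(**payload)


def tiny_config(input_size: int = 64, seed: int = 0) -> ModelConfig:
    """A width-reduced configuration for desk-scale CPU training.

    Same topology as the default network with every width cut roughly
    8-fold, which keeps a full training run on synthetic scenes within
    minutes on one CPU core.
    """
    return ModelConfig(
        input_size=input_size,
        encoder_widths=(8, 16, 32, 64, 64),
        encoder_convs=(2, 2, 3, 3, 3),
        decoder_widths=(32, 16, 8, 8),
        pyramid_channels=16,
        head_channels=8,
        seed=seed,
    )


def _check_square(x: np.ndarray):
    h, w = x.shape[-2], x.shape[-1]
    if h != w:
        raise DimensionError(f"input must be square: height {h} != width {w}")
    for axis, n in (("height", h), ("width", w)):
        if n % 16:
            raise DimensionError(f"input {axis} {n} is not divisible by 16")


def _to_nchw(image) -> Var:
    """Accept HxWx3, 3xHxW or Nx3xHxW and return an NCHW Var."""
    if isinstance(image, Var):
        return image
    a = np.asarray(image, dtype=np.float32)
    if a.ndim == 3 and a.shape[-1] == 3:
        a = a.transpose(2, 0, 1)[None]
    elif a.ndim == 3 and a.shape[0] == 3:
        a = a[None]
    elif a.ndim != 4:
        raise ShapeError(f"cannot interpret input of shape {a.shape} as 3-channel images")
    return Var(a)


class FusionBlock:
    """One multiplicative (pixel-attention) fusion step of the decoder.

    ``deep`` is up-sampled x2, projected to the skip's channel count and
    normalised to [0, 1]; the resulting weights multiply the skip
    feature map element-wise, and two 3x3 conv + ReLU layers refine the
    product to ``out_channels``.
    """

    def __init__(self, in_channels, skip_channels, out_channels, rng, attention="sigmoid", name="fuse"):
        self.attention = attention
        self.project = nn.Conv2d(in_channels, skip_channels, 3, rng, f"{name}.project")
        self.refine = nn.ConvRelu(skip_channels, out_channels, 3, rng, f"{name}.refine")
        self.refine2 = nn.ConvRelu(out_channels, out_channels, 3, rng, f"{name}.refine2")

    def _check(self, deep: Var, skip: Var):
        dh, dw = deep.shape[-2], deep.shape[-1]
        sh, sw = skip.shape[-2], skip.shape[-1]
        if (sh, sw) != (2 * dh, 2 * dw):
            raise ShapeError(
                f"skip side {sh}x{sw} must be exactly twice deep side {dh}x{dw}"
            )

    def weights(self, deep: Var, skip: Var) -> Var:
        """The normalised pixel-level attention weights, in [0, 1]."""
        self._check(deep, skip)
        up = nn.resize_bilinear(deep, skip.shape[-2], skip.shape[-1])
        proj = self.project(up)
        if self.attention == "sigmoid":
            return nn.sigmoid(proj)
        return nn.softmax_pixels(proj)

    def product(self, deep: Var, skip: Var, attention: Optional[np.ndarray] = None) -> Var:
        """The pre-refinement weighted skip features (weights * skip)."""
        w = self.weights(deep, skip) if attention is None else nn.as_var(attention)
        return w * skip

    def __call__(self, deep: Var, skip: Var, attention: Optional[np.ndarray] = None) -> Var:
        return self.refine2(self.refine(self.product(deep, skip, attention)))

    def parameters(self):
        return self.project.parameters() + self.refine.parameters() + self.refine2.parameters()


class MBFFNet:
    """The multi-branch feature-fusion segmentation network."""

    def __init__(self, config: ModelConfig = None):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        w = list(cfg.encoder_widths)

        self.encoder: List[List[nn.ConvRelu]] = []
        ci = 3
        for stage, (width, n_convs) in enumerate(zip(w, cfg.encoder_convs), start=1):
            block = []
            for j in range(n_convs):
                block.append(nn.ConvRelu(ci, width, 3, rng, f"enc{stage}.conv{j + 1}"))
                ci = width
            self.encoder.append(block)

        d = list(cfg.decoder_widths)
        self.center = nn.ConvRelu(w[4], w[4], 3, rng, "center")
        skips = [w[3], w[2], w[1], w[0]]
        ins = [w[4]] + d[:3]
        self.fusions = [
            FusionBlock(ci_, sk, do, rng, cfg.attention, f"fuse{i + 1}")
            for i, (ci_, sk, do) in enumerate(zip(ins, skips, d))
        ]

        cat_width = sum(w)
        self.pyramid_pre = nn.Conv2d(w[0], w[0], 1, rng, "pyr.pre1x1")
        self.pyramid_compress = nn.ConvRelu(cat_width, cfg.pyramid_channels, 3, rng, "pyr.compress")
        self.pyramid_refine = nn.ConvRelu(
            cfg.pyramid_channels, cfg.pyramid_channels, 3, rng, "pyr.refine"
        )

        hc = cfg.head_channels
        self.head_fuse = nn.ConvRelu(cfg.pyramid_channels + d[3], hc, 3, rng, "head.fuse")
        self.head_refine = nn.ConvRelu(hc, hc, 3, rng, "head.refine")
        self.head_out = nn.Conv2d(hc, cfg.out_classes, 1, rng, "head.out")

    # -- architecture ----------------------------------------------------
    def encode(self, image) -> List[Var]:
        """Run the backbone; returns the 5 stage outputs (strides 1..16)."""
        x = _to_nchw(image)
        _check_square(x.data)
        stages = []
        for i, block in enumerate(self.encoder):
            if i > 0:
                x = nn.maxpool2(x)
            for conv in block:
                x = conv(x)
            stages.append(x)
        return stages

    def decode_main(self, stages: Sequence[Var]) -> Var:
        """Centre conv + four multiplicative fusions up to full resolution."""
        self._check_pyramid(stages)
        x = self.center(stages[4])
        for fuse, skip in zip(self.fusions, (stages[3], stages[2], stages[1], stages[0])):
            x = fuse(x, skip)
        return x

    def pyramid_branch(self, stages: Sequence[Var]) -> Var:
        """Hourglass branch: all stages resized to the stride-2 reference."""
        self._check_pyramid(stages)
        ref_h, ref_w = stages[1].shape[-2], stages[1].shape[-1]
        pooled = nn.maxpool2(self.pyramid_pre(stages[0]))
        branches = [pooled, stages[1]] + [
            nn.resize_bilinear(s, ref_h, ref_w) for s in stages[2:]
        ]
        return self.pyramid_refine(self.pyramid_compress(nn.concat(branches)))

    def _check_pyramid(self, stages):
        if len(stages) != 5:
            raise ShapeError(f"encoder pyramid must have 5 stages, got {len(stages)}")
        for i in range(1, 5):
            prev = stages[i - 1].shape[-1]
            if stages[i].shape[-1] * 2 != prev or stages[i].shape[-2] * 2 != prev:
                raise ShapeError(
                    f"stage {i + 1} side {stages[i].shape[-1]} is not half of "
                    f"stage {i} side {prev}"
                )

    def forward(self, image) -> Var:
        """Full pass: per-pixel polyp probabilities, input-sized, 1 channel."""
        stages = self.encode(image)
        main = self.decode_main(stages)
        pyr = self.pyramid_branch(stages)
        pyr_up = nn.resize_bilinear(pyr, main.shape[-2], main.shape[-1])
        x = self.head_fuse(nn.concat([main, pyr_up]))
        x = self.head_refine(x)
        return nn.sigmoid(self.head_out(x))

    __call__ = forward

    def predict(self, image, threshold: float = 0.5):
        """Probability map and binary mask (HxW arrays) for one image."""
        prob = self.forward(image).data[0, 0]
        return prob, (prob >= threshold).astype(np.uint8)

    # -- bookkeeping -----------------------------------------------------
    def parameters(self) -> List[Var]:
        params = [c.weight for b in self.encoder for c in b]
        params.append(self.center.weight)
        for f in self.fusions:
            params.extend(f.parameters())
        params += [
            self.pyramid_pre.weight,
            self.pyramid_compress.weight,
            self.pyramid_refine.weight,
            self.head_fuse.weight,
            self.head_refine.weight,
            self.head_out.weight,
        ]
        return params

    def conv_layer_specs(self, accounting_size: Optional[int] = None) -> List[ConvLayerSpec]:
        """Dump every convolution with its output size at ``accounting_size``.

        The dump is generated from the same layer objects the network
        computes with, so summed spec params always equal the backend's
        trainable weight count.
        """
        s = accounting_size or self.config.input_size
        if s % 16:
            raise DimensionError(f"accounting size {s} is not divisible by 16")
        out = []

        def add(conv, side):
            out.append(
                ConvLayerSpec(
                    name=conv.weight.name, ci=conv.ci, co=conv.co,
                    kw=conv.k, kh=conv.k, lwo=side, lho=side,
                )
            )

        for i, block in enumerate(self.encoder):
            for conv in block:
                add(conv, s >> i)
        add(self.center, s >> 4)
        for i, f in enumerate(self.fusions):
            side = s >> (3 - i)
            add(f.project, side)
            add(f.refine, side)
            add(f.refine2, side)
        add(self.pyramid_pre, s)  # 1x1 applied at full stage-1 resolution
        add(self.pyramid_compress, s >> 1)
        add(self.pyramid_refine, s >> 1)
        add(self.head_fuse, s)
        add(self.head_refine, s)
        add(self.head_out, s)
        return out

    def save_weights(self, path):
        np.savez(path, **{p.name: p.data for p in self.parameters()})

    def load_weights(self, path):
        with np.load(path) as archive:
            for p in self.parameters():
                p.data = archive[p.name].astype(np.float32)
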