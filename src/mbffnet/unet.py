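"""Reference concat-skip U-shaped network (the efficiency baseline).

Canonical VGG16-backbone U-Net: the decoder performs four bilinear x2
up-samplings, concatenates the same-resolution encoder stage along the
channel dimension, and applies two 3x3 conv + ReLU layers per step
(widths 512, 256, 128, 64), followed by a 1x1 logit head.  It shares the
encoder definition with :class:`mbffnet.model.MBFFNet` and exists to
reproduce the parameter/flop comparison against the multiplicative-fusion
decoder.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from . import nn
from .complexity import ConvLayerSpec
from .model import ModelConfig, ShapeError, _check_square, _to_nchw
from .nn import Var

__all__ = ["UNet", "build_unet", "UNET_DECODER_WIDTHS"]

UNET_DECODER_WIDTHS = (512, 256, 128, 64)


class UNet:
    def __init__(self, config: ModelConfig = None, decoder_widths: Sequence[int] = UNET_DECODER_WIDTHS):
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

        self.decoder: List[List[nn.ConvRelu]] = []
        skips = [w[3], w[2], w[1], w[0]]
        ci = w[4]
        for i, (skip, width) in enumerate(zip(skips, decoder_widths), start=1):
            block = [
                nn.ConvRelu(ci + skip, width, 3, rng, f"dec{i}.conv1"),
                nn.ConvRelu(width, width, 3, rng, f"dec{i}.conv2"),
            ]
            self.decoder.append(block)
            ci = width
        self.head = nn.Conv2d(ci, cfg.out_classes, 1, rng, "head.out")
        self.decoder_widths = tuple(decoder_widths)

    def encode(self, image) -> List[Var]:
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

    def forward(self, image) -> Var:
        stages = self.encode(image)
        if len(stages) != 5:
            raise ShapeError("expected a 5-stage encoder pyramid")
        x = stages[4]
        for block, skip in zip(self.decoder, (stages[3], stages[2], stages[1], stages[0])):
            x = nn.resize_bilinear(x, skip.shape[-2], skip.shape[-1])
            x = nn.concat([skip, x])
            for conv in block:
                x = conv(x)
        return nn.sigmoid(self.head(x))

    __call__ = forward

    def predict(self, image, threshold: float = 0.5):
        prob = self.forward(image).data[0, 0]
        return prob, (prob >= threshold).astype(np.uint8)

    def parameters(self) -> List[Var]:
        params = [c.weight for b in self.encoder for c in b]
        params += [c.weight for b in self.decoder for c in b]
        params.append(self.head.weight)
        return params

    def conv_layer_specs(self, accounting_size: Optional[int] = None) -> List[ConvLayerSpec]:
        s = accounting_size or self.config.input_size
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
        for i, block in enumerate(self.decoder):
            for conv in block:
                add(conv, s >> (3 - i))
        add(self.head, s)
        return out

    def save_weights(self, path):
        np.savez(path, **{p.name: p.data for p in self.parameters()})

    def load_weights(self, path):
        with np.load(path) as archive:
            for p in self.parameters():
                p.data = archive[p.name].astype(np.float32)


def build_unet(config: ModelConfig = None) -> UNet:
    return UNet(config)
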