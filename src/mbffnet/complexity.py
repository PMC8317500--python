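"""Closed-form convolution parameter and FLOP accounting.

For one convolution layer with ``ci`` input channels, ``co`` output
channels, kernel ``kw x kh`` and output feature map ``lwo x lho``:

* params = ci * co * kw * kh              (weights only, no biases)
* flops  = ci * co * lwo * lho * kw * kh  (sliding-window multiplies)

and a model's totals are the exact integer sums over its convolution
layers.  Biases, activations, pooling and interpolation are excluded by
convention — note that most off-the-shelf counters report MACs including
biases, which differs from these totals by ``sum(co)`` parameters.

"M" and "B" renderings are decimal (1e6, 1e9), rounded to two decimals.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Optional, Sequence

__all__ = [
    "ConvLayerSpec",
    "ComplexityReport",
    "ComplexityComparison",
    "layer_params",
    "layer_flops",
    "model_complexity",
    "compare",
    "dump_layers_json",
    "load_layers_json",
]


@dataclass(frozen=True)
class ConvLayerSpec:
    """One convolution layer, the unit of the closed-form accounting."""

    name: str
    ci: int
    co: int
    kw: int
    kh: int
    lwo: int
    lho: int

    def __post_init__(self):
        for field in ("ci", "co", "kw", "kh", "lwo", "lho"):
            v = getattr(self, field)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{field} must be a positive integer, got {v!r}")


def layer_params(layer: ConvLayerSpec) -> int:
    return layer.ci * layer.co * layer.kw * layer.kh


def layer_flops(layer: ConvLayerSpec) -> int:
    return layer.ci * layer.co * layer.lwo * layer.lho * layer.kw * layer.kh


@dataclass(frozen=True)
class ComplexityReport:
    model: str
    layers: tuple
    per_layer_params: tuple
    per_layer_flops: tuple
    total_params: int
    total_flops: int

    @property
    def params_m(self) -> float:
        return round(self.total_params / 1e6, 2)

    @property
    def flops_b(self) -> float:
        return round(self.total_flops / 1e9, 2)

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "total_params": self.total_params,
            "total_flops": self.total_flops,
            "params_M": self.params_m,
            "flops_B": self.flops_b,
            "layers": [
                {**asdict(sp), "params": p, "flops": f}
                for sp, p, f in zip(
                    self.layers, self.per_layer_params, self.per_layer_flops
                )
            ],
        }

    def table(self) -> str:
        lines = [f"{'layer':<28}{'ci':>6}{'co':>6}{'k':>4}{'out':>10}{'params':>12}{'flops':>16}"]
        for sp, p, f in zip(self.layers, self.per_layer_params, self.per_layer_flops):
            lines.append(
                f"{sp.name:<28}{sp.ci:>6}{sp.co:>6}{sp.kw:>4}"
                f"{f'{sp.lwo}x{sp.lho}':>10}{p:>12}{f:>16}"
            )
        lines.append(
            f"{'TOTAL':<28}{'':>26}{self.total_params:>12}{self.total_flops:>16}"
        )
        lines.append(f"Param (M): {self.params_m:.2f}   Flops (B): {self.flops_b:.2f}")
        return "\n".join(lines)


def model_complexity(
    layers: Sequence[ConvLayerSpec], model: str = "model"
) -> ComplexityReport:
    """Exact integer totals of the per-layer params/flops over a dump."""
    layers = tuple(layers)
    if not layers:
        raise ValueError("layer list must be non-empty")
    pp = tuple(layer_params(ly) for ly in layers)
    pf = tuple(layer_flops(ly) for ly in layers)
    return ComplexityReport(
        model=model,
        layers=layers,
        per_layer_params=pp,
        per_layer_flops=pf,
        total_params=sum(pp),
        total_flops=sum(pf),
    )


@dataclass(frozen=True)
class ComplexityComparison:
    """``a`` relative to ``b``: ratios and (1 - a/b) percent reductions."""

    a: str
    b: str
    param_ratio: float
    flop_ratio: float
    param_reduction_pct: float
    flop_reduction_pct: float

    def as_dict(self) -> dict:
        return asdict(self)


def compare(a: ComplexityReport, b: ComplexityReport) -> ComplexityComparison:
    if b.total_params == 0 or b.total_flops == 0:
        raise ZeroDivisionError("reference report has zero totals")
    pr = a.total_params / b.total_params
    fr = a.total_flops / b.total_flops
    return ComplexityComparison(
        a=a.model,
        b=b.model,
        param_ratio=pr,
        flop_ratio=fr,
        param_reduction_pct=(1.0 - pr) * 100.0,
        flop_reduction_pct=(1.0 - fr) * 100.0,
    )


def dump_layers_json(layers: Iterable[ConvLayerSpec], path=None) -> str:
    text = json.dumps([asdict(ly) for ly in layers], indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def load_layers_json(source: str, from_path: Optional[bool] = None) -> list:
    if from_path or (from_path is None and not source.lstrip().startswith("[")):
        with open(source) as fh:
            raw = json.load(fh)
    else:
        raw = json.loads(source)
    return [ConvLayerSpec(**entry) for entry in raw]
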