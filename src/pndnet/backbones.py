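"""Backbone feature extractors.

Two kinds of backbone live here:

* ``tiny`` — a three-block convolutional network (32 output channels) that
  trains in seconds on a CPU. It is the only backbone with a runnable
  forward/backward pass in this package and carries all training paths.
* The four ImageNet reference architectures (``xception``, ``resnet50``,
  ``inceptionv3``, ``mobilenetv2``) — declarative adapters exposing the
  architecture's output channel width, final feature-map grid and exact
  parameter count (ImageNet-1000 head included). Their pretrained weights
  are multi-hundred-megabyte downloads; requesting a runnable pretrained
  extractor raises an explicit error rather than silently initializing
  random weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _archspecs
from .nn import AvgPool2d, Conv2d, Layer, ReLU

__all__ = [
    "BackboneSpec",
    "BACKBONE_REGISTRY",
    "TinyBackbone",
    "load_backbone",
    "count_parameters",
    "parameters_in_millions",
    "PretrainedWeightsUnavailable",
]


class PretrainedWeightsUnavailable(RuntimeError):
    """Raised when a runnable pretrained backbone is requested but its
    weights cannot be obtained."""


@dataclass(frozen=True)
class BackboneSpec:
    """Static description of a backbone architecture.

    ``output_channels`` is the channel width C of the final convolutional
    feature map; ``base_grid`` its spatial side for a 224x224 input.
    """

    name: str
    output_channels: int
    base_grid: int
    reference_parameters: int | None = None
    runnable: bool = False
    description: str = ""

    def output_grid(self, input_size: int) -> int:
        if self.name == "inceptionv3":
            return _archspecs.inceptionv3_output_grid(input_size)
        if self.name == "tiny":
            return input_size // 16
        return input_size // 32          # stride-32 architectures

    def parameter_count(self) -> int:
        if self.reference_parameters is None:
            raise ValueError(f"backbone {self.name!r} has no static parameter table; "
                             "instantiate it and use count_parameters()")
        return self.reference_parameters


BACKBONE_REGISTRY: dict[str, BackboneSpec] = {
    "xception": BackboneSpec("xception", 2048, 7, _archspecs.xception_parameters(),
                             description="depth-wise separable convolutions with residual connections"),
    "resnet50": BackboneSpec("resnet50", 2048, 7, _archspecs.resnet50_parameters(),
                             description="bottleneck residual blocks"),
    "inceptionv3": BackboneSpec("inceptionv3", 2048, 5, _archspecs.inceptionv3_parameters(),
                                description="factorized inception modules"),
    "mobilenetv2": BackboneSpec("mobilenetv2", 1280, 7, _archspecs.mobilenetv2_parameters(),
                                description="inverted residual linear bottlenecks"),
    "tiny": BackboneSpec("tiny", 32, 14, None, runnable=True,
                         description="three-conv-block test backbone, no pretraining"),
}


class TinyBackbone(Layer):
    """Three stride-2 conv blocks (3->16->32->32) plus a final 2x2 average
    pool: total downsampling x16, so a 64x64 input yields a 4x4x32 map."""

    CHANNELS = 16, 32, 32

    def __init__(self, rng: np.random.Generator | None = None, trainable: bool = True):
        rng = rng or np.random.default_rng(0)
        c = self.CHANNELS
        self.layers: list[Layer] = [
            Conv2d(3, c[0], 3, stride=2, padding=1, rng=rng), ReLU(),
            Conv2d(c[0], c[1], 3, stride=2, padding=1, rng=rng), ReLU(),
            Conv2d(c[1], c[2], 3, stride=2, padding=1, rng=rng), ReLU(),
            AvgPool2d(2),
        ]
        self.trainable = trainable
        self.output_channels = c[2]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        if not self.trainable:
            return []
        return [p for layer in self.layers for p in layer.parameters()]

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()


def load_backbone(name: str, *, pretrained: bool = False, trainable: bool = True,
                  rng: np.random.Generator | None = None) -> TinyBackbone:
    """Return a runnable feature extractor for ``name``.

    Only the ``tiny`` backbone is runnable here. The ImageNet architectures
    raise: with ``pretrained=True`` because their weights are not
    obtainable in this installation (and random initialization in place of
    pretrained weights would be silently wrong), and without pretraining
    because a randomly initialized 25M-parameter extractor has no
    supported use in this package. Their specs remain fully queryable via
    ``BACKBONE_REGISTRY``.
    """
    if name not in BACKBONE_REGISTRY:
        raise ValueError(f"unknown backbone {name!r}; available: {sorted(BACKBONE_REGISTRY)}")
    spec = BACKBONE_REGISTRY[name]
    if not spec.runnable:
        if pretrained:
            raise PretrainedWeightsUnavailable(
                f"pretrained weights for {name!r} are not available in this "
                "installation; refusing to substitute random initialization")
        raise PretrainedWeightsUnavailable(
            f"backbone {name!r} is an architecture-spec adapter (parameter "
            "counting and geometry only); use backbone='tiny' for runnable models")
    return TinyBackbone(rng=rng, trainable=trainable)


def count_parameters(model) -> int:
    """Exact parameter count of a runnable model or a registered spec name."""
    if isinstance(model, str):
        return BACKBONE_REGISTRY[model].parameter_count() if model != "tiny" \
            else TinyBackbone().n_parameters
    if isinstance(model, BackboneSpec):
        return model.parameter_count()
    n = 0
    layers = getattr(model, "layers", None)
    if layers is None:
        return model.n_parameters
    for layer in layers:
        n += sum(int(p.size) for _, p, _ in layer.parameters())
    return n


def parameters_in_millions(count: int | str, decimals: int = 1) -> float:
    if isinstance(count, str):
        count = count_parameters(count)
    return round(count / 1e6, decimals)
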