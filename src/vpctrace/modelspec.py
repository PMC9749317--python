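"""Classifier architecture specs and builders.

Three families:

* 2-D image model — a convolutional backbone over the 256 x 512 x 3
  printout tensor, then global average pooling, a dense layer (default
  width 512), dropout 0.5 and a 2-way softmax output.
* single-input 1-D model — a stack of conv blocks (1-D conv stride 3,
  batch norm, ReLU, max pool size 5 stride 3) over the full 1250 x 12
  tensor, then GAP, dropout 0.5 and dense(2).
* multi-input 1-D model — twelve weight-independent copies of the block
  stack, one per lead of shape 1250 x 1, GAP features concatenated and
  fed straight to dense(2) (no dropout in this head).

With stride-3 convs and stride-3 pools each full block shrinks the
sequence roughly nine-fold, so from 1250 samples at most two pooled
blocks plus one unpooled conv block fit — the default stack is three
blocks with filters (32, 64, 128) and pooling on the first two.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .nn import (
    AvgPool2D,
    BatchNorm,
    Conv1D,
    Conv2D,
    Dense,
    Dropout,
    GlobalAvgPool1D,
    GlobalAvgPool2D,
    MaxPool1D,
    MaxPool2D,
    MultiInputModel,
    ReLU,
    ResidualConv1D,
    Sequential,
)

SWEEP_KERNEL_SIZES = (3, 5, 7, 9, 11)


def conv_output_length(length: int, kernel: int, stride: int) -> int:
    """Valid-padding output length: floor((L - k) / s) + 1."""
    if length < kernel:
        raise ValueError(f"length {length} shorter than kernel {kernel}")
    return (length - kernel) // stride + 1


@dataclass(frozen=True)
class ConvBlockSpec:
    """One 1-D block: conv (stride 3) + batch norm + ReLU [+ max pool 5/3]."""

    n_filters: int
    kernel_size: int = 7
    conv_stride: int = 3
    pool_size: int = 5
    pool_stride: int = 3
    pool: bool = True

    def __post_init__(self):
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if min(self.conv_stride, self.pool_stride) < 1:
            raise ValueError("strides must be >= 1")


@dataclass(frozen=True)
class TimeSeriesModelSpec:
    mode: str = "single_input"            # or "multi_input"
    blocks: tuple = (
        ConvBlockSpec(32), ConvBlockSpec(64), ConvBlockSpec(128, pool=False),
    )
    input_len: int = 1250
    n_leads: int = 12
    dropout_rate: float = 0.5
    n_classes: int = 2
    residual: bool = False

    def __post_init__(self):
        if self.mode not in ("single_input", "multi_input"):
            raise ValueError("mode must be 'single_input' or 'multi_input'")
        if not self.blocks:
            raise ValueError("at least one conv block is required")
        if self.n_classes != 2:
            raise ValueError("the classifier is two-way (VPC vs NOR)")


@dataclass(frozen=True)
class ImageModelSpec:
    backbone_id: str = "TINY"
    dense_size: int = 512
    dropout_rate: float = 0.5
    n_classes: int = 2
    input_shape: tuple = (256, 512, 3)

    def __post_init__(self):
        if self.dense_size < 1:
            raise ValueError("dense_size must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes != 2:
            raise ValueError("the classifier is two-way (VPC vs NOR)")


def ts_feature_lengths(spec: TimeSeriesModelSpec) -> list:
    """Sequence length after each conv / pool stage (shape arithmetic)."""
    L = spec.input_len
    out = []
    for b in spec.blocks:
        L = conv_output_length(L, b.kernel_size, b.conv_stride)
        out.append(L)
        if b.pool:
            L = conv_output_length(L, b.pool_size, b.pool_stride)
            out.append(L)
    return out


def default_ts_spec(mode: str = "single_input", kernel_size: int = 7,
                    residual: bool = False) -> TimeSeriesModelSpec:
    blocks = tuple(
        replace(b, kernel_size=kernel_size)
        for b in TimeSeriesModelSpec().blocks
    )
    return TimeSeriesModelSpec(mode=mode, blocks=blocks, residual=residual)


def tiny_ts_spec(mode: str = "single_input", kernel_size: int = 7) -> TimeSeriesModelSpec:
    """Small two-block stack for CPU-bound experiments and tests."""
    blocks = (
        ConvBlockSpec(16, kernel_size=kernel_size),
        ConvBlockSpec(32, kernel_size=kernel_size),
    )
    return TimeSeriesModelSpec(mode=mode, blocks=blocks)


def _ts_stack(spec: TimeSeriesModelSpec, in_ch: int, rng) -> tuple:
    """Conv-block stack layers and the final channel width."""
    layers = []
    ch = in_ch
    L = spec.input_len
    for b in spec.blocks:
        L = conv_output_length(L, b.kernel_size, b.conv_stride)
        if spec.residual:
            layers.append(ResidualConv1D(ch, b.n_filters, b.kernel_size,
                                         b.conv_stride, rng))
        else:
            layers.append(Conv1D(ch, b.n_filters, b.kernel_size, b.conv_stride, rng))
            layers.append(BatchNorm(b.n_filters))
            layers.append(ReLU())
        if b.pool:
            L = conv_output_length(L, b.pool_size, b.pool_stride)
            layers.append(MaxPool1D(b.pool_size, b.pool_stride))
        ch = b.n_filters
    layers.append(GlobalAvgPool1D())
    return layers, ch


def build_ts_model(spec: TimeSeriesModelSpec, seed: int = 0):
    """Build a runnable time-series model from its spec.

    Kernel sizes outside the canonical sweep range {3, 5, 7, 9, 11} are
    accepted with a warning.
    """
    for b in spec.blocks:
        if b.kernel_size not in SWEEP_KERNEL_SIZES:
            warnings.warn(
                f"kernel size {b.kernel_size} is outside the usual sweep "
                f"range {SWEEP_KERNEL_SIZES}", stacklevel=2)
    ts_feature_lengths(spec)  # raises early if the stack cannot fit
    rng = np.random.default_rng(seed)
    if spec.mode == "single_input":
        layers, ch = _ts_stack(spec, spec.n_leads, rng)
        layers.append(Dropout(spec.dropout_rate, rng))
        layers.append(Dense(ch, spec.n_classes, rng))
        return Sequential(layers)
    branches = []
    for _ in range(spec.n_leads):
        layers, ch = _ts_stack(spec, 1, rng)
        branches.append(Sequential(layers))
    head = Sequential([Dense(spec.n_leads * ch, spec.n_classes, rng)])
    return MultiInputModel(branches, head)


def _tiny_backbone(rng) -> tuple:
    """Small 2-D backbone: 4x average pool, then three conv/pool stages."""
    layers = [AvgPool2D(4)]
    ch = 3
    for out_ch in (8, 16, 32):
        layers += [Conv2D(ch, out_ch, 3, 1, rng), BatchNorm(out_ch), ReLU(),
                   MaxPool2D(2)]
        ch = out_ch
    layers.append(GlobalAvgPool2D())
    return layers, ch


_VGG16_CFG = (64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
              512, 512, 512, "M", 512, 512, 512, "M")


def _vgg16_backbone(rng) -> tuple:
    """The 13-conv VGG16 feature stack (3x3 convs, 2x2 pools, no batch
    norm), built with valid padding.  Constructible and trainable in
    principle, but far too slow for routine CPU use — prefer TINY."""
    layers = []
    ch = 3
    for item in _VGG16_CFG:
        if item == "M":
            layers.append(MaxPool2D(2))
        else:
            layers += [Conv2D(ch, item, 3, 1, rng), ReLU()]
            ch = item
    layers.append(GlobalAvgPool2D())
    return layers, ch


def _unavailable(name):
    def _raise(rng):
        raise NotImplementedError(
            f"backbone {name!r} has no CPU implementation in this package; "
            "runnable backbones: TINY, VGG16"
        )
    return _raise


BACKBONES = {
    "TINY": _tiny_backbone,
    "VGG16": _vgg16_backbone,
    "ResNet50V2": _unavailable("ResNet50V2"),
    "InceptionV3": _unavailable("InceptionV3"),
    "InceptionResNetV2": _unavailable("InceptionResNetV2"),
    "Xception": _unavailable("Xception"),
}


def build_image_model(spec: ImageModelSpec, seed: int = 0):
    """Backbone -> GAP -> dense(dense_size) -> dropout -> dense(2)."""
    if spec.backbone_id not in BACKBONES:
        raise ValueError(
            f"unknown backbone {spec.backbone_id!r}; registry: "
            f"{sorted(BACKBONES)}"
        )
    rng = np.random.default_rng(seed)
    backbone, ch = BACKBONES[spec.backbone_id](rng)
    head = [
        Dense(ch, spec.dense_size, rng),
        ReLU(),
        Dropout(spec.dropout_rate, rng),
        Dense(spec.dense_size, spec.n_classes, rng),
    ]
    return Sequential(backbone + head)


def kernel_size_grid(mode: str, sizes=SWEEP_KERNEL_SIZES,
                     base: TimeSeriesModelSpec | None = None) -> list:
    """One spec per kernel size, identical in every other field."""
    if not sizes:
        raise ValueError("sizes must be nonempty")
    base = base if base is not None else default_ts_spec(mode)
    out = []
    for k in sizes:
        blocks = tuple(replace(b, kernel_size=k) for b in base.blocks)
        out.append(dataclasses.replace(base, mode=mode, blocks=blocks))
    return out
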