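"""CNN backbone architectures built on the NumPy layer engine.

Each builder returns a :class:`BackboneModel` whose ``forward_features``
yields the activation vector at the network's global-pooling tap point — the
layer immediately preceding the classification head — which is where deep
features are harvested for fusion with the texture battery:

================  ===========================  ==============
backbone          tap point                    vector length
================  ===========================  ==============
ResNet101         pool5 (global avg pool)      2048
InceptionV3       avg_pool                     2048
EfficientNet_b0   GlobAvgPool                  1280
EfficientNet_ASPP gapool (after ASPP)          3 x branch width
ConvNext_base     adaptiveAvgPool2d            1024
tiny_test_cnn     gap                          64
================  ===========================  ==============

The classification head of every backbone is a fresh 2-way linear layer
(HCC vs PAR).  Weights are randomly initialized (He for convolutions); no
pretrained checkpoints are bundled.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    AvgPool2d,
    BatchNorm2d,
    Conv2d,
    Dropout,
    GELU,
    GlobalAvgPool,
    Layer,
    LayerNorm2d,
    Linear,
    MaxPool2d,
    ReLU,
    Sequential,
    Sigmoid,
    SiLU,
)

__all__ = [
    "BackboneModel", "ASPPHead", "build_resnet101", "build_inception_v3",
    "build_efficientnet_b0", "build_efficientnet_aspp", "build_convnext_base",
    "build_tiny_test_cnn",
]


class BackboneModel:
    """A feature-extracting CNN with a 2-way classification head.

    ``forward_features`` maps an (N, C, H, W) float batch in [0, 1] to the
    (N, feature_length) tap activations; ``forward_logits`` applies the head.
    """

    def __init__(self, name: str, features: Layer, head: Linear, input_size: int,
                 in_channels: int, tap_layer: str, feature_length: int):
        self.name = name
        self.features = features
        self.head = head
        self.input_size = input_size
        self.in_channels = in_channels
        self.tap_layer = tap_layer
        self.feature_length = feature_length

    def forward_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.features.forward(np.asarray(x, dtype=np.float32), train=train)

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.forward_features(x, train=train), train=train)


def _conv_bn(in_ch, out_ch, kernel, rng, stride=1, pad=0, act="relu", groups=1, dilation=1):
    actf = {"relu": ReLU, "silu": SiLU}[act]
    return Sequential(
        Conv2d(in_ch, out_ch, kernel, stride=stride, pad=pad, groups=groups,
               dilation=dilation, bias=False, rng=rng),
        BatchNorm2d(out_ch),
        actf(),
    )


# ---------------------------------------------------------------- ResNet101

class _Bottleneck(Layer):
    def __init__(self, in_ch, mid, out_ch, stride, rng):
        self.conv1 = _conv_bn(in_ch, mid, 1, rng)
        self.conv2 = _conv_bn(mid, mid, 3, rng, stride=stride, pad=1)
        self.conv3 = Sequential(Conv2d(mid, out_ch, 1, bias=False, rng=rng), BatchNorm2d(out_ch))
        if stride != 1 or in_ch != out_ch:
            self.down = Sequential(Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
                                   BatchNorm2d(out_ch))
        else:
            self.down = None
        self.relu = ReLU()

    def forward(self, x, train=False):
        identity = x if self.down is None else self.down.forward(x)
        out = self.conv3.forward(self.conv2.forward(self.conv1.forward(x)))
        return self.relu.forward(out + identity)


def build_resnet101(rng: np.random.Generator | None = None) -> BackboneModel:
    """ResNet101: stem + bottleneck stages [3, 4, 23, 3]; pool5 tap of width 2048."""
    rng = rng or np.random.default_rng(0)
    layers: list[Layer] = [
        _conv_bn(3, 64, 7, rng, stride=2, pad=3),
        MaxPool2d(3, stride=2, pad=1),
    ]
    in_ch = 64
    for mid, blocks, stride in ((64, 3, 1), (128, 4, 2), (256, 23, 2), (512, 3, 2)):
        out_ch = mid * 4
        for b in range(blocks):
            layers.append(_Bottleneck(in_ch, mid, out_ch, stride if b == 0 else 1, rng))
            in_ch = out_ch
    layers.append(GlobalAvgPool())
    return BackboneModel("ResNet101", Sequential(*layers), Linear(2048, 2, rng=rng),
                         input_size=224, in_channels=3, tap_layer="pool5", feature_length=2048)


# ------------------------------------------------------------- InceptionV3

class _Branches(Layer):
    """Parallel branches whose outputs are concatenated along channels."""

    def __init__(self, *branches: Layer):
        self.branches = branches

    def forward(self, x, train=False):
        return np.concatenate([b.forward(x) for b in self.branches], axis=1)


def _inception_a(in_ch, pool_ch, rng):
    return _Branches(
        _conv_bn(in_ch, 64, 1, rng),
        Sequential(_conv_bn(in_ch, 48, 1, rng), _conv_bn(48, 64, 5, rng, pad=2)),
        Sequential(_conv_bn(in_ch, 64, 1, rng), _conv_bn(64, 96, 3, rng, pad=1),
                   _conv_bn(96, 96, 3, rng, pad=1)),
        Sequential(AvgPool2d(3, stride=1, pad=1), _conv_bn(in_ch, pool_ch, 1, rng)),
    )


def _inception_b(in_ch, rng):
    return _Branches(
        _conv_bn(in_ch, 384, 3, rng, stride=2),
        Sequential(_conv_bn(in_ch, 64, 1, rng), _conv_bn(64, 96, 3, rng, pad=1),
                   _conv_bn(96, 96, 3, rng, stride=2)),
        MaxPool2d(3, stride=2),
    )


def _inception_c(in_ch, c7, rng):
    return _Branches(
        _conv_bn(in_ch, 192, 1, rng),
        Sequential(_conv_bn(in_ch, c7, 1, rng), _conv_bn(c7, c7, (1, 7), rng, pad=(0, 3)),
                   _conv_bn(c7, 192, (7, 1), rng, pad=(3, 0))),
        Sequential(_conv_bn(in_ch, c7, 1, rng), _conv_bn(c7, c7, (7, 1), rng, pad=(3, 0)),
                   _conv_bn(c7, c7, (1, 7), rng, pad=(0, 3)),
                   _conv_bn(c7, c7, (7, 1), rng, pad=(3, 0)),
                   _conv_bn(c7, 192, (1, 7), rng, pad=(0, 3))),
        Sequential(AvgPool2d(3, stride=1, pad=1), _conv_bn(in_ch, 192, 1, rng)),
    )


def _inception_d(in_ch, rng):
    return _Branches(
        Sequential(_conv_bn(in_ch, 192, 1, rng), _conv_bn(192, 320, 3, rng, stride=2)),
        Sequential(_conv_bn(in_ch, 192, 1, rng), _conv_bn(192, 192, (1, 7), rng, pad=(0, 3)),
                   _conv_bn(192, 192, (7, 1), rng, pad=(3, 0)),
                   _conv_bn(192, 192, 3, rng, stride=2)),
        MaxPool2d(3, stride=2),
    )


def _inception_e(in_ch, rng):
    return _Branches(
        _conv_bn(in_ch, 320, 1, rng),
        Sequential(_conv_bn(in_ch, 384, 1, rng),
                   _Branches(_conv_bn(384, 384, (1, 3), rng, pad=(0, 1)),
                             _conv_bn(384, 384, (3, 1), rng, pad=(1, 0)))),
        Sequential(_conv_bn(in_ch, 448, 1, rng), _conv_bn(448, 384, 3, rng, pad=1),
                   _Branches(_conv_bn(384, 384, (1, 3), rng, pad=(0, 1)),
                             _conv_bn(384, 384, (3, 1), rng, pad=(1, 0)))),
        Sequential(AvgPool2d(3, stride=1, pad=1), _conv_bn(in_ch, 192, 1, rng)),
    )


def build_inception_v3(rng: np.random.Generator | None = None) -> BackboneModel:
    """InceptionV3 (299 input): stem, A/B/C/D/E mixed blocks; avg_pool tap of width 2048."""
    rng = rng or np.random.default_rng(0)
    features = Sequential(
        _conv_bn(3, 32, 3, rng, stride=2),
        _conv_bn(32, 32, 3, rng),
        _conv_bn(32, 64, 3, rng, pad=1),
        MaxPool2d(3, stride=2),
        _conv_bn(64, 80, 1, rng),
        _conv_bn(80, 192, 3, rng),
        MaxPool2d(3, stride=2),
        _inception_a(192, 32, rng),
        _inception_a(256, 64, rng),
        _inception_a(288, 64, rng),
        _inception_b(288, rng),
        _inception_c(768, 128, rng),
        _inception_c(768, 160, rng),
        _inception_c(768, 160, rng),
        _inception_c(768, 192, rng),
        _inception_d(768, rng),
        _inception_e(1280, rng),
        _inception_e(2048, rng),
        GlobalAvgPool(),
    )
    return BackboneModel("InceptionV3", features, Linear(2048, 2, rng=rng),
                         input_size=299, in_channels=3, tap_layer="avg_pool",
                         feature_length=2048)


# ---------------------------------------------------------- EfficientNet_b0

class _SqueezeExcite(Layer):
    def __init__(self, ch, reduced, rng):
        self.fc1 = Linear(ch, reduced, rng=rng)
        self.fc2 = Linear(reduced, ch, rng=rng)
        self.silu = SiLU()
        self.sig = Sigmoid()

    def forward(self, x, train=False):
        s = x.mean(axis=(2, 3))
        s = self.sig.forward(self.fc2.forward(self.silu.forward(self.fc1.forward(s))))
        return x * s[:, :, None, None]


class _MBConv(Layer):
    def __init__(self, in_ch, out_ch, expand, kernel, stride, rng):
        mid = in_ch * expand
        self.expand = _conv_bn(in_ch, mid, 1, rng, act="silu") if expand != 1 else None
        self.depthwise = _conv_bn(mid, mid, kernel, rng, stride=stride,
                                  pad=kernel // 2, act="silu", groups=mid)
        self.se = _SqueezeExcite(mid, max(1, in_ch // 4), rng)
        self.project = Sequential(Conv2d(mid, out_ch, 1, bias=False, rng=rng),
                                  BatchNorm2d(out_ch))
        self.residual = stride == 1 and in_ch == out_ch

    def forward(self, x, train=False):
        out = x if self.expand is None else self.expand.forward(x)
        out = self.project.forward(self.se.forward(self.depthwise.forward(out)))
        return out + x if self.residual else out


_EFFNET_B0_STAGES = (
    # expand, out_ch, repeats, stride, kernel
    (1, 16, 1, 1, 3),
    (6, 24, 2, 2, 3),
    (6, 40, 2, 2, 5),
    (6, 80, 3, 2, 3),
    (6, 112, 3, 1, 5),
    (6, 192, 4, 2, 5),
    (6, 320, 1, 1, 3),
)


def _effnet_trunk(rng) -> tuple[Sequential, int]:
    layers: list[Layer] = [_conv_bn(3, 32, 3, rng, stride=2, pad=1, act="silu")]
    in_ch = 32
    for expand, out_ch, repeats, stride, kernel in _EFFNET_B0_STAGES:
        for r in range(repeats):
            layers.append(_MBConv(in_ch, out_ch, expand, kernel, stride if r == 0 else 1, rng))
            in_ch = out_ch
    layers.append(_conv_bn(in_ch, 1280, 1, rng, act="silu"))
    return Sequential(*layers), 1280


def build_efficientnet_b0(rng: np.random.Generator | None = None) -> BackboneModel:
    """EfficientNet_b0 (224 input): MBConv trunk + 1280-wide head; GlobAvgPool tap.

    The tap length is the canonical head width actually built (1280).
    """
    rng = rng or np.random.default_rng(0)
    trunk, width = _effnet_trunk(rng)
    features = Sequential(trunk, GlobalAvgPool(), Dropout(0.2, rng=rng))
    return BackboneModel("EfficientNet_b0", features, Linear(width, 2, rng=rng),
                         input_size=224, in_channels=3, tap_layer="GlobAvgPool",
                         feature_length=width)


class ASPPHead(Layer):
    """Atrous spatial pyramid pooling head.

    Three parallel branches on the incoming feature map — a 1x1 convolution
    and two 3x3 atrous convolutions with dilation rates 2 and 3 (padding
    preserves the spatial size) — are depth-concatenated to 3x``branch_channels``
    channels, globally average-pooled, and passed through dropout.
    """

    def __init__(self, input_channels: int, branch_channels: int = 256,
                 dropout_p: float = 0.5, rng: np.random.Generator | None = None):
        if branch_channels <= 0:
            raise ValueError(f"branch_channels must be positive, got {branch_channels}")
        rng = rng or np.random.default_rng(0)
        self.branch1 = Conv2d(input_channels, branch_channels, 1, rng=rng)
        self.branch2 = Conv2d(input_channels, branch_channels, 3, pad=2, dilation=2, rng=rng)
        self.branch3 = Conv2d(input_channels, branch_channels, 3, pad=3, dilation=3, rng=rng)
        self.pool = GlobalAvgPool()
        self.dropout = Dropout(dropout_p, rng=rng)
        self.out_channels = 3 * branch_channels

    def forward(self, x, train=False):
        cat = np.concatenate(
            [self.branch1.forward(x), self.branch2.forward(x), self.branch3.forward(x)],
            axis=1,
        )
        return self.dropout.forward(self.pool.forward(cat), train=train)


def build_efficientnet_aspp(rng: np.random.Generator | None = None,
                            branch_channels: int = 256,
                            dropout_p: float = 0.5) -> BackboneModel:
    """EfficientNet_b0 trunk with an ASPP module before the classifier (gapool tap).

    The tap length is 3 x ``branch_channels`` as built.
    """
    rng = rng or np.random.default_rng(0)
    trunk, width = _effnet_trunk(rng)
    head = ASPPHead(width, branch_channels=branch_channels, dropout_p=dropout_p, rng=rng)
    features = Sequential(trunk, head)
    return BackboneModel("EfficientNet_ASPP", features, Linear(head.out_channels, 2, rng=rng),
                         input_size=224, in_channels=3, tap_layer="gapool",
                         feature_length=head.out_channels)


# ------------------------------------------------------------ ConvNext_base

class _ConvNextBlock(Layer):
    def __init__(self, ch, rng, layer_scale=1e-6):
        self.dw = Conv2d(ch, ch, 7, pad=3, groups=ch, rng=rng)
        self.norm = LayerNorm2d(ch)
        self.pw1 = Conv2d(ch, 4 * ch, 1, rng=rng)
        self.act = GELU()
        self.pw2 = Conv2d(4 * ch, ch, 1, rng=rng)
        self.gamma = np.full(ch, layer_scale, dtype=np.float32)

    def forward(self, x, train=False):
        out = self.norm.forward(self.dw.forward(x))
        out = self.pw2.forward(self.act.forward(self.pw1.forward(out)))
        return x + out * self.gamma[None, :, None, None]


def build_convnext_base(rng: np.random.Generator | None = None) -> BackboneModel:
    """ConvNext_base: 4x4 patchify stem, stages [3, 3, 27, 3] of widths
    [128, 256, 512, 1024]; adaptiveAvgPool2d tap of width 1024."""
    rng = rng or np.random.default_rng(0)
    dims = (128, 256, 512, 1024)
    depths = (3, 3, 27, 3)
    layers: list[Layer] = [Conv2d(3, dims[0], 4, stride=4, rng=rng), LayerNorm2d(dims[0])]
    for i, (dim, depth) in enumerate(zip(dims, depths)):
        if i > 0:
            layers += [LayerNorm2d(dims[i - 1]), Conv2d(dims[i - 1], dim, 2, stride=2, rng=rng)]
        layers += [_ConvNextBlock(dim, rng) for _ in range(depth)]
    layers += [GlobalAvgPool()]
    features = Sequential(*layers)
    return BackboneModel("ConvNext_base", features, Linear(dims[-1], 2, rng=rng),
                         input_size=224, in_channels=3, tap_layer="adaptiveAvgPool2d",
                         feature_length=dims[-1])


# ------------------------------------------------------------- tiny_test_cnn

class TinyCNN(BackboneModel):
    """Small 3-conv-block CNN for desk-scale experiments; fully trainable.

    Grayscale 56x56 input, 64-channel global-average-pooled features, 2-way
    head.  Supports backpropagation through all layers.
    """

    def __init__(self, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        features = Sequential(
            Conv2d(1, 16, 3, pad=1, rng=rng), ReLU(), MaxPool2d(2),
            Conv2d(16, 32, 3, pad=1, rng=rng), ReLU(), MaxPool2d(2),
            Conv2d(32, 64, 3, pad=1, rng=rng), ReLU(), MaxPool2d(2),
            GlobalAvgPool(),
        )
        super().__init__("tiny_test_cnn", features, Linear(64, 2, rng=rng),
                         input_size=56, in_channels=1, tap_layer="gap", feature_length=64)

    def trainable(self):
        """(param, grad-getter) pairs for the SGDM update."""
        modules = [self.features, self.head]
        for m in modules:
            yield m


def build_tiny_test_cnn(rng: np.random.Generator | None = None) -> TinyCNN:
    return TinyCNN(rng)
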