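"""Deep-feature extraction: backbone construction, fine-tuning, activation tapping.

Deep features are the activations at the global-pooling layer of a CNN
backbone (the layer just before the fully connected classifier), harvested
per patch and aligned row-by-row with the texture feature matrix.  Training
uses stochastic gradient descent with momentum (SGDM) and the study's
hyperparameters: learning rate 0.0002, momentum 0.9, minibatch 30,
100 epochs, 2 outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .nn.backbones import (
    ASPPHead,
    BackboneModel,
    TinyCNN,
    build_convnext_base,
    build_efficientnet_aspp,
    build_efficientnet_b0,
    build_inception_v3,
    build_resnet101,
    build_tiny_test_cnn,
)
from .nn.layers import softmax_cross_entropy
from .patch_io import HCC, Patch

__all__ = [
    "DeepFeatureSpec",
    "TrainConfig",
    "BACKBONE_BUILDERS",
    "build_backbone",
    "build_aspp_head",
    "finetune",
    "extract_features",
    "patches_to_batch",
]

BACKBONE_BUILDERS = {
    "ResNet101": build_resnet101,
    "InceptionV3": build_inception_v3,
    "EfficientNet_b0": build_efficientnet_b0,
    "EfficientNet_ASPP": build_efficientnet_aspp,
    "ConvNext_base": build_convnext_base,
    "tiny_test_cnn": build_tiny_test_cnn,
}


@dataclass
class DeepFeatureSpec:
    """Which backbone to build and where to tap it.

    ``expected_length`` may be left None, in which case it is filled from the
    built model; if set, a mismatch with the built tap width is an error.
    """

    backbone_name: str
    tap_layer: str | None = None
    expected_length: int | None = None
    pretrained: bool = False
    seed: int = 0


@dataclass
class TrainConfig:
    """SGDM fine-tuning hyperparameters (study defaults)."""

    learning_rate: float = 0.0002
    momentum: float = 0.9
    minibatch: int = 30
    epochs: int = 100
    num_outputs: int = 2


def build_backbone(spec: DeepFeatureSpec) -> BackboneModel:
    """Build the requested backbone with its 2-way head and registered tap point."""
    if spec.backbone_name not in BACKBONE_BUILDERS:
        raise ValueError(
            f"unknown backbone {spec.backbone_name!r}; supported: {sorted(BACKBONE_BUILDERS)}"
        )
    if spec.pretrained:
        raise ValueError(
            "no pretrained checkpoints are bundled with this package; "
            "build with pretrained=False (random initialization)"
        )
    model = BACKBONE_BUILDERS[spec.backbone_name](np.random.default_rng(spec.seed))
    if spec.tap_layer is not None and spec.tap_layer != model.tap_layer:
        raise ValueError(
            f"tap layer {spec.tap_layer!r} not available for {spec.backbone_name}; "
            f"available: {model.tap_layer!r}"
        )
    if spec.expected_length is not None and spec.expected_length != model.feature_length:
        raise ValueError(
            f"{spec.backbone_name} tap yields {model.feature_length} features, "
            f"not the declared {spec.expected_length}"
        )
    spec.expected_length = model.feature_length
    return model


def build_aspp_head(input_channels: int, branch_channels: int = 256,
                    dropout_p: float = 0.5, seed: int = 0) -> ASPPHead:
    """Standalone atrous-spatial-pyramid-pooling head (see :class:`ASPPHead`)."""
    return ASPPHead(input_channels, branch_channels, dropout_p,
                    rng=np.random.default_rng(seed))


def patches_to_batch(patches: list[Patch], model: BackboneModel) -> np.ndarray:
    """Resize patches to the backbone's input size and replicate gray to its channels."""
    size = model.input_size
    batch = np.empty((len(patches), model.in_channels, size, size), dtype=np.float32)
    for i, p in enumerate(patches):
        arr = p.pixels.astype(np.float32) / 255.0
        if arr.shape[0] != size:
            arr = ndimage.zoom(arr, size / arr.shape[0], order=1)
            arr = arr[:size, :size]
            if arr.shape[0] < size or arr.shape[1] < size:
                arr = np.pad(arr, ((0, size - arr.shape[0]), (0, size - arr.shape[1])),
                             mode="edge")
        batch[i] = arr[None, :, :]
    return batch


def _labels_to_index(patches: list[Patch]) -> np.ndarray:
    return np.array([1 if p.label == HCC else 0 for p in patches], dtype=np.int64)


def _sgdm_step(param_layers, lr, momentum, velocities):
    for layer in param_layers:
        for (name, p), (_, g) in zip(layer.params(), layer.grads()):
            if g is None:
                continue
            key = (id(layer), name)
            v = velocities.get(key)
            if v is None:
                v = np.zeros_like(p)
            v = momentum * v - lr * g
            velocities[key] = v
            p += v


def finetune(
    model: BackboneModel,
    patches: list[Patch],
    config: TrainConfig | None = None,
    seed: int = 0,
    mode: str = "auto",
) -> BackboneModel:
    """Fine-tune a backbone's 2-class head (or the full tiny network) with SGDM.

    ``mode='full'`` backpropagates through every layer and is supported for
    the tiny test CNN; ``mode='head'`` trains only the linear head on frozen
    tap features and works for every backbone.  ``'auto'`` picks full for the
    tiny CNN and head otherwise.  Per-epoch mean losses are recorded on
    ``model.loss_history``.  Deterministic given the seed.
    """
    config = config or TrainConfig()
    if config.num_outputs != 2:
        raise ValueError("this task is binary: num_outputs must be 2")
    y = _labels_to_index(patches)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if mode == "auto":
        mode = "full" if isinstance(model, TinyCNN) else "head"
    if mode == "full" and not isinstance(model, TinyCNN):
        raise ValueError("full-network training is supported for tiny_test_cnn only")
    rng = np.random.default_rng(seed)
    x = patches_to_batch(patches, model)
    n = len(patches)
    velocities: dict = {}
    losses: list[float] = []
    frozen_feats = model.forward_features(x) if mode == "head" else None
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.minibatch):
            idx = order[start : start + config.minibatch]
            if mode == "full":
                feats = model.forward_features(x[idx], train=True)
                logits = model.head.forward(feats, train=True)
                loss, dlogits = softmax_cross_entropy(logits, y[idx])
                dfeats = model.head.backward(dlogits)
                model.features.backward(dfeats)
                _sgdm_step([model.features, model.head], config.learning_rate,
                           config.momentum, velocities)
            else:
                logits = model.head.forward(frozen_feats[idx], train=True)
                loss, dlogits = softmax_cross_entropy(logits, y[idx])
                model.head.backward(dlogits)
                _sgdm_step([model.head], config.learning_rate, config.momentum, velocities)
            epoch_losses.append(loss)
        losses.append(float(np.mean(epoch_losses)))
    model.loss_history = losses
    return model


def extract_features(
    model: BackboneModel,
    patches: list[Patch],
    tap_layer: str | None = None,
    batch_size: int = 64,
) -> pd.DataFrame:
    """Tap activations for each patch; one row per patch, columns <backbone>_f<i>.

    Extraction runs in evaluation mode (dropout inactive), so it is
    deterministic and identical patches yield identical rows.
    """
    if tap_layer is not None and tap_layer != model.tap_layer:
        raise ValueError(
            f"tap layer {tap_layer!r} absent; available layers: [{model.tap_layer!r}]"
        )
    rows = []
    for start in range(0, len(patches), batch_size):
        chunk = patches[start : start + batch_size]
        rows.append(model.forward_features(patches_to_batch(chunk, model)))
    feats = np.vstack(rows) if rows else np.zeros((0, model.feature_length))
    cols = [f"{model.name}_f{i}" for i in range(model.feature_length)]
    return pd.DataFrame(feats, columns=cols)
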