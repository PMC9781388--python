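"""The tooth-texture CNN: architecture, augmentation, training, inference.

The default architecture is a 14-layer stack — input, four 3x3
convolutions (16, 32, 32, 64 filters), three 2x2 max-pool layers
interleaved, dropout after the last convolution and after the first dense
layer, a flatten, two ReLU dense layers (156 and 344 units), and a 9-way
softmax output. The dense widths were solved so the default model has
exactly 728,789 trainable parameters at 64x64x1 input.

Training minimizes categorical cross-entropy with Adam, augments training
batches only (random affine: rotation, zoom, shifts, shear), and stops
early once validation loss has not improved for a configured number of
epochs, restoring the best weights seen.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .errors import ParameterError


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the classifier.

    ``conv_blocks`` are (filters, kernel_size) pairs; pools are 2x2 and
    placed after the first three convolutions; dropouts sit after the last
    convolution and after the first dense layer.
    """

    input_size: int = 64
    conv_blocks: tuple[tuple[int, int], ...] = ((16, 3), (32, 3), (32, 3), (64, 3))
    dropout_rates: tuple[float, float] = (0.25, 0.5)
    dense_units: tuple[int, ...] = (156, 344)
    n_classes: int = 9

    def validate(self) -> None:
        if len(self.conv_blocks) != 4:
            raise ParameterError("exactly 4 convolutional blocks required")
        if len(self.dropout_rates) != 2:
            raise ParameterError("exactly 2 dropout rates required")
        if not self.dense_units:
            raise ParameterError("at least one dense layer required")
        if self.input_size % 8:
            raise ParameterError("input_size must be divisible by 8 (three 2x2 pools)")
        if self.n_classes < 2:
            raise ParameterError("need at least 2 classes")


@dataclass(frozen=True)
class AugmentationConfig:
    """Random affine augmentation ranges; all zero (or disabled) = identity."""

    rotation_range: float = 15.0  # degrees, +/-
    zoom_range: float = 0.1  # fraction, +/-
    width_shift: float = 0.1  # fraction of width, +/-
    height_shift: float = 0.1  # fraction of height, +/-
    shear_range: float = 10.0  # degrees, +/-
    enabled: bool = True

    def validate(self) -> None:
        for v in (self.rotation_range, self.zoom_range, self.width_shift,
                  self.height_shift, self.shear_range):
            if v < 0:
                raise ParameterError("augmentation ranges must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    max_epochs: int = 250
    split_ratio: float = 0.8
    early_stop_patience: int = 20
    seed: int = 0
    learning_rate: float = 1e-3

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if not 0 < self.split_ratio < 1:
            raise ParameterError("split_ratio must lie in (0, 1)")
        if self.max_epochs < 1 or self.early_stop_patience < 0:
            raise ParameterError("invalid epoch/patience settings")


def build_model(cfg: ModelConfig = ModelConfig()) -> nn.Network:
    """Instantiate (and shape-check) the network for ``cfg``.

    Layer counting convention: input + 4 conv + 3 pool + 2 dropout +
    flatten + hidden dense stack + softmax output; the default config
    yields 14 named layers.
    """
    cfg.validate()
    (f1, k1), (f2, k2), (f3, k3), (f4, k4) = cfg.conv_blocks
    layers: list[tuple[str, nn.Layer]] = [
        ("input", nn.Input((cfg.input_size, cfg.input_size, 1))),
        ("conv1", nn.Conv2D(f1, k1)),
        ("pool1", nn.MaxPool2D(2)),
        ("conv2", nn.Conv2D(f2, k2)),
        ("pool2", nn.MaxPool2D(2)),
        ("conv3", nn.Conv2D(f3, k3)),
        ("pool3", nn.MaxPool2D(2)),
        ("conv4", nn.Conv2D(f4, k4)),
        ("dropout1", nn.Dropout(cfg.dropout_rates[0])),
        ("flatten", nn.Flatten()),
    ]
    for i, units in enumerate(cfg.dense_units, start=1):
        layers.append((f"dense{i}", nn.Dense(units)))
        if i == 1:
            layers.append(("dropout2", nn.Dropout(cfg.dropout_rates[1])))
    layers.append(("output", nn.Dense(cfg.n_classes, relu=False)))
    layers.append(("softmax", nn.Softmax()))

    net = nn.Network(layers)
    net.build((cfg.input_size, cfg.input_size, 1))
    net.initialize(np.random.default_rng(0))
    # counting convention folds the linear output and its softmax into one layer
    net.layer_count = len(layers) - 1
    return net


def count_parameters(model: nn.Network) -> int:
    """Total trainable weights and biases across all layers."""
    return model.n_params()


def _background_intensity(img: np.ndarray) -> float:
    border = np.concatenate([img[0], img[-1], img[:, 0], img[:, -1]])
    return float(np.median(border))


def augment_image(img, cfg: AugmentationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply one random affine transform sampled within ``cfg``'s ranges.

    The transform composes rotation, isotropic zoom, shear and translation
    about the image center; resampling is bilinear with the background
    intensity (median of the border pixels) as fill value.
    """
    cfg.validate()
    a = np.asarray(img, dtype=np.float64)
    if not cfg.enabled:
        return a.copy()
    theta = np.deg2rad(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
    zoom = 1.0 + rng.uniform(-cfg.zoom_range, cfg.zoom_range)
    shear = np.deg2rad(rng.uniform(-cfg.shear_range, cfg.shear_range))
    tr = rng.uniform(-cfg.height_shift, cfg.height_shift) * a.shape[0]
    tc = rng.uniform(-cfg.width_shift, cfg.width_shift) * a.shape[1]

    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shr = np.array([[1.0, np.tan(shear)], [0.0, 1.0]])
    m = zoom * (rot @ shr)
    center = (np.asarray(a.shape) - 1) / 2.0
    # output coord y maps to input coord m_inv @ (y - center - t) + center
    m_inv = np.linalg.inv(m)
    offset = center - m_inv @ (center + np.array([tr, tc]))
    return ndimage.affine_transform(
        a, m_inv, offset=offset, order=1, mode="constant",
        cval=_background_intensity(a),
    )


@dataclass
class History:
    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    stopped_epoch: int = 0


def _to_tensor(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    return x


def train(
    model: nn.Network,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    tcfg: TrainConfig = TrainConfig(),
    acfg: AugmentationConfig = AugmentationConfig(),
    feature_fn=None,
) -> tuple[nn.Network, History]:
    """Fit the model; returns it with the best-validation-loss weights.

    Augmentation is applied to training batches only. If ``feature_fn`` is
    given it maps each (augmented) 2D training image to the classifier
    input — e.g. a DWT texture map — so augmentation acts on the image,
    not on the extracted features; validation images must already be
    transformed. Training stops at ``max_epochs`` or once validation loss
    has gone ``early_stop_patience`` consecutive epochs without improving.
    """
    tcfg.validate()
    acfg.validate()
    x_train, y_train = train_set
    x_val, y_val = val_set
    if len(x_train) == 0:
        raise ParameterError("empty training set")
    y_train = np.asarray(y_train, dtype=np.int64)
    y_val = np.asarray(y_val, dtype=np.int64)
    if len(np.unique(y_train)) < 2:
        warnings.warn("training set contains a single class")

    rng = np.random.default_rng(tcfg.seed)
    model.initialize(rng)
    opt = nn.Adam(model, lr=tcfg.learning_rate)
    x_train = _to_tensor(x_train)
    x_val = _to_tensor(x_val)
    if feature_fn is not None and not acfg.enabled:
        # without augmentation the transform is deterministic; do it once
        x_train = np.stack([feature_fn(im[..., 0]) for im in x_train]).astype(
            np.float32
        )[..., None]
        feature_fn = None

    history = History()
    best_loss = np.inf
    best_weights = model.get_weights()
    stale = 0
    for epoch in range(1, tcfg.max_epochs + 1):
        order = rng.permutation(len(x_train))
        losses, correct = [], 0
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            xb = x_train[idx]
            if acfg.enabled or feature_fn is not None:
                planes = [im[..., 0] for im in xb]
                if acfg.enabled:
                    planes = [augment_image(p, acfg, rng) for p in planes]
                if feature_fn is not None:
                    planes = [feature_fn(p) for p in planes]
                xb = np.stack(planes).astype(np.float32)[..., None]
            yb = y_train[idx]
            probs = model.forward(xb, training=True, rng=rng)
            losses.append(nn.cross_entropy(probs, yb) * len(idx))
            correct += int((probs.argmax(axis=1) == yb).sum())
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            model.backward(grad.astype(np.float32) / len(yb))
            opt.step()
        history.train_loss.append(sum(losses) / len(order))
        history.train_acc.append(correct / len(order))

        val_probs = predict_proba(model, x_val)
        vl = nn.cross_entropy(val_probs, y_val)
        history.val_loss.append(vl)
        history.val_acc.append(float((val_probs.argmax(axis=1) == y_val).mean()))

        if vl < best_loss - 1e-9:
            best_loss = vl
            best_weights = model.get_weights()
            stale = 0
        else:
            stale += 1
            if stale > tcfg.early_stop_patience:
                break
    history.stopped_epoch = epoch
    model.set_weights(best_weights)
    return model, history


def predict_proba(model: nn.Network, images: np.ndarray,
                  batch_size: int = 64) -> np.ndarray:
    x = _to_tensor(images)
    chunks = [
        model.forward(x[i : i + batch_size], training=False)
        for i in range(0, len(x), batch_size)
    ]
    return np.concatenate(chunks) if chunks else np.zeros((0,))


def predict(model: nn.Network, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Argmax labels (ties broken toward the lower index) and probabilities."""
    probs = predict_proba(model, images)
    return probs.argmax(axis=1), probs


def weights_checksum(model: nn.Network) -> int:
    """CRC over all weight bytes — a compact reproducibility fingerprint."""
    crc = 0
    for w in model.get_weights():
        crc = zlib.crc32(np.ascontiguousarray(w).tobytes(), crc)
    return crc
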