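"""The three classifier architectures as abstract layer specifications.

* **model1** — stacked recurrent network for the 1D sequence
  representation: three LSTM layers of 128 units, each followed by
  dropout 0.2, then a fully connected head and a two-way softmax.
* **model2** — 2D convolutional network for 128 x 128 x 3 feature
  images: three conv/max-pool/batch-norm blocks with 32, 64 and 128
  filters, a 128-unit ReLU dense layer, dropout 0.5, softmax.
* **model3** — hybrid for 64 x 64 x 3 images: two conv/pool/batch-norm
  blocks (32 and 64 filters), feature maps reshaped to a sequence
  (rows as timesteps), two LSTM layers of 64 and 128 units, dropout
  0.2, dense head, softmax.

Specs are backend-independent: parameter counts come from closed forms
(``count_parameters``) and ``compile_network`` instantiates the numpy
backend for training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "TrainConfig",
    "build_model1",
    "build_model2",
    "build_model3",
    "count_parameters",
    "compile_network",
    "train",
    "predict_proba",
    "predict_label",
]

LAYER_KINDS = (
    "conv2d",
    "maxpool2d",
    "batchnorm",
    "flatten",
    "flatten_seq",
    "lstm",
    "dropout",
    "dense",
    "softmax",
)

CLASS_ORDER = ("normal", "abnormal")  # class index 0, 1


class ShapeInferenceError(ValueError):
    """Raised when a layer's input shape cannot be resolved."""


@dataclass(frozen=True)
class LayerSpec:
    """One abstract layer: a kind plus its hyperparameters."""

    kind: str
    filters: int | None = None
    kernel: int | None = None
    stride: int | None = None
    units: int | None = None
    rate: float | None = None
    activation: str | None = None
    return_sequences: bool = False

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        for attr in ("filters", "kernel", "stride", "units"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise ValueError(f"{attr} must be positive, got {v}")
        if self.rate is not None and not (0 <= self.rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Adam / categorical cross-entropy training settings."""

    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class ModelSpec:
    """Named architecture: ordered layers plus a training configuration."""

    name: str
    input_shape: tuple[int, ...]
    layers: tuple[LayerSpec, ...]
    train_config: TrainConfig = field(default_factory=TrainConfig)
    n_classes: int = 2

    def __post_init__(self) -> None:
        if not self.layers or self.layers[-1].kind != "softmax":
            raise ValueError("the final layer must be a softmax head")
        if self.layers[-1].units != self.n_classes:
            raise ValueError("softmax units must equal n_classes")


def build_model1(
    input_shape: tuple[int, int],
    dense_units: int = 64,
    lstm_units: int = 128,
    epochs: int = 50,
) -> ModelSpec:
    """Stacked-LSTM classifier for (timesteps, features) sequences."""
    t, f = input_shape
    if t < 1 or f < 1:
        raise ValueError(f"invalid input shape {input_shape}")
    layers = (
        LayerSpec("lstm", units=lstm_units, return_sequences=True),
        LayerSpec("dropout", rate=0.2),
        LayerSpec("lstm", units=lstm_units, return_sequences=True),
        LayerSpec("dropout", rate=0.2),
        LayerSpec("lstm", units=lstm_units),
        LayerSpec("dropout", rate=0.2),
        LayerSpec("dense", units=dense_units, activation="relu"),
        LayerSpec("softmax", units=2),
    )
    return ModelSpec("model1", (t, f), layers, TrainConfig(epochs=epochs, batch_size=32))


def build_model2(input_shape: tuple[int, int, int] = (128, 128, 3), epochs: int = 100) -> ModelSpec:
    """2D CNN for 128 x 128 x 3 feature images."""
    layers = (
        LayerSpec("conv2d", filters=32, kernel=3, stride=1, activation="relu"),
        LayerSpec("maxpool2d", kernel=2, stride=2),
        LayerSpec("batchnorm"),
        LayerSpec("conv2d", filters=64, kernel=3, stride=1, activation="relu"),
        LayerSpec("maxpool2d", kernel=2, stride=2),
        LayerSpec("batchnorm"),
        LayerSpec("conv2d", filters=128, kernel=3, stride=1, activation="relu"),
        LayerSpec("maxpool2d", kernel=2, stride=2),
        LayerSpec("batchnorm"),
        LayerSpec("flatten"),
        LayerSpec("dense", units=128, activation="relu"),
        LayerSpec("dropout", rate=0.5),
        LayerSpec("softmax", units=2),
    )
    return ModelSpec("model2", tuple(input_shape), layers, TrainConfig(epochs=epochs, batch_size=32))


def build_model3(
    input_shape: tuple[int, int, int] = (64, 64, 3),
    dense_units: int = 64,
    epochs: int = 50,
) -> ModelSpec:
    """Hybrid CNN -> LSTM classifier for 64 x 64 x 3 feature images."""
    layers = (
        LayerSpec("conv2d", filters=32, kernel=3, stride=1, activation="relu"),
        LayerSpec("maxpool2d", kernel=2, stride=2),
        LayerSpec("batchnorm"),
        LayerSpec("conv2d", filters=64, kernel=3, stride=1, activation="relu"),
        LayerSpec("maxpool2d", kernel=2, stride=2),
        LayerSpec("batchnorm"),
        LayerSpec("flatten_seq"),
        LayerSpec("lstm", units=64, return_sequences=True),
        LayerSpec("lstm", units=128),
        LayerSpec("dropout", rate=0.2),
        LayerSpec("dense", units=dense_units, activation="relu"),
        LayerSpec("softmax", units=2),
    )
    return ModelSpec("model3", tuple(input_shape), layers, TrainConfig(epochs=epochs, batch_size=32))


def _infer_shapes(spec: ModelSpec) -> list[tuple[int, ...]]:
    """Input shape of every layer, derived by walking the layer chain."""
    shape = tuple(spec.input_shape)
    shapes = []
    for layer in spec.layers:
        shapes.append(shape)
        k = layer.kind
        if k == "conv2d":
            if len(shape) != 3:
                raise ShapeInferenceError(f"conv2d expects (H, W, C), got {shape}")
            h, w, c = shape
            kk = layer.kernel or 3
            if h < kk or w < kk:
                raise ShapeInferenceError(f"conv2d kernel {kk} exceeds input {shape}")
            shape = (h - kk + 1, w - kk + 1, layer.filters)
        elif k == "maxpool2d":
            if len(shape) != 3:
                raise ShapeInferenceError(f"maxpool2d expects (H, W, C), got {shape}")
            h, w, c = shape
            shape = (h // 2, w // 2, c)
        elif k == "batchnorm":
            pass
        elif k == "flatten":
            shape = (int(np.prod(shape)),)
        elif k == "flatten_seq":
            if len(shape) != 3:
                raise ShapeInferenceError(f"flatten_seq expects (H, W, C), got {shape}")
            h, w, c = shape
            shape = (h, w * c)
        elif k == "lstm":
            if len(shape) != 2:
                raise ShapeInferenceError(f"lstm expects (timesteps, features), got {shape}")
            t, f = shape
            shape = (t, layer.units) if layer.return_sequences else (layer.units,)
        elif k == "dropout":
            pass
        elif k in ("dense", "softmax"):
            if len(shape) != 1:
                raise ShapeInferenceError(f"{k} expects a flat input, got {shape}")
            shape = (layer.units,)
    return shapes


def count_parameters(spec: ModelSpec) -> int:
    """Total trainable parameters, by closed form per layer.

    dense/softmax: (n_in + 1) * units; conv2d: (kh*kw*c_in + 1) * filters;
    lstm: 4 * (units * (n_in + units) + units); batchnorm: 2 * channels.
    """
    total = 0
    for layer, shape in zip(spec.layers, _infer_shapes(spec)):
        k = layer.kind
        if k == "conv2d":
            kk = layer.kernel or 3
            total += (kk * kk * shape[-1] + 1) * layer.filters
        elif k == "lstm":
            total += 4 * (layer.units * (shape[-1] + layer.units) + layer.units)
        elif k in ("dense", "softmax"):
            total += (shape[0] + 1) * layer.units
        elif k == "batchnorm":
            total += 2 * shape[-1]
    return total


def compile_network(spec: ModelSpec, seed: int = 0) -> nn.Network:
    """Instantiate the numpy backend for a spec (seeded initialization)."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    for layer, shape in zip(spec.layers, _infer_shapes(spec)):
        k = layer.kind
        if k == "conv2d":
            layers.append(
                nn.Conv2D(shape[-1], layer.filters, layer.kernel or 3,
                          activation=layer.activation or "relu", rng=rng)
            )
        elif k == "maxpool2d":
            layers.append(nn.MaxPool2D())
        elif k == "batchnorm":
            layers.append(nn.BatchNorm(shape[-1]))
        elif k == "flatten":
            layers.append(nn.Flatten())
        elif k == "flatten_seq":
            layers.append(nn.FlattenToSequence())
        elif k == "lstm":
            layers.append(
                nn.LSTM(shape[-1], layer.units, return_sequences=layer.return_sequences, rng=rng)
            )
        elif k == "dropout":
            layers.append(nn.Dropout(layer.rate, rng=rng))
        elif k == "dense":
            layers.append(nn.Dense(shape[0], layer.units, activation=layer.activation or "linear", rng=rng))
        elif k == "softmax":
            layers.append(nn.Dense(shape[0], layer.units, activation="linear", rng=rng))
            layers.append(nn.Softmax())
    return nn.Network(layers)


def _to_onehot(y) -> np.ndarray:
    """Labels (strings or {0,1} ints) -> one-hot over (normal, abnormal)."""
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        idx = np.array([CLASS_ORDER.index(str(v)) for v in y])
    else:
        idx = y.astype(int)
    if set(np.unique(idx)) - {0, 1}:
        raise ValueError("labels must be binary (normal/abnormal)")
    if len(np.unique(idx)) < 2:
        raise ValueError("training requires at least one example of each class")
    onehot = np.zeros((len(idx), 2))
    onehot[np.arange(len(idx)), idx] = 1.0
    return onehot


def train(
    spec: ModelSpec,
    x: np.ndarray,
    y,
    config: TrainConfig | None = None,
    x_val: np.ndarray | None = None,
    y_val=None,
) -> tuple[nn.Network, nn.TrainingHistory]:
    """Train a compiled spec; returns the network and its history."""
    config = config or spec.train_config
    x = np.asarray(x, dtype=np.float64)
    if x.shape[1:] != tuple(spec.input_shape):
        raise ValueError(
            f"feature shape {x.shape[1:]} does not match spec input {spec.input_shape}"
        )
    y_onehot = _to_onehot(y)
    yv = _to_onehot(y_val) if y_val is not None else None
    network = compile_network(spec, seed=config.seed)
    history = nn.train_network(
        network,
        x,
        y_onehot,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        seed=config.seed,
        x_val=x_val,
        y_val=yv,
    )
    return network, history


def predict_proba(network: nn.Network, x: np.ndarray) -> np.ndarray:
    """Per-class probabilities, rows summing to 1."""
    return network.predict_proba(np.asarray(x, dtype=np.float64))


def predict_label(network: nn.Network, x: np.ndarray) -> np.ndarray:
    """Class labels; probability ties resolve to class index 0 (normal)."""
    probs = predict_proba(network, x)
    # argmax returns the first maximal index, so an exact tie -> class 0.
    idx = probs.argmax(axis=1)
    return np.array([CLASS_ORDER[i] for i in idx])
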