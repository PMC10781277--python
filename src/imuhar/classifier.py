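"""The 1D convolutional movement classifier and its training loop.

Architecture: four valid (unpadded) 1-D convolution layers, kernel 5 and
stride 2, with 32/64/128/256 output features, followed by three dense
layers of 800, 200 and ``n_classes`` units.  With the ROM window length of
200 the temporal feature lengths shrink 200 -> 98 -> 47 -> 22 -> 9; with
the ADL window length of 740 they shrink 740 -> 368 -> 182 -> 89 -> 43.
Every layer — including the final dense layer — is ReLU-activated, the
output layer additionally passes through a softmax, and the first two dense
layers use dropout with probability 0.7 during training.  ``final_relu``
can be disabled for the conventional plain-logit softmax head, since a
ReLU ahead of the softmax zeroes negative logits.

Training uses AdamW (lr 0.001, betas (0.9, 0.999), eps 1e-8, weight decay
0.01) on softmax cross-entropy, batch size 256 windows, 40 epochs, with a
fixed seed for weight initialization, shuffling and dropout.  Given the
same seed and thread configuration, runs are reproducible (floating-point
reductions can differ across BLAS builds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import (
    AdamW,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    ReLU,
    Sequential,
    softmax,
    softmax_cross_entropy,
)


def conv_output_length(l_in: int, kernel: int = 5, stride: int = 2) -> int:
    """Output length of a valid strided convolution:
    floor((L - kernel)/stride) + 1."""
    if l_in < kernel:
        raise ValueError(f"input length {l_in} shorter than kernel {kernel}")
    return (l_in - kernel) // stride + 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture parameters; defaults follow the published network."""

    input_length: int
    n_classes: int
    input_channels: int = 30
    conv_kernel: int = 5
    conv_stride: int = 2
    conv_features: tuple[int, ...] = (32, 64, 128, 256)
    dense_sizes: tuple[int, ...] = (800, 200)
    dropout_p: float = 0.7
    final_relu: bool = False

    def conv_chain(self) -> list[int]:
        """Temporal lengths through the conv stack, input included."""
        lengths = [self.input_length]
        for _ in self.conv_features:
            lengths.append(
                conv_output_length(lengths[-1], self.conv_kernel, self.conv_stride)
            )
        return lengths

    def flatten_size(self) -> int:
        return self.conv_chain()[-1] * self.conv_features[-1]

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        chain = self.conv_chain()  # raises if any layer underflows
        if chain[-1] < 1:
            raise ValueError("final conv feature length < 1")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    weight_decay: float = 0.01
    batch_size: int = 256
    epochs: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")


def build_model(config: ModelConfig, rng: np.random.Generator) -> Sequential:
    """Construct the untrained network with He-initialized weights."""
    layers: list = []
    in_ch = config.input_channels
    for feats in config.conv_features:
        layers.append(
            Conv1D(in_ch, feats, config.conv_kernel, config.conv_stride, rng)
        )
        layers.append(ReLU())
        in_ch = feats
    layers.append(Flatten())
    in_features = config.flatten_size()
    for size in config.dense_sizes:
        layers.append(Dense(in_features, size, rng))
        layers.append(ReLU())
        layers.append(Dropout(config.dropout_p))
        in_features = size
    out = Dense(in_features, config.n_classes, rng)
    if config.final_relu:
        # start the output units in the ReLU's active regime: with zero
        # biases the ReLU-then-softmax head can die (all logits negative
        # -> uniform softmax -> zero gradient everywhere)
        out.b.value[:] = 1.0
    layers.append(out)
    # final ReLU + softmax are applied in the loss / predict path
    return Sequential(layers)


@dataclass
class TrainedModel:
    """A trained network plus everything needed to reproduce it."""

    network: Sequential
    model_config: ModelConfig
    train_config: TrainConfig
    classes: np.ndarray  # class labels in output-unit order
    loss_history: list[float] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class probabilities, rows summing to 1 (inference is
        deterministic: dropout off)."""
        x = np.asarray(x, dtype=np.float32)
        outs = []
        for start in range(0, len(x), batch_size):
            logits = self.network.forward(x[start : start + batch_size], train=False)
            if self.model_config.final_relu:
                logits = np.maximum(logits, 0.0)
            outs.append(softmax(logits))
        return np.vstack(outs)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax labels; ties break toward the lowest class index."""
        proba = self.predict_proba(x)
        return self.classes[np.argmax(proba, axis=1)]


def train(
    x: np.ndarray,
    y: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig = TrainConfig(),
    classes: Sequence[int] | None = None,
    provenance: dict | None = None,
) -> TrainedModel:
    """Train the classifier on labeled windows.

    ``x`` is (n_windows, window_length, n_channels); ``y`` holds movement
    ids.  ``classes`` fixes the output-unit ordering (defaults to the sorted
    labels present); training on a label outside ``classes`` is an error.
    """
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y)
    if x.ndim != 3 or len(x) != len(y):
        raise ValueError("x must be (n, time, channels) aligned with y")
    if len(x) == 0:
        raise ValueError("empty training set")
    if x.shape[1] != model_config.input_length or x.shape[2] != model_config.input_channels:
        raise ValueError(
            f"window shape {x.shape[1:]} does not match model config "
            f"({model_config.input_length}, {model_config.input_channels})"
        )
    class_arr = np.array(sorted(set(y)) if classes is None else list(classes))
    index_of = {c: i for i, c in enumerate(class_arr)}
    try:
        targets = np.array([index_of[c] for c in y], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in classes") from exc

    ss = np.random.SeedSequence(train_config.seed)
    init_rng, shuffle_rng, dropout_rng = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    network = build_model(model_config, init_rng)
    network.set_dropout_rng(dropout_rng)
    optimizer = AdamW(
        network.params(),
        lr=train_config.learning_rate,
        betas=train_config.betas,
        eps=train_config.eps,
        weight_decay=train_config.weight_decay,
    )

    n = len(x)
    history: list[float] = []
    for _ in range(train_config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            network.zero_grad()
            logits = network.forward(x[idx], train=True)
            loss, dlogits = softmax_cross_entropy(
                logits, targets[idx], final_relu=model_config.final_relu
            )
            network.backward(dlogits)
            optimizer.step()
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / n)

    return TrainedModel(
        network=network,
        model_config=model_config,
        train_config=train_config,
        classes=class_arr,
        loss_history=history,
        provenance={
            "n_windows": int(n),
            "seed": train_config.seed,
            **(provenance or {}),
        },
    )
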