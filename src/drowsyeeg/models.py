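"""CNN models for scalogram feature extraction and the raw-signal baseline.

The 2-D model family is parameterized by convolutional depth: each block
is conv(3x3, ReLU) -> maxpool(2x2) -> dropout(0.25), followed by flatten
-> dense(128, ReLU) -> dropout(0.5) -> a single sigmoid unit trained
with binary cross-entropy (Adam, batch 32, up to 50 epochs, early
stopping with patience 10).  The two-block model uses the printed filter
widths (16, 64); other depths follow a doubling ladder from 16 capped at
128, so the selected three-block model is (16, 32, 64).  The 128-d
activations of the penultimate dense layer (post-ReLU, no dropout at
inference) are the features handed to the SVM head.

The 1-D baseline consumes raw filtered 30-s segments with convolutional
kernel sizes 64 and 32.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import nn

INPUT_SHAPE = (64, 64, 3)
DENSE_WIDTH = 128
SEGMENT_SAMPLES = 15360  # 30 s x 512 Hz


def filters_for_depth(depth: int) -> tuple[int, ...]:
    """Filter widths per conv block for a given depth.

    Depth 2 keeps the printed (16, 64); other depths double from 16,
    capped at 128.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if depth == 2:
        return (16, 64)
    return tuple(min(16 * 2**i, 128) for i in range(depth))


@dataclass(frozen=True)
class CNNConfig:
    """Architecture of the 2-D scalogram CNN."""

    n_conv_blocks: int = 3
    filters_per_block: tuple[int, ...] | None = None
    kernel: tuple[int, int] = (3, 3)
    pool: int = 2
    block_dropout: float = 0.25
    dense_width: int = DENSE_WIDTH
    head_dropout: float = 0.5
    input_shape: tuple[int, int, int] = INPUT_SHAPE

    @property
    def filters(self) -> tuple[int, ...]:
        f = self.filters_per_block or filters_for_depth(self.n_conv_blocks)
        if len(f) != self.n_conv_blocks:
            raise ValueError("filters_per_block length must equal n_conv_blocks")
        if any(v < 1 for v in f):
            raise ValueError("filter counts must be >= 1")
        return tuple(f)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings shared by the CNN models."""

    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stopping_patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.early_stopping_patience > self.epochs:
            raise ValueError("patience must not exceed epochs")


def build_cnn(config: CNNConfig, seed: int = 0) -> nn.Sequential:
    """Assemble the depth-parameterized 2-D CNN.

    Raises if the requested pooling depth collapses the spatial size to
    zero before the flatten.
    """
    rng = np.random.default_rng(seed)
    h, w, c = config.input_shape
    layers: list[nn.Layer] = []
    in_ch = c
    for f in config.filters:
        layers += [
            nn.Conv2D(in_ch, f, config.kernel, rng),
            nn.ReLU(),
            nn.MaxPool2D(config.pool),
            nn.Dropout(config.block_dropout),
        ]
        h, w = h // config.pool, w // config.pool
        if h < 1 or w < 1:
            raise ValueError(
                f"{config.n_conv_blocks} pooling blocks collapse a "
                f"{config.input_shape[0]}x{config.input_shape[1]} input to zero"
            )
        in_ch = f
    layers.append(nn.Flatten())
    layers.append(nn.Dense(h * w * in_ch, config.dense_width, rng))
    layers.append(nn.ReLU())
    feature_index = len(layers)  # features = post-ReLU dense activations
    layers.append(nn.Dropout(config.head_dropout))
    layers.append(nn.Dense(config.dense_width, 1, rng))
    return nn.Sequential(layers, feature_index=feature_index)


def build_cnn1d(
    kernel_sizes: tuple[int, int] = (64, 32),
    filters: tuple[int, int] = (16, 32),
    strides: tuple[int, int] = (4, 2),
    pool: int = 4,
    dense_width: int = 64,
    dropout: float = 0.5,
    input_length: int = SEGMENT_SAMPLES,
    seed: int = 0,
) -> nn.Sequential:
    """Assemble the 1-D raw-signal baseline CNN."""
    if input_length < max(kernel_sizes):
        raise ValueError("input shorter than the largest kernel")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    length, in_ch = input_length, 1
    for k, f, s in zip(kernel_sizes, filters, strides):
        layers += [nn.Conv1D(in_ch, f, k, s, rng), nn.ReLU(), nn.MaxPool1D(pool)]
        length = int(np.ceil(length / s)) // pool
        in_ch = f
    layers.append(nn.Flatten())
    layers.append(nn.Dense(length * in_ch, dense_width, rng))
    layers.append(nn.ReLU())
    feature_index = len(layers)
    layers.append(nn.Dropout(dropout))
    layers.append(nn.Dense(dense_width, 1, rng))
    return nn.Sequential(layers, feature_index=feature_index)


class ConvNetClassifier(BaseEstimator, ClassifierMixin, TransformerMixin):
    """Depth-parameterized 2-D CNN on scalogram images, sklearn-style.

    ``fit`` trains the sigmoid head end-to-end; ``transform`` returns
    the 128-d penultimate features, so the estimator drops into a
    pipeline in front of an SVM head.

    Parameters mirror :class:`CNNConfig` and :class:`TrainConfig`.
    """

    def __init__(self, depth: int = 3, filters: tuple[int, ...] | None = None,
                 dense_width: int = DENSE_WIDTH, epochs: int = 50,
                 batch_size: int = 32, learning_rate: float = 1e-3,
                 patience: int = 10, validation_fraction: float = 0.1,
                 input_shape: tuple[int, int, int] = INPUT_SHAPE,
                 random_state: int = 0):
        self.depth = depth
        self.filters = filters
        self.dense_width = dense_width
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.input_shape = input_shape
        self.random_state = random_state

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, np.float32)
        if X.ndim != 4 or X.shape[1:] != tuple(self.input_shape):
            raise ValueError(
                f"expected images of shape (n,) + {tuple(self.input_shape)}, got {X.shape}"
            )
        return X

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y).ravel()
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need samples of both classes")
        config = CNNConfig(
            n_conv_blocks=self.depth,
            filters_per_block=tuple(self.filters) if self.filters else None,
            dense_width=self.dense_width,
            input_shape=tuple(self.input_shape),
        )
        self.config_ = config
        self.net_ = build_cnn(config, seed=self.random_state)
        self.history_ = nn.train(
            self.net_, X, (y == self.classes_[1]).astype(np.float32),
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, patience=self.patience,
            validation_fraction=self.validation_fraction,
            seed=self.random_state,
        )
        self.n_features_out_ = self.dense_width
        return self

    def decision_function(self, X):
        check_is_fitted(self, "net_")
        return self.net_.forward(self._check_X(X)).ravel()

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def transform(self, X):
        """128-d penultimate features (deterministic at inference)."""
        check_is_fitted(self, "net_")
        return self.net_.features(self._check_X(X))

    def save(self, path):
        check_is_fitted(self, "net_")
        np.savez(path, **self.net_.state_dict(),
                 _meta_depth=self.depth, _meta_dense=self.dense_width)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = False
        return tags


class Conv1DClassifier(BaseEstimator, ClassifierMixin):
    """1-D CNN baseline on raw filtered 30-s segments."""

    def __init__(self, kernel_sizes: tuple[int, int] = (64, 32),
                 filters: tuple[int, int] = (16, 32),
                 epochs: int = 50, batch_size: int = 32,
                 learning_rate: float = 1e-3, patience: int = 10,
                 input_length: int = SEGMENT_SAMPLES,
                 scale: float = 50.0, random_state: int = 0):
        self.kernel_sizes = kernel_sizes
        self.filters = filters
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.input_length = input_length
        self.scale = scale  # fixed amplitude normalization, microvolt
        self.random_state = random_state

    def _check_X(self, X):
        X = np.asarray(X, np.float32)
        if X.ndim == 2:
            X = X[..., None]
        if X.shape[1] != self.input_length:
            raise ValueError(f"expected segments of {self.input_length} samples, got {X.shape}")
        return X / self.scale

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y).ravel()
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need samples of both classes")
        self.net_ = build_cnn1d(
            kernel_sizes=tuple(self.kernel_sizes), filters=tuple(self.filters),
            input_length=self.input_length, seed=self.random_state,
        )
        self.history_ = nn.train(
            self.net_, X, (y == self.classes_[1]).astype(np.float32),
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, patience=self.patience,
            seed=self.random_state,
        )
        return self

    def decision_function(self, X):
        check_is_fitted(self, "net_")
        return self.net_.forward(self._check_X(X)).ravel()

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = False
        return tags


def extract_features(model: ConvNetClassifier, images: np.ndarray) -> np.ndarray:
    """128-d feature vectors for a stack of images (thin wrapper)."""
    return model.transform(images)
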