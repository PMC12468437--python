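"""Scikit-learn style classifiers wrapping the three architectures.

Each estimator holds the hyperparameters of one architecture, builds
its :class:`~pcglearn.models.ModelSpec` at ``fit`` time, trains the
numpy backend, and exposes ``predict`` / ``predict_proba``.  They
compose with sklearn pipelines and model selection; the defaults are
the published architectures, while the unit/epoch knobs allow scaled-
down variants for quick experiments.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import models as M

__all__ = [
    "LSTMSequenceClassifier",
    "ConvNetImageClassifier",
    "ConvRecurrentImageClassifier",
    "LateFusionClassifier",
]


class _NeuralClassifier(ClassifierMixin, BaseEstimator):
    """Shared fit/predict machinery; subclasses supply ``_build_spec``."""

    def _build_spec(self, input_shape) -> M.ModelSpec:
        raise NotImplementedError

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.spec_ = self._build_spec(X.shape[1:])
        config = M.TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=self.random_state,
        )
        self.network_, self.history_ = M.train(self.spec_, X, y, config)
        self.n_parameters_ = M.count_parameters(self.spec_)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1:] != tuple(self.spec_.input_shape):
            raise ValueError(
                f"X has shape {X.shape[1:]}, expected {self.spec_.input_shape}"
            )
        return M.predict_proba(self.network_, X)

    def predict(self, X):
        return M.predict_label(self.network_, np.asarray(X, dtype=np.float64))


class LSTMSequenceClassifier(_NeuralClassifier):
    """Stacked-LSTM classifier for (n, timesteps, features) sequences.

    The default configuration is three 128-unit LSTM layers with
    dropout 0.2 after each, a 64-unit ReLU head, a two-way softmax, and
    Adam / categorical cross-entropy for 50 epochs at batch size 32.
    """

    def __init__(
        self,
        lstm_units: int = 128,
        dense_units: int = 64,
        epochs: int = 50,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        random_state: int = 0,
    ):
        self.lstm_units = lstm_units
        self.dense_units = dense_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _build_spec(self, input_shape):
        if len(input_shape) != 2:
            raise ValueError(f"expected (n, timesteps, features) input, got trailing {input_shape}")
        return M.build_model1(
            input_shape,
            dense_units=self.dense_units,
            lstm_units=self.lstm_units,
            epochs=self.epochs,
        )


class ConvNetImageClassifier(_NeuralClassifier):
    """2D CNN for (n, 128, 128, 3) feature images (100 epochs default)."""

    def __init__(
        self,
        epochs: int = 100,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        random_state: int = 0,
    ):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _build_spec(self, input_shape):
        if len(input_shape) != 3:
            raise ValueError(f"expected (n, H, W, 3) input, got trailing {input_shape}")
        return M.build_model2(input_shape, epochs=self.epochs)


class ConvRecurrentImageClassifier(_NeuralClassifier):
    """Hybrid CNN -> LSTM for (n, 64, 64, 3) feature images."""

    def __init__(
        self,
        dense_units: int = 64,
        epochs: int = 50,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        random_state: int = 0,
    ):
        self.dense_units = dense_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _build_spec(self, input_shape):
        if len(input_shape) != 3:
            raise ValueError(f"expected (n, H, W, 3) input, got trailing {input_shape}")
        return M.build_model3(input_shape, dense_units=self.dense_units, epochs=self.epochs)


class LateFusionClassifier(ClassifierMixin, BaseEstimator):
    """Average the class probabilities of two fitted base classifiers.

    An optional interpretation of multimodal fusion: the sequence model
    and the image model are trained independently on their own
    representations and their softmax outputs are averaged.  ``fit``
    takes ``X`` as a pair (X_sequence, X_image).
    """

    def __init__(self, sequence_estimator=None, image_estimator=None):
        self.sequence_estimator = sequence_estimator
        self.image_estimator = image_estimator

    def fit(self, X, y):
        x_seq, x_img = X
        self.seq_ = (self.sequence_estimator or LSTMSequenceClassifier()).fit(x_seq, y)
        self.img_ = (self.image_estimator or ConvNetImageClassifier()).fit(x_img, y)
        self.classes_ = np.unique(np.asarray(y))
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "seq_")
        x_seq, x_img = X
        return 0.5 * (self.seq_.predict_proba(x_seq) + self.img_.predict_proba(x_img))

    def predict(self, X):
        probs = self.predict_proba(X)
        return np.array([M.CLASS_ORDER[i] for i in probs.argmax(axis=1)])
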