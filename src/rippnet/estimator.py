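"""scikit-learn-style estimator wrapping the full training procedure.

``PrecursorClassifier`` accepts raw amino-acid sequences (or pre-encoded
20 x 120 one-hot matrices), runs the imbalance-aware round-based training
loop, and predicts with the checkpointed best weights. It follows the
scikit-learn estimator contract (get_params/set_params, fitted attributes
with trailing underscores, ``classes_``), so it composes with model
selection utilities, at the cost of re-deriving the positive/negative pools
from ``y`` inside :meth:`fit`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .encoding import DEFAULT_ALPHABET, encode
from .models import ModelSpec, build_model
from .training import TrainingConfig, train_arrays


def _encode_inputs(X) -> np.ndarray:
    if isinstance(X, np.ndarray) and X.ndim == 3:
        if X.shape[1:] != (20, 120):
            raise ValueError(f"encoded input must have shape (n, 20, 120), got {X.shape}")
        return X.astype(np.float64)
    return np.stack([encode(str(s)).matrix for s in X])


class PrecursorClassifier(ClassifierMixin, BaseEstimator):
    """Neural precursor-peptide classifier with negative-resampling training.

    Parameters
    ----------
    architecture : str
        One of ``lstm``, ``cnn_linear``, ``cnn_parallel``,
        ``cnn_linear_lstm``, ``cnn_parallel_lstm``.
    negative_subsample_fraction, train_fraction, resample_interval,
    patience, max_rounds, batch_size, learning_rate
        Training-loop constants; see :class:`rippnet.training.TrainingConfig`.
    threshold : float
        Positive-call threshold on the precursor probability (strict;
        ties are called negative).
    random_state : int
        Seeds weight initialization, subsampling, splitting and dropout.

    Attributes
    ----------
    model_ : rippnet.models.Classifier
        The trained network carrying the best checkpointed weights.
    history_ : rippnet.training.TrainingHistory
        Per-round loss/accuracy/checkpoint/resample records.
    classes_ : ndarray of shape (2,)
        Always ``[0, 1]``.
    """

    def __init__(
        self,
        architecture: str = "cnn_parallel",
        negative_subsample_fraction: float = 0.35,
        train_fraction: float = 0.85,
        resample_interval: int = 5,
        patience: int = 50,
        max_rounds: int = 200,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.architecture = architecture
        self.negative_subsample_fraction = negative_subsample_fraction
        self.train_fraction = train_fraction
        self.resample_interval = resample_interval
        self.patience = patience
        self.max_rounds = max_rounds
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.threshold = threshold
        self.random_state = random_state

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            negative_subsample_fraction=self.negative_subsample_fraction,
            train_fraction=self.train_fraction,
            resample_interval=self.resample_interval,
            patience=self.patience,
            max_rounds=self.max_rounds,
            seed=self.random_state,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
        )

    def fit(self, X, y):
        """Fit on sequences (or encoded matrices) with binary labels."""
        X_enc = _encode_inputs(X)
        y = np.asarray(y, dtype=np.int64)
        if len(y) != len(X_enc):
            raise ValueError("X and y length mismatch")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be 0 (non-precursor) or 1 (precursor)")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present in y")
        model = build_model(
            ModelSpec(architecture=self.architecture),
            alphabet=DEFAULT_ALPHABET,
            seed=self.random_state,
        )
        self.model_, self.history_ = train_arrays(
            model, X_enc[y == 1], X_enc[y == 0], self._config()
        )
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 20 * 120
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(_encode_inputs(X))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return (proba[:, 1] > self.threshold).astype(np.int64)

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]
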