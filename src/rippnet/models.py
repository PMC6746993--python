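"""The five precursor-peptide classifier architectures.

All networks consume the 20 x 120 one-hot peptide matrix and emit two
softmax-normalised scores interpretable as P(non-precursor) and
P(precursor). The designs mirror successful short-text classifiers:

* ``lstm`` — a bidirectional LSTM (60 cells, 0.15 recurrent dropout), dense
  layer of 60 units, then the classification head.
* ``cnn_linear`` — three stacked convolutions, width-2 max pooling, a
  40-unit dense layer, then the head.
* ``cnn_parallel`` — three parallel branches of two stacked convolutions
  (kernel sizes 3/6/9, pooling between the two), concatenated, merged by a
  150-filter kernel-3 convolution, width-3 pooling, a 60-unit dense layer,
  then the head.
* ``cnn_linear_lstm`` / ``cnn_parallel_lstm`` — the same CNN trunks with a
  60-cell LSTM inserted before the dense layer.

A 0.5-rate dropout layer sits between the dense layer and the head in every
architecture. Convolutions use "same" padding so the 120-column input never
underflows under stacking and pooling.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .encoding import Alphabet, DEFAULT_ALPHABET
from .nn import autograd as ag
from .nn.layers import BiLSTM, Conv1D, Dense, Dropout, Flatten, LSTM, MaxPool1D

FORMAT_VERSION = "1"
ARCHITECTURES = ("lstm", "cnn_linear", "cnn_parallel", "cnn_linear_lstm", "cnn_parallel_lstm")

WEIGHTS_FILE = "weights.npz"
METADATA_FILE = "model.json"


class ConfigurationError(ValueError):
    pass


class ModelLoadError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Declarative architecture description with resolved hyperparameters.

    The linear-CNN filter/kernel sizes and the parallel branch kernels are
    artifact defaults (the architecture family fixes only their count and
    arrangement); they are serialized with trained weights.
    """

    architecture: str = "cnn_parallel"
    lstm_units: int = 60
    lstm_recurrent_dropout: float = 0.15
    head_dropout: float = 0.5
    dense_units: int | None = None
    cnn_linear_filters: tuple[int, int, int] = (64, 128, 64)
    cnn_linear_kernels: tuple[int, int, int] = (7, 5, 3)
    parallel_branch_kernels: tuple[int, int, int] = (3, 6, 9)
    parallel_branch_filters: int = 64
    merge_conv_filters: int = 150
    merge_conv_kernel: int = 3
    final_pool: int | None = None

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ConfigurationError(
                f"unknown architecture {self.architecture!r}; expected one of {ARCHITECTURES}"
            )
        if self.dense_units is None:
            # linear-CNN trunks use a 40-unit dense layer, all others 60
            self.dense_units = 40 if self.architecture.startswith("cnn_linear") else 60
        if self.final_pool is None:
            self.final_pool = 3 if "parallel" in self.architecture else 2
        for frac in (self.lstm_recurrent_dropout, self.head_dropout):
            if not 0.0 <= frac < 1.0:
                raise ConfigurationError(f"dropout fraction {frac} outside [0, 1)")
        counts = (
            self.lstm_units,
            *self.cnn_linear_filters,
            *self.cnn_linear_kernels,
            *self.parallel_branch_kernels,
            self.parallel_branch_filters,
            self.merge_conv_filters,
            self.merge_conv_kernel,
            self.dense_units,
            self.final_pool,
        )
        if any(int(c) != c or c <= 0 for c in counts):
            raise ConfigurationError("unit/filter/kernel counts must be positive integers")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("cnn_linear_filters", "cnn_linear_kernels", "parallel_branch_kernels"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        for k in ("cnn_linear_filters", "cnn_linear_kernels", "parallel_branch_kernels"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


class Classifier:
    """A built (possibly trained) network: spec, alphabet, parameters.

    ``predict_proba`` takes inputs in the serialized 20-rows-by-120-columns
    orientation and returns an (n, 2) array of class probabilities summing
    to 1 per row. Dropout is active only inside :meth:`loss_and_grads`.
    """

    def __init__(self, spec: ModelSpec, alphabet: Alphabet = DEFAULT_ALPHABET, seed: int = 0):
        self.spec = spec
        self.alphabet = alphabet
        self.seed = seed
        self.metadata = {
            "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "version": FORMAT_VERSION,
        }
        self._build(np.random.default_rng(seed))

    # -- construction -----------------------------------------------------

    def _build(self, rng):
        s = self.spec
        n_alpha = self.alphabet.size
        self.layers: dict[str, object] = {}

        def L(layer):
            self.layers[layer.name] = layer
            return layer

        arch = s.architecture
        if arch == "lstm":
            L(BiLSTM("bilstm", rng, n_alpha, s.lstm_units, s.lstm_recurrent_dropout))
            L(Dense("dense", rng, 2 * s.lstm_units, s.dense_units, activation="relu"))
        elif arch in ("cnn_linear", "cnn_linear_lstm"):
            c_prev = n_alpha
            for i, (f, k) in enumerate(zip(s.cnn_linear_filters, s.cnn_linear_kernels), 1):
                L(Conv1D(f"conv{i}", rng, c_prev, f, k))
                c_prev = f
            L(MaxPool1D(s.final_pool))
            if arch == "cnn_linear_lstm":
                L(LSTM("lstm", rng, c_prev, s.lstm_units))
                dense_in = s.lstm_units
            else:
                dense_in = (120 // s.final_pool) * c_prev
            L(Dense("dense", rng, dense_in, s.dense_units, activation="relu"))
        elif arch in ("cnn_parallel", "cnn_parallel_lstm"):
            for bi, k in enumerate(s.parallel_branch_kernels, 1):
                L(Conv1D(f"branch{bi}_conv1", rng, n_alpha, s.parallel_branch_filters, k))
                L(Conv1D(f"branch{bi}_conv2", rng, s.parallel_branch_filters, s.parallel_branch_filters, k))
            L(Conv1D("merge_conv", rng, 3 * s.parallel_branch_filters, s.merge_conv_filters, s.merge_conv_kernel))
            L(MaxPool1D(s.final_pool))
            if arch == "cnn_parallel_lstm":
                L(LSTM("lstm", rng, s.merge_conv_filters, s.lstm_units))
                dense_in = s.lstm_units
            else:
                dense_in = (120 // (2 * s.final_pool)) * s.merge_conv_filters
            L(Dense("dense", rng, dense_in, s.dense_units, activation="relu"))
        L(Dropout(s.head_dropout))
        L(Dense("head", rng, s.dense_units, 2))

    def parameters(self) -> list[tuple[str, nn.Tensor]]:
        out = []
        for layer in self.layers.values():
            out.extend(layer.parameters())
        return out

    def n_parameters(self) -> int:
        return sum(int(t.data.size) for _, t in self.parameters())

    # -- forward ----------------------------------------------------------

    def _forward(self, x: nn.Tensor, training: bool, rng=None) -> nn.Tensor:
        s = self.spec
        arch = s.architecture
        if arch == "lstm":
            h = self.layers["bilstm"](x, training=training, rng=rng)
            h = self.layers["dense"](h)
        elif arch in ("cnn_linear", "cnn_linear_lstm"):
            h = x
            for i in range(1, 4):
                h = self.layers[f"conv{i}"](h)
            h = self.layers[f"maxpool{s.final_pool}"](h)
            if arch == "cnn_linear_lstm":
                h = self.layers["lstm"](h, training=training, rng=rng)
            else:
                h = Flatten()(h)
            h = self.layers["dense"](h)
        else:
            branches = []
            for bi in range(1, 4):
                b = self.layers[f"branch{bi}_conv1"](x)
                b = ag.maxpool1d(b, 2)
                b = self.layers[f"branch{bi}_conv2"](b)
                branches.append(b)
            h = ag.concat(branches, axis=2)
            h = self.layers["merge_conv"](h)
            h = self.layers[f"maxpool{s.final_pool}"](h)
            if arch == "cnn_parallel_lstm":
                h = self.layers["lstm"](h, training=training, rng=rng)
            else:
                h = Flatten()(h)
            h = self.layers["dense"](h)
        h = self.layers[f"dropout{s.head_dropout}"](h, training=training, rng=rng)
        return self.layers["head"](h)

    @staticmethod
    def _to_positions_last(batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim == 2:
            batch = batch[None]
        if batch.ndim != 3 or batch.shape[1:] != (20, 120):
            raise ValueError(f"expected inputs of shape (n, 20, 120), got {batch.shape}")
        return batch.transpose(0, 2, 1)  # internally positions are the "time" axis

    def predict_proba(self, batch: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities for a batch of 20 x 120 one-hot matrices."""
        x = self._to_positions_last(batch)
        chunks = []
        for start in range(0, x.shape[0], batch_size):
            logits = self._forward(nn.Tensor(x[start : start + batch_size]), training=False)
            chunks.append(nn.softmax(logits.data))
        return np.concatenate(chunks, axis=0)

    def loss_and_grads(self, batch: np.ndarray, labels: np.ndarray, rng) -> float:
        """One training forward/backward pass; gradients land on parameters."""
        x = nn.Tensor(self._to_positions_last(batch))
        logits = self._forward(x, training=True, rng=rng)
        loss = ag.softmax_cross_entropy(logits, labels)
        loss.backward()
        return float(loss.data)

    # -- weights ----------------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.parameters()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        params = dict(self.parameters())
        missing = set(params) - set(weights)
        if missing:
            raise ModelLoadError(f"weights missing parameters: {sorted(missing)}")
        for name, t in params.items():
            arr = np.asarray(weights[name], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ModelLoadError(
                    f"parameter {name!r} has shape {arr.shape}, expected {t.data.shape}"
                )
            t.data = arr.copy()


def build_model(
    spec: ModelSpec | str, alphabet: Alphabet = DEFAULT_ALPHABET, seed: int = 0
) -> Classifier:
    """Construct an untrained classifier from a spec or architecture name."""
    if isinstance(spec, str):
        spec = ModelSpec(architecture=spec)
    return Classifier(spec, alphabet=alphabet, seed=seed)


def predict(model: Classifier, batch: np.ndarray) -> np.ndarray:
    """(p_negative, p_positive) pairs, one row per input, rows summing to 1."""
    return model.predict_proba(batch)


def save_model(model: Classifier, path) -> None:
    """Write weights (npz) plus a JSON text sidecar into directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / WEIGHTS_FILE, **model.get_weights())
    meta = {
        "format_version": FORMAT_VERSION,
        "architecture": model.spec.architecture,
        "spec": model.spec.to_dict(),
        "alphabet": model.alphabet.symbols,
        "created": model.metadata.get("created"),
        "training_run": model.metadata.get("training_run"),
    }
    with open(path / METADATA_FILE, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path, expected_architecture: str | None = None) -> Classifier:
    """Load a saved model; metadata must carry version, alphabet and spec."""
    path = Path(path)
    meta_path = path / METADATA_FILE
    if not meta_path.exists():
        raise ModelLoadError(f"missing metadata file {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelLoadError(f"corrupt metadata in {meta_path}: {exc}") from exc
    for required in ("format_version", "alphabet", "spec", "architecture"):
        if required not in meta or meta[required] in (None, ""):
            raise ModelLoadError(f"metadata field {required!r} missing from {meta_path}")
    if meta["format_version"] != FORMAT_VERSION:
        raise ModelLoadError(
            f"unsupported format_version {meta['format_version']!r} in {meta_path}"
        )
    if expected_architecture is not None and meta["architecture"] != expected_architecture:
        raise ModelLoadError(
            f"model at {path} is {meta['architecture']!r}, not {expected_architecture!r}"
        )
    spec = ModelSpec.from_dict(meta["spec"])
    model = Classifier(spec, alphabet=Alphabet(meta["alphabet"]))
    with np.load(path / WEIGHTS_FILE) as npz:
        model.set_weights({k: npz[k] for k in npz.files})
    model.metadata.update({k: meta.get(k) for k in ("created", "training_run")})
    return model
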