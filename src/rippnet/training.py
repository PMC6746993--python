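"""Imbalance-aware round-based training with negative resampling.

The curated negative pool is roughly seven times the positive pool, so each
training cycle pairs the full positive set with a fresh 35% subsample of the
negatives (preventing the model from overtraining on negative data). The
combined set is split 85/15 stratified by class; each round runs one epoch
of Adam on sparse cross-entropy over the training partition and measures
total accuracy on the held-out partition. Weights are checkpointed whenever
held-out accuracy strictly improves, the negative subsample (and split) is
redrawn every 5 rounds, and training halts after 50 improvement-free rounds
or 200 rounds total. The checkpointed best weights, never the final-round
weights, are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .encoding import Alphabet, DEFAULT_ALPHABET, encode_batch
from .io import PeptideSet
from .models import Classifier
from .nn.optim import Adam


@dataclass
class TrainingConfig:
    """Constants of the training loop plus the run seed."""

    negative_subsample_fraction: float = 0.35
    train_fraction: float = 0.85
    resample_interval: int = 5
    patience: int = 50
    max_rounds: int = 200
    seed: int = 0
    batch_size: int = 32
    optimizer_name: str = "adam"
    loss_name: str = "sparse cross-entropy"
    learning_rate: float = 1e-3

    def __post_init__(self):
        for frac in (self.negative_subsample_fraction, self.train_fraction):
            if not 0.0 < frac < 1.0:
                raise ValueError(f"fraction {frac} outside (0, 1)")
        if self.patience > self.max_rounds:
            raise ValueError("patience must not exceed max_rounds")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class RoundRecord:
    round: int
    train_loss: float
    heldout_accuracy: float
    checkpointed: bool
    resampled: bool


@dataclass
class TrainingHistory:
    rounds: list[RoundRecord] = field(default_factory=list)
    best_accuracy: float = 0.0
    best_round: int = 0
    stop_reason: str = ""
    # held-out partition of the best round, for checkpoint re-evaluation
    best_heldout: Optional[tuple[np.ndarray, np.ndarray]] = None

    def log_lines(self) -> list[str]:
        return [
            f"round={r.round} loss={r.train_loss:.6f} heldout_accuracy={r.heldout_accuracy:.6f} "
            f"checkpointed={int(r.checkpointed)} resampled={int(r.resampled)}"
            for r in self.rounds
        ] + [
            f"best_round={self.best_round} best_accuracy={self.best_accuracy:.6f} "
            f"stop_reason={self.stop_reason}"
        ]


@dataclass
class AccuracyReport:
    """Per-class and total accuracy with the underlying counts."""

    n_positive: int
    n_negative: int
    correct_positive: int
    correct_negative: int

    @property
    def positive_accuracy(self) -> float:
        return self.correct_positive / self.n_positive if self.n_positive else float("nan")

    @property
    def negative_accuracy(self) -> float:
        return self.correct_negative / self.n_negative if self.n_negative else float("nan")

    @property
    def total_accuracy(self) -> float:
        return (self.correct_positive + self.correct_negative) / (self.n_positive + self.n_negative)


def majority_baseline(positive_count: int, negative_count: int) -> float:
    """Total accuracy of always predicting the larger class."""
    if positive_count < 0 or negative_count < 0:
        raise ValueError("counts must be non-negative")
    total = positive_count + negative_count
    if total == 0:
        raise ValueError("at least one count must be positive")
    return max(positive_count, negative_count) / total


def subsample_negatives(negatives: PeptideSet, fraction: float, rng: np.random.Generator) -> PeptideSet:
    """Uniform subset without replacement of size floor(fraction * n)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction {fraction} outside (0, 1)")
    n = len(negatives)
    size = int(np.floor(fraction * n))
    if size == 0:
        raise ValueError(f"subsample of {n} records at fraction {fraction} is empty")
    idx = np.sort(rng.choice(n, size=size, replace=False))
    return PeptideSet(
        records=[negatives[i] for i in idx],
        name=negatives.name,
        provenance=negatives.provenance,
    )


def _subsample_indices(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    size = int(np.floor(fraction * n))
    if size == 0:
        raise ValueError("negative subsample is empty")
    return np.sort(rng.choice(n, size=size, replace=False))


def split_train_heldout(X: np.ndarray, y: np.ndarray, train_fraction: float, rng: np.random.Generator):
    """Stratified split preserving the class ratio to within one record."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present to split")
    train_idx, held_idx = [], []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both partitions non-empty per class
        train_idx.append(idx[:n_train])
        held_idx.append(idx[n_train:])
    train_idx = np.sort(np.concatenate(train_idx))
    held_idx = np.sort(np.concatenate(held_idx))
    return (X[train_idx], y[train_idx]), (X[held_idx], y[held_idx])


def _accuracy(model: Classifier, X: np.ndarray, y: np.ndarray) -> float:
    probs = model.predict_proba(X)
    calls = (probs[:, 1] > 0.5).astype(np.int64)
    return float(np.mean(calls == y))


def evaluate_arrays(model: Classifier, X: np.ndarray, y: np.ndarray) -> AccuracyReport:
    y = np.asarray(y)
    probs = model.predict_proba(X)
    calls = (probs[:, 1] > 0.5).astype(np.int64)
    pos = y == 1
    neg = y == 0
    return AccuracyReport(
        n_positive=int(pos.sum()),
        n_negative=int(neg.sum()),
        correct_positive=int(np.sum(calls[pos] == 1)),
        correct_negative=int(np.sum(calls[neg] == 0)),
    )


def evaluate(model: Classifier, dataset: PeptideSet, alphabet: Alphabet = DEFAULT_ALPHABET) -> AccuracyReport:
    """Per-class and total accuracy of ``model`` on a labeled peptide set."""
    X, y = encode_batch(dataset, alphabet, for_training=True)
    if y is None:
        raise ValueError("evaluation requires labeled records")
    return evaluate_arrays(model, X, y)


def train_arrays(
    model: Classifier,
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    config: TrainingConfig,
) -> tuple[Classifier, TrainingHistory]:
    """Run the round-based loop on pre-encoded positive/negative arrays."""
    if len(X_pos) == 0 or len(X_neg) == 0:
        raise ValueError("both positive and negative sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam([t for _, t in model.parameters()], lr=config.learning_rate)
    history = TrainingHistory()
    best_weights = None
    train_X = train_y = held_X = held_y = None

    for r in range(1, config.max_rounds + 1):
        resampled = (r - 1) % config.resample_interval == 0
        if resampled:
            idx = _subsample_indices(len(X_neg), config.negative_subsample_fraction, rng)
            X = np.concatenate([X_pos, X_neg[idx]])
            y = np.concatenate(
                [np.ones(len(X_pos), dtype=np.int64), np.zeros(len(idx), dtype=np.int64)]
            )
            (train_X, train_y), (held_X, held_y) = split_train_heldout(
                X, y, config.train_fraction, rng
            )
        # one epoch over the training partition
        order = rng.permutation(len(train_X))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            optimizer.zero_grad()
            loss = model.loss_and_grads(train_X[batch], train_y[batch], rng)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at round {r}")
            optimizer.step()
            losses.append(loss)
        acc = _accuracy(model, held_X, held_y)
        checkpointed = acc > history.best_accuracy
        if checkpointed:
            history.best_accuracy = acc
            history.best_round = r
            history.best_heldout = (held_X, held_y)
            best_weights = model.get_weights()
        history.rounds.append(
            RoundRecord(
                round=r,
                train_loss=float(np.mean(losses)),
                heldout_accuracy=acc,
                checkpointed=checkpointed,
                resampled=resampled,
            )
        )
        if r - history.best_round >= config.patience:
            history.stop_reason = "patience"
            break
    else:
        history.stop_reason = "max_rounds"

    if best_weights is not None:
        model.set_weights(best_weights)
    return model, history


def train(
    model: Classifier,
    positives: PeptideSet,
    negatives: PeptideSet,
    config: TrainingConfig,
) -> tuple[Classifier, TrainingHistory]:
    """Train ``model`` on labeled peptide sets; returns best-checkpoint model."""
    X_pos, _ = encode_batch(positives, model.alphabet)
    X_neg, _ = encode_batch(negatives, model.alphabet)
    return train_arrays(model, X_pos, X_neg, config)
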