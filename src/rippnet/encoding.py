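"""Fixed-width one-hot encoding of peptide sequences.

Each residue becomes a length-20 indicator vector over the canonical amino
acids; sequences are truncated after residue 120 and shorter sequences are
zero-padded on the C-terminal side, giving every peptide the same 20 x 120
matrix shape expected by the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CANONICAL_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MAX_LENGTH = 120


class EncodingError(ValueError):
    """A sequence cannot be represented in the model alphabet."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet defining the one-hot row layout.

    The order is part of a trained model's contract and is serialized with
    its weights; the default is the 20 canonical codes in alphabetical order.
    """

    symbols: str = CANONICAL_AMINO_ACIDS

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet contains duplicate symbols")
        if len(self.symbols) != 20:
            raise ValueError("alphabet must contain exactly 20 symbols")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index_of(self, symbol: str) -> int:
        i = self.symbols.find(symbol)
        if i < 0:
            raise EncodingError(f"symbol {symbol!r} not in alphabet")
        return i


DEFAULT_ALPHABET = Alphabet()


@dataclass
class EncodedPeptide:
    """One-hot matrix (rows = alphabet, columns = positions) plus true length."""

    matrix: np.ndarray
    true_length: int


def encode(
    sequence: str, alphabet: Alphabet = DEFAULT_ALPHABET, max_length: int = MAX_LENGTH
) -> EncodedPeptide:
    """One-hot encode ``sequence``; residues beyond ``max_length`` are dropped."""
    if not sequence:
        raise EncodingError("cannot encode an empty sequence")
    true_length = min(len(sequence), max_length)
    matrix = np.zeros((alphabet.size, max_length))
    for j in range(true_length):
        symbol = sequence[j]
        row = alphabet.symbols.find(symbol)
        if row < 0:
            raise EncodingError(f"symbol {symbol!r} at position {j + 1} not in alphabet")
        matrix[row, j] = 1.0
    return EncodedPeptide(matrix=matrix, true_length=true_length)


def decode(encoded: EncodedPeptide, alphabet: Alphabet = DEFAULT_ALPHABET) -> str:
    """Invert :func:`encode` (exact for sequences up to 120 residues)."""
    matrix = encoded.matrix
    residues = []
    for j in range(encoded.true_length):
        col = matrix[:, j]
        (rows,) = np.nonzero(col)
        if len(rows) != 1 or col[rows[0]] != 1.0:
            raise EncodingError(f"malformed encoding: column {j} is not one-hot")
        residues.append(alphabet.symbols[rows[0]])
    if np.any(matrix[:, encoded.true_length :]):
        raise EncodingError("malformed encoding: non-zero padding column")
    return "".join(residues)


def encode_batch(peptide_set, alphabet: Alphabet = DEFAULT_ALPHABET, for_training: bool = False):
    """Encode a :class:`~rippnet.io.PeptideSet` into a stacked array.

    Returns ``(X, y)`` where ``X`` has shape ``(n, 20, 120)`` in record order
    and ``y`` is the aligned integer label vector, or ``None`` when the batch
    is unlabeled (prediction). A training batch must be fully labeled.
    """
    records = list(peptide_set)
    if not records:
        raise ValueError("cannot encode an empty peptide set")
    X = np.stack([encode(r.sequence, alphabet).matrix for r in records])
    labels = [r.label for r in records]
    n_labeled = sum(lab is not None for lab in labels)
    if for_training and n_labeled != len(records):
        raise ValueError("training batch mixes labeled and unlabeled records")
    y = np.array(labels, dtype=np.int64) if n_labeled == len(records) else None
    return X, y
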