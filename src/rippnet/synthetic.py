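"""Synthetic peptide datasets with a known, learnable class signal.

Real precursor-peptide corpora are assembled from external databases and
mining tools; for testing and benchmarking, this module emulates their key
property instead: positives carry a conserved leader-like motif (with
per-position substitution noise) inside otherwise random 20-120 aa
sequences, while negatives are motif-free but composition-matched to the
positive class. Matching residue composition removes the trivial
frequency-based shortcut, so a classifier that separates these sets must
have learned positional sequence structure. An exact sliding-window motif
scan provides a Bayes-optimal reference: at zero substitution noise it
separates the classes perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .encoding import CANONICAL_AMINO_ACIDS
from .io import PeptideRecord, PeptideSet

# arbitrary fixed 10-mer over the canonical alphabet; nothing biological
DEFAULT_MOTIF = "LCEWSKADGV"
# leader-like window: residues 3-12 (0-based offset 2), mimicking the
# N-terminal recognition region that tailoring enzymes bind
LEADER_OFFSET = 2


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset draw."""

    n_positive: int = 100
    n_negative: int = 100
    length_range: tuple[int, int] = (20, 120)
    motif: str = DEFAULT_MOTIF
    substitution_prob: float = 0.1
    motif_position_mode: str = "fixed_leader"  # or "uniform"
    background: np.ndarray | None = None  # frequency vector over the 20 residues
    seed: int = 0

    def __post_init__(self):
        if self.motif_position_mode not in ("fixed_leader", "uniform"):
            raise ValueError(f"unknown motif_position_mode {self.motif_position_mode!r}")
        if len(self.motif) >= self.length_range[0]:
            raise ValueError("motif must be shorter than the minimum sequence length")
        if not set(self.motif) <= set(CANONICAL_AMINO_ACIDS):
            raise ValueError("motif must use canonical residues")
        if self.background is None:
            self.background = np.full(20, 1.0 / 20)
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")


def motif_identity(sequence: str, motif: str) -> float:
    """Best sliding-window fractional identity of ``motif`` in ``sequence``."""
    k = len(motif)
    if len(sequence) < k:
        return 0.0
    best = 0
    for start in range(len(sequence) - k + 1):
        matches = sum(a == b for a, b in zip(sequence[start : start + k], motif))
        if matches > best:
            best = matches
    return best / k


def motif_scan_oracle(sequences, motif: str, min_identity: float = 0.8) -> np.ndarray:
    """Ground-truth classifier: positive iff a window reaches ``min_identity``.

    At zero substitution noise this scan (with ``min_identity=1.0``)
    separates the generated classes perfectly.
    """
    return np.array([int(motif_identity(s, motif) >= min_identity) for s in sequences])


def bayes_oracle(sequences, spec: "SyntheticSpec") -> np.ndarray:
    """Exact Bayes-optimal classifier under the generative model.

    Computes the log-likelihood ratio of each sequence under the positive
    model (motif embedded at the leader window, or uniformly, with
    per-position substitution noise) versus the background model, deciding
    positive when the ratio exceeds 1 (equal priors). This is the
    information-theoretic ceiling: no classifier seeing only the sequence
    can beat it in expectation, so it upper-bounds the networks on this
    benchmark.
    """
    k = len(spec.motif)
    p_sub = spec.substitution_prob
    bg = spec.background
    aa_index = {aa: i for i, aa in enumerate(CANONICAL_AMINO_ACIDS)}
    calls = []
    for seq in sequences:
        idx = np.array([aa_index[r] for r in seq])
        if spec.motif_position_mode == "fixed_leader":
            starts = [min(LEADER_OFFSET, len(seq) - k)]
        else:
            starts = range(len(seq) - k + 1)
        window_llrs = []
        for s in starts:
            llr = 0.0
            for i, motif_res in enumerate(spec.motif):
                r = idx[s + i]
                p_pos = (1.0 - p_sub) * (CANONICAL_AMINO_ACIDS[r] == motif_res) + p_sub / 20.0
                llr += np.log(p_pos) - np.log(bg[r])
            window_llrs.append(llr)
        # positive likelihood averages over equally likely start positions
        total = logsumexp(window_llrs) - np.log(len(window_llrs))
        calls.append(int(total > 0.0))
    return np.array(calls)


def _sample_sequence(rng, length, background):
    idx = rng.choice(20, size=length, p=background)
    return "".join(CANONICAL_AMINO_ACIDS[i] for i in idx)


def _noised_motif(rng, motif, substitution_prob):
    out = []
    for residue in motif:
        if rng.random() < substitution_prob:
            out.append(CANONICAL_AMINO_ACIDS[rng.integers(20)])
        else:
            out.append(residue)
    return "".join(out)


def _composition(sequences) -> np.ndarray:
    counts = np.zeros(20)
    lookup = {aa: i for i, aa in enumerate(CANONICAL_AMINO_ACIDS)}
    for s in sequences:
        for residue in s:
            counts[lookup[residue]] += 1
    return counts / counts.sum()


def generate(spec: SyntheticSpec) -> tuple[PeptideSet, PeptideSet]:
    """Draw one positive and one negative peptide set.

    Positives embed a noised copy of the motif (leader window or uniform
    position); negatives are sampled from the positives' empirical residue
    composition and rejected if any window resembles the motif (>= 60%
    identity), so the two classes differ only in positional structure.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    k = len(spec.motif)

    positives = []
    for i in range(spec.n_positive):
        length = int(rng.integers(lo, hi + 1))
        seq = list(_sample_sequence(rng, length, spec.background))
        if spec.motif_position_mode == "fixed_leader":
            start = min(LEADER_OFFSET, length - k)
        else:
            start = int(rng.integers(0, length - k + 1))
        seq[start : start + k] = _noised_motif(rng, spec.motif, spec.substitution_prob)
        positives.append(PeptideRecord(id=f"pos_{i}", sequence="".join(seq), label=1))

    # negatives drawn from the positives' empirical composition -> matched
    neg_background = _composition([r.sequence for r in positives])
    negatives = []
    max_attempts = 50 * max(spec.n_negative, 1)
    attempts = 0
    while len(negatives) < spec.n_negative:
        if attempts >= max_attempts:
            raise RuntimeError("composition-matched, motif-free sampling did not converge")
        attempts += 1
        length = int(rng.integers(lo, hi + 1))
        seq = _sample_sequence(rng, length, neg_background)
        if motif_identity(seq, spec.motif) >= 0.6:
            continue
        negatives.append(PeptideRecord(id=f"neg_{len(negatives)}", sequence=seq, label=0))

    return (
        PeptideSet(records=positives, name="synthetic_positives", provenance=f"seed={spec.seed}"),
        PeptideSet(records=negatives, name="synthetic_negatives", provenance=f"seed={spec.seed}"),
    )


def generate_imbalanced(spec: SyntheticSpec, ratio: int = 7) -> tuple[PeptideSet, PeptideSet]:
    """Generate with ``ratio`` negatives per positive (default 7:1, matching
    the imbalance of curated precursor-peptide corpora)."""
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    import dataclasses

    spec = dataclasses.replace(spec, n_negative=ratio * spec.n_positive)
    return generate(spec)
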