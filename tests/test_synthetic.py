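"""The synthetic benchmark: determinism, motif signal, composition matching."""

import numpy as np
import pytest

from rippnet.encoding import CANONICAL_AMINO_ACIDS
from rippnet.io import validate_and_filter
from rippnet.synthetic import (
    SyntheticSpec,
    bayes_oracle,
    generate,
    generate_imbalanced,
    motif_identity,
    motif_scan_oracle,
)


def _composition(pset):
    counts = {aa: 0 for aa in CANONICAL_AMINO_ACIDS}
    total = 0
    for rec in pset:
        for residue in rec.sequence:
            counts[residue] += 1
            total += 1
    return {aa: c / total for aa, c in counts.items()}


@pytest.fixture(scope="module")
def default_draw():
    spec = SyntheticSpec(n_positive=150, n_negative=150, seed=1)
    return spec, generate(spec)


def test_generation_is_deterministic():
    spec = SyntheticSpec(n_positive=100, n_negative=100, seed=1)
    a_pos, a_neg = generate(spec)
    b_pos, b_neg = generate(spec)
    assert [r.sequence for r in a_pos] == [r.sequence for r in b_pos]
    assert [r.sequence for r in a_neg] == [r.sequence for r in b_neg]


def test_positives_carry_a_recognizable_motif(default_draw):
    spec, (pos, _) = default_draw
    # at 10% substitution noise nearly all embedded motifs keep >= 80% identity;
    # every positive must at least carry a clearly non-background match
    identities = [motif_identity(r.sequence, spec.motif) for r in pos]
    assert np.mean(np.array(identities) >= 0.8) > 0.9
    assert min(identities) >= 0.5


def test_negatives_are_motif_free(default_draw):
    spec, (_, neg) = default_draw
    assert all(motif_identity(r.sequence, spec.motif) < 0.6 for r in neg)


def test_composition_matched_within_two_percent(default_draw):
    _, (pos, neg) = default_draw
    comp_pos = _composition(pos)
    comp_neg = _composition(neg)
    for aa in CANONICAL_AMINO_ACIDS:
        assert abs(comp_pos[aa] - comp_neg[aa]) <= 0.02


def test_generated_sets_pass_validation_unchanged(default_draw):
    _, (pos, neg) = default_draw
    for pset in (pos, neg):
        kept, report = validate_and_filter(pset)
        assert report.n_removed == 0
        assert len(kept) == len(pset)


def test_scan_oracle_perfect_at_zero_noise():
    spec = SyntheticSpec(n_positive=80, n_negative=80, substitution_prob=0.0, seed=9)
    pos, neg = generate(spec)
    seqs = [r.sequence for r in pos] + [r.sequence for r in neg]
    truth = np.array([1] * len(pos) + [0] * len(neg))
    np.testing.assert_array_equal(motif_scan_oracle(seqs, spec.motif, min_identity=1.0), truth)


def test_bayes_oracle_separates_noisy_classes(default_draw):
    spec, (pos, neg) = default_draw
    seqs = [r.sequence for r in pos] + [r.sequence for r in neg]
    truth = np.array([1] * len(pos) + [0] * len(neg))
    assert np.mean(bayes_oracle(seqs, spec) == truth) >= 0.99


def test_imbalanced_ratio_and_subsample_arithmetic():
    spec = SyntheticSpec(n_positive=300, seed=2)
    pos, neg = generate_imbalanced(spec, ratio=7)
    assert len(pos) == 300
    assert len(neg) == 2100
    # a 35% negative subsample restores ~2.45 negatives per positive
    assert int(np.floor(0.35 * len(neg))) / len(pos) == pytest.approx(2.45)


def test_uniform_motif_position_mode():
    spec = SyntheticSpec(
        n_positive=50, n_negative=10, motif_position_mode="uniform", substitution_prob=0.0, seed=3
    )
    pos, _ = generate(spec)
    starts = {r.sequence.find(spec.motif) for r in pos}
    assert all(s >= 0 for s in starts)
    assert len(starts) > 5  # placement actually varies


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        SyntheticSpec(motif="A" * 25)  # longer than min length
    with pytest.raises(ValueError):
        SyntheticSpec(motif_position_mode="centered")
    with pytest.raises(ValueError):
        generate_imbalanced(SyntheticSpec(), ratio=0)
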