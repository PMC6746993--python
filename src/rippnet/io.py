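"""Reading, validating, filtering and dereplicating peptide sequence sets.

FASTA is the interchange format: precursor-peptide training sets and
candidate pools are plain amino-acid FASTA files, typically emitted by an
ORF caller. Records carrying non-canonical residues (X, B, Z, J, U, O or an
internal stop) are excluded outright — the one-hot encoding has no wildcard
row — and length filtering enforces the 20-120 aa window within which short
precursor peptides are sought.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from Bio import SeqIO

from .encoding import CANONICAL_AMINO_ACIDS

MIN_LENGTH = 20
MAX_LENGTH = 120

_CANONICAL = frozenset(CANONICAL_AMINO_ACIDS)


class EmptyInputError(ValueError):
    """No parseable records in the input."""


class EmptyOutputError(ValueError):
    """Filtering removed every record."""


class DuplicateIdError(ValueError):
    """Two FASTA records share an id; predictions are keyed by id."""


@dataclass
class PeptideRecord:
    """One identified amino-acid sequence with optional class label.

    ``label`` is 1 for a precursor peptide, 0 for a non-precursor;
    ``hit_flag`` is an externally supplied profile-HMM hit annotation.
    """

    id: str
    sequence: str
    label: Optional[int] = None
    hit_flag: Optional[bool] = None

    def __post_init__(self):
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def is_canonical(self) -> bool:
        return bool(self.sequence) and set(self.sequence) <= _CANONICAL


@dataclass
class PeptideSet:
    """An ordered collection of peptide records."""

    records: list[PeptideRecord] = field(default_factory=list)
    name: str = ""
    provenance: str = ""

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def label_counts(self) -> dict:
        counts = {0: 0, 1: 0, None: 0}
        for r in self.records:
            counts[r.label] += 1
        return counts


@dataclass
class FilterReport:
    """Per-reason exclusion counts from :func:`validate_and_filter`."""

    n_input: int = 0
    n_kept: int = 0
    removed_non_canonical: int = 0
    removed_too_short: int = 0
    removed_too_long: int = 0

    @property
    def n_removed(self) -> int:
        return self.removed_non_canonical + self.removed_too_short + self.removed_too_long

    def summary_lines(self) -> list[str]:
        return [
            f"input records: {self.n_input}",
            f"kept: {self.n_kept}",
            f"removed (non-canonical residue): {self.removed_non_canonical}",
            f"removed (shorter than minimum): {self.removed_too_short}",
            f"removed (longer than maximum): {self.removed_too_long}",
        ]

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "removed_non_canonical": self.removed_non_canonical,
            "removed_too_short": self.removed_too_short,
            "removed_too_long": self.removed_too_long,
        }


def read_fasta(path, label: Optional[int] = None, name: str = "") -> PeptideSet:
    """Read an amino-acid FASTA file into a :class:`PeptideSet`.

    Sequences are upper-cased and a single trailing stop codon ``*`` is
    stripped (ORF callers commonly emit it). ``label``, when given, is
    applied to every record. Duplicate ids raise :class:`DuplicateIdError`.
    """
    path = Path(path)
    records = []
    seen_ids = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if entry.id in seen_ids:
            raise DuplicateIdError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen_ids.add(entry.id)
        records.append(PeptideRecord(id=entry.id, sequence=seq, label=label))
    if not records:
        raise EmptyInputError(f"no FASTA records parsed from {path}")
    return PeptideSet(records=records, name=name or path.stem, provenance=str(path))


def validate_and_filter(
    peptide_set: PeptideSet,
    min_len: int = MIN_LENGTH,
    max_len: int = MAX_LENGTH,
    allow_out_of_range: bool = False,
) -> tuple[PeptideSet, FilterReport]:
    """Drop records with non-canonical residues or out-of-range lengths.

    Length bounds are inclusive. With ``allow_out_of_range`` the length
    filter is waived (over-length sequences are truncated later, at
    encoding); the residue filter always applies because excluded symbols
    have no one-hot row.
    """
    report = FilterReport(n_input=len(peptide_set))
    kept = []
    for rec in peptide_set:
        if not rec.is_canonical():
            report.removed_non_canonical += 1
            continue
        if not allow_out_of_range:
            if rec.length < min_len:
                report.removed_too_short += 1
                continue
            if rec.length > max_len:
                report.removed_too_long += 1
                continue
        kept.append(rec)
    report.n_kept = len(kept)
    if not kept:
        raise EmptyOutputError(f"all {report.n_input} records removed by validation")
    return (
        PeptideSet(records=kept, name=peptide_set.name, provenance=peptide_set.provenance),
        report,
    )


def dereplicate(peptide_set: PeptideSet) -> PeptideSet:
    """Keep the first occurrence of each distinct sequence string.

    Order is otherwise preserved; the operation is idempotent. Sources of
    curated precursor sets overlap heavily, so training sets are always
    dereplicated before use.
    """
    seen = set()
    kept = []
    for rec in peptide_set:
        if rec.sequence in seen:
            continue
        seen.add(rec.sequence)
        kept.append(rec)
    return PeptideSet(records=kept, name=peptide_set.name, provenance=peptide_set.provenance)


def write_predictions(results, path) -> None:
    """Write prediction records as a TSV table (scores to 6 decimal places)."""
    results = list(results)
    if not results:
        raise ValueError("no prediction records to write")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("id\tlength\tscore_negative\tscore_positive\tcall\n")
        for r in results:
            fh.write(
                f"{r.id}\t{r.length}\t{r.score_negative:.6f}\t{r.score_positive:.6f}\t{r.call}\n"
            )


def read_predictions(path) -> list:
    """Read back a TSV written by :func:`write_predictions`."""
    from .enrichment import PredictionRecord

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["id", "length", "score_negative", "score_positive", "call"]
        if header != expected:
            raise ValueError(f"unexpected prediction table header: {header}")
        for line in fh:
            rid, length, s0, s1, call = line.rstrip("\n").split("\t")
            out.append(
                PredictionRecord(
                    id=rid,
                    length=int(length),
                    score_negative=float(s0),
                    score_positive=float(s1),
                    call=call,
                )
            )
    return out


def read_hit_flags(path) -> dict[str, bool]:
    """Read a two-column (id, 0/1) TSV of external profile-HMM hit flags."""
    flags = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            rid, flag = parts
            if rid == "id":  # optional header row
                continue
            if flag not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: hit flag must be 0 or 1, got {flag!r}")
            flags[rid] = flag == "1"
    return flags
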