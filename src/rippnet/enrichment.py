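"""Hit-rate enrichment of classifier calls against external annotations.

In a genome-mining workflow, candidate peptides carry an external binary
annotation — typically whether the sequence matches a profile HMM of a
known precursor family. A useful classifier concentrates those hits: the
fold enrichment is the hit rate among sequences called positive divided by
the hit rate of the whole candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


@dataclass
class PredictionRecord:
    """Per-sequence class scores and the resulting call."""

    id: str
    length: int
    score_negative: float
    score_positive: float
    call: str  # "precursor" or "non-precursor"


def make_call(score_positive: float, threshold: float = 0.5) -> str:
    """Positive iff the score strictly exceeds the threshold (ties negative)."""
    return "precursor" if score_positive > threshold else "non-precursor"


@dataclass
class EnrichmentSummary:
    n_total: int
    n_called_positive: int
    n_called_negative: int
    hits_total: int
    hits_in_positive_calls: int
    hits_in_negative_calls: int
    hit_rate_overall: float
    hit_rate_positive_calls: Optional[float]
    hit_rate_negative_calls: Optional[float]
    fold_enrichment: Optional[float]  # None when undefined (zero denominator)

    def summary_lines(self) -> list[str]:
        def pct(x):
            return "undefined" if x is None else f"{100 * x:.2f}%"

        fold = "undefined" if self.fold_enrichment is None else f"{self.fold_enrichment:.2f}"
        return [
            f"sequences: {self.n_total}",
            f"called precursor: {self.n_called_positive}",
            f"hit rate overall: {pct(self.hit_rate_overall)}",
            f"hit rate among precursor calls: {pct(self.hit_rate_positive_calls)}",
            f"hit rate among non-precursor calls: {pct(self.hit_rate_negative_calls)}",
            f"fold enrichment: {fold}",
        ]


def enrichment_report(predictions, hit_flags: dict[str, bool]) -> EnrichmentSummary:
    """Compare classifier calls with external hit annotations.

    Every prediction id must appear in ``hit_flags``; fold enrichment is
    reported as ``None`` (undefined) when the overall hit rate is zero or no
    sequence was called positive, never as infinity.
    """
    predictions = list(predictions)
    missing = [p.id for p in predictions if p.id not in hit_flags]
    if missing:
        raise KeyError(f"ids missing from hit table: {missing}")
    n = len(predictions)
    if n == 0:
        raise ValueError("no predictions to summarise")
    pos = [p for p in predictions if p.call == "precursor"]
    neg = [p for p in predictions if p.call != "precursor"]
    hits_total = sum(hit_flags[p.id] for p in predictions)
    hits_pos = sum(hit_flags[p.id] for p in pos)
    hits_neg = sum(hit_flags[p.id] for p in neg)
    rate_all = hits_total / n
    rate_pos = hits_pos / len(pos) if pos else None
    rate_neg = hits_neg / len(neg) if neg else None
    fold = None
    if rate_pos is not None and rate_all > 0:
        fold = rate_pos / rate_all
    return EnrichmentSummary(
        n_total=n,
        n_called_positive=len(pos),
        n_called_negative=len(neg),
        hits_total=hits_total,
        hits_in_positive_calls=hits_pos,
        hits_in_negative_calls=hits_neg,
        hit_rate_overall=rate_all,
        hit_rate_positive_calls=rate_pos,
        hit_rate_negative_calls=rate_neg,
        fold_enrichment=fold,
    )
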