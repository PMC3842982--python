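"""Read quality control: B-tail trimming, length filtering, dataset capping.

Illumina 1.5-era pipelines flag unreliable read tails with runs of Q2 bases
(the character 'B' in Phred-64 encoding), the so-called "B-tail".  QC here is
defined by the quality threshold, not the literal character: the maximal
3' suffix in which every base is below ``min_q`` (default Q15) is removed.
A pair is kept only if BOTH trimmed mates are at least ``min_len`` bases
(default 50) — repeat detection and primer design need usable sequence on
both mates.  The retained stream is capped at ``max_pairs`` QC-passed pairs
(default 5 million) in input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .fastq_io import ReadPair

__all__ = ["QCParams", "QCReport", "btail_trim", "qc_pair", "run_qc"]


@dataclass(frozen=True)
class QCParams:
    """Quality-control thresholds.

    min_q: bases with quality below this are trimmable tail (Phred units).
    min_len: minimum post-trim length required of each mate (bp).
    max_pairs: cap on the number of QC-passed pairs retained.
    """

    min_q: int = 15
    min_len: int = 50
    max_pairs: int = 5_000_000

    def __post_init__(self) -> None:
        if self.min_q < 0 or self.min_len < 1 or self.max_pairs < 1:
            raise ValueError("invalid QC parameters")


@dataclass
class QCReport:
    pairs_in: int = 0
    pairs_trimmed: int = 0
    pairs_dropped_short: int = 0
    pairs_retained: int = 0
    bases_trimmed: int = 0
    truncated_at_cap: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def btail_trim(seq: str, qual: list[int], min_q: int = 15) -> tuple[str, list[int]]:
    """Remove the maximal all-below-threshold suffix of a read.

    Scans from the 3' end until the first base with quality >= ``min_q``;
    everything after it is removed.  Interior low-quality bases are never
    touched, and a low-quality prefix is not a tail.  Idempotent.
    """
    end = len(qual)
    while end > 0 and qual[end - 1] < min_q:
        end -= 1
    if end == len(seq):
        return seq, qual
    return seq[:end], qual[:end]


def qc_pair(pair: ReadPair, params: QCParams = QCParams()) -> ReadPair | None:
    """Trim both mates; return the trimmed pair, or None if either mate is short."""
    s1, q1 = btail_trim(pair.seq1, pair.qual1, params.min_q)
    s2, q2 = btail_trim(pair.seq2, pair.qual2, params.min_q)
    if len(s1) < params.min_len or len(s2) < params.min_len:
        return None
    return ReadPair(pair.pair_id, s1, q1, s2, q2, dict(pair.meta))


def run_qc(
    pairs: Iterable[ReadPair],
    params: QCParams = QCParams(),
    report: QCReport | None = None,
) -> Iterator[ReadPair]:
    """QC a stream, emitting passing pairs in order up to ``max_pairs``.

    If ``report`` is supplied its counters are filled in as the stream is
    consumed (the generator must be exhausted for the totals to be final).
    """
    rep = report if report is not None else QCReport()
    for pair in pairs:
        rep.pairs_in += 1
        kept = qc_pair(pair, params)
        trimmed = (
            len(pair.seq1) + len(pair.seq2) - (len(kept.seq1) + len(kept.seq2))
            if kept is not None
            else None
        )
        if kept is None:
            rep.pairs_dropped_short += 1
            continue
        if trimmed:
            rep.pairs_trimmed += 1
            rep.bases_trimmed += trimmed
        rep.pairs_retained += 1
        yield kept
        if rep.pairs_retained >= params.max_pairs:
            rep.truncated_at_cap = True
            return
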