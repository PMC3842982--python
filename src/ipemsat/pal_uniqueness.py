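"""Primer-uniqueness screening across the whole read set.

A PAL whose forward and reverse primer each occur exactly once in the entire
dataset is a *premium PAL* (pPAL): its primers are very unlikely to sit in a
repetitive element, the classic failure mode in which one primer pair
amplifies many loci at once.  Occurrences are counted at the sequence level —
every (read, offset) position at which the primer OR its reverse complement
appears as an exact substring of either mate, overlapping hits included —
which is the strictest reading of "found only one time" and is what guards
against multi-locus amplification.

Counting uses an Aho–Corasick automaton built over the primer set (written
here because no multi-pattern matcher ships with the scientific stack):
one streaming pass over the reads, with memory proportional to the number of
patterns times their length, never to the dataset size.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

from .fastq_io import ReadPair
from .primer_design import PALRecord
from .ssr_detect import revcomp

__all__ = [
    "AhoCorasick",
    "OccurrenceTable",
    "HistogramBins",
    "HISTOGRAM_EDGES",
    "count_occurrences",
    "flag_premium",
    "copy_number_histogram",
]

#: Copy-number histogram bins: (low, high) inclusive, exhaustive over >= 1.
HISTOGRAM_EDGES: tuple[tuple[int, float], ...] = (
    (1, 1),
    (2, 10),
    (11, 100),
    (101, 1_000),
    (1_001, 10_000),
    (10_001, 100_000),
    (100_001, float("inf")),
)

HISTOGRAM_LABELS = ("1", "2-10", "11-100", "101-1000", "1001-10000",
                    "10001-100000", ">100000")


class AhoCorasick:
    """Multi-pattern exact matcher over a fixed pattern set.

    Classic construction: a trie with failure links collapsed into a dense
    goto function, plus per-state output lists, so the scan advances one
    state per character with no backtracking.
    """

    def __init__(self, patterns: Sequence[str]):
        if not patterns:
            raise ValueError("pattern set must be nonempty")
        self.patterns = list(patterns)
        # trie
        goto: list[dict[str, int]] = [{}]
        out: list[list[int]] = [[]]
        for pi, pat in enumerate(self.patterns):
            s = 0
            for ch in pat:
                nxt = goto[s].get(ch)
                if nxt is None:
                    goto.append({})
                    out.append([])
                    nxt = len(goto) - 1
                    goto[s][ch] = nxt
                s = nxt
            out[s].append(pi)
        # BFS failure links; outputs inherited along them
        fail = [0] * len(goto)
        q: deque[int] = deque(goto[0].values())
        while q:
            r = q.popleft()
            for ch, t in goto[r].items():
                q.append(t)
                f = fail[r]
                while f and ch not in goto[f]:
                    f = fail[f]
                nxt = goto[f].get(ch, 0)
                fail[t] = nxt if nxt != t else 0
                out[t].extend(out[fail[t]])
        self._goto = self._densify(goto, fail)
        self._out = out

    @staticmethod
    def _bfs_order(goto: list[dict[str, int]]) -> list[int]:
        order = [0]
        q = deque(goto[0].values())
        seen = {0, *goto[0].values()}
        order.extend(goto[0].values())
        while q:
            s = q.popleft()
            for t in goto[s].values():
                if t not in seen:
                    seen.add(t)
                    order.append(t)
                    q.append(t)
        return order

    @staticmethod
    def _densify(
        goto: list[dict[str, int]], fail: list[int]
    ) -> list[dict[str, int]]:
        dense: list[dict[str, int] | None] = [None] * len(goto)
        dense[0] = dict(goto[0])
        for s in AhoCorasick._bfs_order(goto):
            if s == 0:
                continue
            d = dict(dense[fail[s]])  # parent in BFS was densified first
            d.update(goto[s])
            dense[s] = d
        return dense  # type: ignore[return-value]

    def count_into(self, text: str, counts: list[int]) -> None:
        """Add every (offset, pattern) hit in ``text`` to ``counts``."""
        goto = self._goto
        out = self._out
        s = 0
        for ch in text:
            s = goto[s].get(ch, 0)
            if out[s]:
                for pi in out[s]:
                    counts[pi] += 1

    def scan(self, text: str) -> list[int]:
        counts = [0] * len(self.patterns)
        self.count_into(text, counts)
        return counts


@dataclass
class OccurrenceTable:
    """Copy number of each primer across the read set (both strands)."""

    counts: dict[str, int]

    def __getitem__(self, primer: str) -> int:
        return self.counts[primer]

    def __contains__(self, primer: str) -> bool:
        return primer in self.counts

    def __len__(self) -> int:
        return len(self.counts)


def count_occurrences(
    primers: Iterable[str], reads: Iterable[ReadPair]
) -> OccurrenceTable:
    """Exact occurrence counts of each primer (or its reverse complement)
    over both mates of every pair, overlapping hits included.

    The result is independent of read order.  A primer planted in k fully
    covered genomic copies is counted at least k times.
    """
    primer_list = sorted(set(primers))
    if not primer_list:
        raise ValueError("no primers to count")
    for p in primer_list:
        if not (10 <= len(p) <= 36) or any(c not in "ACGT" for c in p):
            raise ValueError(f"invalid primer {p!r}")
    # Deduplicate search patterns: a primer and its reverse complement are
    # the same oligo, and a palindromic primer must not be counted twice.
    patterns: list[str] = []
    pattern_index: dict[str, int] = {}
    owners: list[list[int]] = []  # pattern -> primer indices it contributes to
    for i, p in enumerate(primer_list):
        for variant in {p, revcomp(p)}:
            j = pattern_index.get(variant)
            if j is None:
                j = len(patterns)
                pattern_index[variant] = j
                patterns.append(variant)
                owners.append([])
            owners[j].append(i)
    ac = AhoCorasick(patterns)
    pat_counts = [0] * len(patterns)
    for pair in reads:
        ac.count_into(pair.seq1, pat_counts)
        ac.count_into(pair.seq2, pat_counts)
    totals = [0] * len(primer_list)
    for j, c in enumerate(pat_counts):
        for i in owners[j]:
            totals[i] += c
    return OccurrenceTable({p: totals[i] for i, p in enumerate(primer_list)})


def flag_premium(
    records: Iterable[PALRecord], table: OccurrenceTable
) -> list[PALRecord]:
    """Set copy numbers and the pPAL flag on every PAL record.

    A pPAL has both primers at copy number exactly 1 (the design read
    itself).  A copy number of 0 is impossible by construction and raises.
    """
    out = []
    for rec in records:
        if rec.primer_pair is not None:
            pp = rec.primer_pair
            if pp.fwd_seq not in table or pp.rev_seq not in table:
                raise ValueError(f"{rec.pair_id}: primer missing from table")
            rec.fwd_copies = table[pp.fwd_seq]
            rec.rev_copies = table[pp.rev_seq]
            if rec.fwd_copies < 1 or rec.rev_copies < 1:
                raise ValueError(
                    f"{rec.pair_id}: primer copy number 0 — the design read "
                    "itself was not counted"
                )
            rec.is_ppal = rec.fwd_copies == 1 and rec.rev_copies == 1
        out.append(rec)
    return out


@dataclass
class HistogramBins:
    """Copy-number histogram over the fixed logarithmic-style bins."""

    labels: tuple[str, ...]
    counts: list[int]
    proportions: list[float]

    @property
    def total(self) -> int:
        return sum(self.counts)


def copy_number_histogram(
    table: OccurrenceTable,
    records: Iterable[PALRecord] | None = None,
    which: str = "forward",
) -> HistogramBins:
    """Bin primer copy numbers into {1, 2–10, ..., >100,000}.

    With ``records`` given, histograms the designed primers of those records
    (``which`` in forward/reverse/both, one entry per primer per record);
    otherwise histograms every primer in the table once.
    """
    if which not in ("forward", "reverse", "both"):
        raise ValueError("which must be forward, reverse or both")
    values: list[int] = []
    if records is None:
        values = list(table.counts.values())
    else:
        for rec in records:
            if rec.primer_pair is None:
                continue
            if which in ("forward", "both"):
                values.append(table[rec.primer_pair.fwd_seq])
            if which in ("reverse", "both"):
                values.append(table[rec.primer_pair.rev_seq])
    if not values:
        raise ValueError("nothing to histogram")
    counts = [0] * len(HISTOGRAM_EDGES)
    for v in values:
        if v < 1:
            raise ValueError(f"copy number {v} < 1")
        for b, (lo, hi) in enumerate(HISTOGRAM_EDGES):
            if lo <= v <= hi:
                counts[b] += 1
                break
    n = len(values)
    return HistogramBins(
        labels=HISTOGRAM_LABELS,
        counts=counts,
        proportions=[c / n for c in counts],
    )
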