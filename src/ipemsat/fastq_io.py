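"""Paired-end FASTQ input/output with explicit quality-encoding handling.

Readers yield :class:`ReadPair` records; every downstream stage (QC, repeat
detection, primer design, uniqueness counting) consumes that stream.  Both
two-file and interleaved layouts are accepted; two-file is the canonical
output form.  Plain and gzip-compressed files are supported transparently.

Quality strings are decoded to integer Phred scores at read time using an
explicit ASCII offset (33 for Sanger/Illumina 1.8+, 64 for Illumina 1.3–1.5),
so downstream code never sees encoding-dependent characters.  In Phred-64
data the character 'B' decodes to Q2 — the trailing low-quality run that the
QC stage trims.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from itertools import zip_longest
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "ReadPair",
    "QualityEncoding",
    "PHRED33",
    "PHRED64",
    "EncodingError",
    "PairingError",
    "read_pairs",
    "read_pairs_interleaved",
    "detect_encoding",
    "write_pairs",
]


class PairingError(ValueError):
    """Mate files disagree (record count or identifiers)."""


class EncodingError(ValueError):
    """Quality characters are inconsistent with the stated Phred offset."""


@dataclass(frozen=True)
class QualityEncoding:
    """A Phred ASCII encoding: ``score = ord(char) - offset``."""

    name: str
    offset: int

    def __post_init__(self) -> None:
        if self.offset not in (33, 64):
            raise ValueError(f"unsupported Phred offset {self.offset}")


PHRED33 = QualityEncoding("phred33", 33)
PHRED64 = QualityEncoding("phred64", 64)

#: Biopython SeqIO format name for each supported encoding.
_BIO_FORMAT = {33: "fastq", 64: "fastq-illumina"}

# Suffixes stripped from read ids so the two mates of a pair compare equal.
_MATE_SUFFIXES = ("/1", "/2")


@dataclass
class ReadPair:
    """One paired-end record: two mates with per-base Phred scores.

    ``seq1``/``seq2`` are uppercase strings over {A, C, G, T, N};
    ``qual1``/``qual2`` are lists of integer Phred scores of equal length.
    ``meta`` carries free-form tags (species label, library prep, ...).
    """

    pair_id: str
    seq1: str
    qual1: list[int]
    seq2: str
    qual2: list[int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.pair_id}: sequence/quality length mismatch")

    @property
    def mates(self) -> tuple[tuple[str, list[int]], tuple[str, list[int]]]:
        return (self.seq1, self.qual1), (self.seq2, self.qual2)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def strip_mate_suffix(read_id: str) -> str:
    """Normalise a read id by removing mate designators.

    Handles ``/1`` ``/2`` suffixes and Casava 1.8 ``name 1:...`` / ``name 2:...``
    descriptions (the latter are already split off by the FASTQ parser, which
    keeps only the first whitespace-delimited token as ``id``).
    """
    for suf in _MATE_SUFFIXES:
        if read_id.endswith(suf):
            return read_id[: -len(suf)]
    return read_id


def _decode_record(rec: SeqRecord) -> tuple[str, str, list[int]]:
    seq = str(rec.seq).upper()
    qual = rec.letter_annotations["phred_quality"]
    return rec.id, seq, list(qual)


def _check_scores(read_id: str, qual: list[int], encoding: QualityEncoding) -> None:
    low = min(qual, default=0)
    if low < 0:
        other = "phred33" if encoding.offset == 64 else "phred64"
        raise EncodingError(
            f"{read_id}: quality character below offset {encoding.offset}; "
            f"the file is probably {other}-encoded"
        )


def _iter_fastq(handle: IO[str], encoding: QualityEncoding, label: str):
    """Parse FASTQ, translating the parser's range errors into EncodingError."""
    it = SeqIO.parse(handle, _BIO_FORMAT[encoding.offset])
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            other = "phred33" if encoding.offset == 64 else "phred64"
            raise EncodingError(
                f"{label}: quality characters inconsistent with "
                f"{encoding.name} (try {other}): {exc}"
            ) from exc
        yield rec


def read_pairs(
    path1: str | Path,
    path2: str | Path,
    encoding: QualityEncoding = PHRED33,
) -> Iterator[ReadPair]:
    """Stream record-aligned mate files as :class:`ReadPair` objects.

    Files must contain the same number of records in the same order, with ids
    equal after mate-suffix stripping.  Raises :class:`PairingError` naming
    the first divergent record otherwise, and :class:`EncodingError` if a
    quality character falls below the stated offset.
    """
    with _open_text(path1) as h1, _open_text(path2) as h2:
        it1 = _iter_fastq(h1, encoding, Path(path1).name)
        it2 = _iter_fastq(h2, encoding, Path(path2).name)
        for i, (r1, r2) in enumerate(zip_longest(it1, it2)):
            if r1 is None or r2 is None:
                short = Path(path1).name if r1 is None else Path(path2).name
                raise PairingError(
                    f"mate files have different record counts: "
                    f"{short} ends at record {i}"
                )
            id1, seq1, q1 = _decode_record(r1)
            id2, seq2, q2 = _decode_record(r2)
            base1, base2 = strip_mate_suffix(id1), strip_mate_suffix(id2)
            if base1 != base2:
                raise PairingError(
                    f"mate id mismatch at record {i}: {id1!r} vs {id2!r}"
                )
            _check_scores(id1, q1, encoding)
            _check_scores(id2, q2, encoding)
            yield ReadPair(base1, seq1, q1, seq2, q2)


def read_pairs_interleaved(
    path: str | Path, encoding: QualityEncoding = PHRED33
) -> Iterator[ReadPair]:
    """Stream an interleaved FASTQ (mate 1 and mate 2 alternating)."""
    with _open_text(path) as handle:
        it = _iter_fastq(handle, encoding, Path(path).name)
        for i, r1 in enumerate(it):
            r2 = next(it, None)
            if r2 is None:
                raise PairingError(
                    f"interleaved file has an odd record count; "
                    f"record {2 * i} ({r1.id}) has no mate"
                )
            id1, seq1, q1 = _decode_record(r1)
            id2, seq2, q2 = _decode_record(r2)
            base1, base2 = strip_mate_suffix(id1), strip_mate_suffix(id2)
            if base1 != base2:
                raise PairingError(
                    f"interleaved mate id mismatch at pair {i}: {id1!r} vs {id2!r}"
                )
            _check_scores(id1, q1, encoding)
            _check_scores(id2, q2, encoding)
            yield ReadPair(base1, seq1, q1, seq2, q2)


def detect_encoding(
    path: str | Path,
    n_probe: int = 1000,
    default: QualityEncoding = PHRED33,
) -> QualityEncoding:
    """Infer the Phred offset from the first ``n_probe`` records.

    Characters below '@' (ord 64) can only be Phred-33; characters above 'h'
    (ord 104, Q40 in Phred-64) only occur in Phred-64 files in practice.  If
    every character falls in the overlap zone 'B'..'h' the call is ambiguous
    and ``default`` is returned with a warning.
    """
    if n_probe < 1:
        raise ValueError("n_probe must be >= 1")
    lo, hi = 255, 0
    n_seen = 0
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq-sanger"):
            # re-encode to raw chars via the known parse offset of 33
            for q in rec.letter_annotations["phred_quality"]:
                c = q + 33
                lo, hi = min(lo, c), max(hi, c)
            n_seen += 1
            if n_seen >= n_probe:
                break
    if n_seen == 0:
        raise ValueError(f"{path}: no FASTQ records to probe")
    if lo < 64:
        return PHRED33
    if lo >= ord("B") and hi > ord("h"):
        return PHRED64
    logger.warning(
        "%s: quality characters all in the ambiguous range %r-%r; "
        "defaulting to %s",
        path,
        chr(lo),
        chr(hi),
        default.name,
    )
    return default


def write_pairs(
    pairs: Iterable[ReadPair],
    path1: str | Path,
    path2: str | Path,
    encoding: QualityEncoding = PHRED33,
) -> int:
    """Write pairs to two mate files; returns the number of pairs written.

    Round-trip identity holds: reading the written files back with the same
    encoding reproduces (pair_id, seq, decoded quality) exactly.
    """
    fmt = _BIO_FORMAT[encoding.offset]

    def _rec(pid: str, mate: int, seq: str, qual: list[int]) -> SeqRecord:
        rec = SeqRecord(Seq(seq), id=f"{pid}/{mate}", description="")
        rec.letter_annotations["phred_quality"] = qual
        return rec

    n = 0
    with _open_text_w(path1) as h1, _open_text_w(path2) as h2:
        for pair in pairs:
            SeqIO.write([_rec(pair.pair_id, 1, pair.seq1, pair.qual1)], h1, fmt)
            SeqIO.write([_rec(pair.pair_id, 2, pair.seq2, pair.qual2)], h2, fmt)
            n += 1
    return n


def _open_text_w(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "w")
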