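"""Perfect microsatellite (SSR) detection in short reads.

Finds every maximal perfect tandem repeat of a primitive 2–6 bp unit in each
mate and classifies read pairs as SSR-positive.  A repeat run is *perfect*
(the unit repeated an integer number of times with no interruptions),
*primitive* (the unit is not itself a repetition of a shorter string, which
excludes homopolymers and prevents an AC run from also being reported as
ACAC), and *maximal* (it cannot be extended by one full unit on either side).
'N' bases break any repeat.

Motifs are grouped into classes by their canonical form: the lexicographic
minimum over all cyclic rotations of the unit and of its reverse complement,
so AC/CA/GT/TG all count as one dinucleotide class.

Each SSR-positive pair is assigned exactly one unit-length class — that of
its longest repeat run (ties to the larger unit, then the earlier locus on
mate 1 then mate 2) — so per-class counts partition the positive-pair total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fastq_io import ReadPair

__all__ = [
    "RepeatParams",
    "SSRLocus",
    "canonical_motif",
    "find_perfect_repeats",
    "classify_pair",
    "revcomp",
    "CLASS_NAMES",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Conventional names for unit-length classes.
CLASS_NAMES = {2: "2mer", 3: "3mer", 4: "4mer", 5: "5mer", 6: "6mer"}

#: Minimum whole-repeat counts by unit length; common practice for
#: short-read SSR mining (dinucleotides need more copies to be useful).
DEFAULT_MIN_REPEATS = {2: 6, 3: 4, 4: 4, 5: 4, 6: 4}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatParams:
    """Which repeats count: unit lengths and per-unit-length minimum copies."""

    min_repeats_by_unit: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )

    def __post_init__(self) -> None:
        for u, m in self.min_repeats_by_unit.items():
            if u not in (2, 3, 4, 5, 6):
                raise ValueError(f"unit length {u} outside 2..6")
            if m < 2:
                raise ValueError(f"minimum repeat count for {u}-mers must be >= 2")

    @property
    def units_allowed(self) -> tuple[int, ...]:
        return tuple(sorted(self.min_repeats_by_unit))


@dataclass(frozen=True)
class SSRLocus:
    """One maximal perfect repeat run on one mate.

    Coordinates are 0-based half-open on the (trimmed) read; ``unit`` is the
    motif as read at ``start``; ``canonical_unit`` its motif class.
    """

    pair_id: str
    mate: int
    start: int
    end: int
    unit: str
    canonical_unit: str
    n_repeats: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def is_primitive(unit: str) -> bool:
    """True if the unit is not a whole-number repetition of a shorter string."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit[:d] * (n // d) == unit:
            return False
    return True


def canonical_motif(unit: str) -> str:
    """Canonical representative of a motif class.

    Lexicographic minimum over all cyclic rotations of ``unit`` and all
    cyclic rotations of its reverse complement, e.g. GT -> AC, GAT -> ATC.
    """
    if not unit or any(c not in "ACGT" for c in unit):
        raise ValueError(f"motif must be non-empty over ACGT, got {unit!r}")
    if len(unit) < 2 or not is_primitive(unit):
        raise ValueError(f"motif must be primitive with length >= 2, got {unit!r}")
    rc = revcomp(unit)
    doubled, doubled_rc = unit + unit, rc + rc
    n = len(unit)
    return min(
        min(doubled[i : i + n] for i in range(n)),
        min(doubled_rc[i : i + n] for i in range(n)),
    )


def find_perfect_repeats(
    seq: str,
    params: RepeatParams = RepeatParams(),
    pair_id: str = "",
    mate: int = 1,
) -> list[SSRLocus]:
    """All maximal perfect primitive repeat runs meeting the minimum counts.

    Runs of different unit lengths may overlap; each run is reported once,
    anchored at its leftmost whole-unit start.  Runs with a partial extra
    unit on the right are reported with whole-repeat span only.
    """
    n = len(seq)
    loci: list[SSRLocus] = []
    for u in params.units_allowed:
        min_rep = params.min_repeats_by_unit[u]
        if n < u * min_rep:
            continue
        # match[i] is True where seq[i] == seq[i+u] and both are ACGT;
        # a run of k consecutive matches spans k+u bases of tandem structure.
        i = 0
        limit = n - u
        while i < limit:
            a, b = seq[i], seq[i + u]
            if a != b or a == "N":
                i += 1
                continue
            j = i
            while j < limit and seq[j] == seq[j + u] and seq[j] != "N":
                j += 1
            run_len = (j - i) + u  # total bases of tandem structure
            n_rep = run_len // u
            if n_rep >= min_rep:
                unit = seq[i : i + u]
                if is_primitive(unit):
                    loci.append(
                        SSRLocus(
                            pair_id=pair_id,
                            mate=mate,
                            start=i,
                            end=i + n_rep * u,
                            unit=unit,
                            canonical_unit=canonical_motif(unit),
                            n_repeats=n_rep,
                        )
                    )
            i = j + 1
    loci.sort(key=lambda l: (l.start, l.end, len(l.unit)))
    return loci


def classify_pair(
    pair: ReadPair, params: RepeatParams = RepeatParams()
) -> tuple[bool, list[SSRLocus], str | None]:
    """Detect repeats on both mates and assign the pair's motif class.

    Returns ``(is_ssr_positive, loci, motif_class)`` where ``motif_class``
    is the :data:`CLASS_NAMES` label of the dominant locus — greatest
    ``length_bp``, ties to larger unit length, then the earlier locus on
    mate 1 before mate 2 — or None for a negative pair.  Using a single
    class per pair makes class counts partition the positive-pair total.
    """
    loci = find_perfect_repeats(pair.seq1, params, pair.pair_id, mate=1)
    loci += find_perfect_repeats(pair.seq2, params, pair.pair_id, mate=2)
    if not loci:
        return False, [], None
    best = max(loci, key=lambda l: (l.length_bp, len(l.unit), -l.mate, -l.start))
    return True, loci, CLASS_NAMES[len(best.unit)]
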