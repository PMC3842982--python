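"""Primer-pair design on SSR-positive read pairs, and PAL classification.

For each SSR-positive pair, a forward primer is sought on mate 1 and a
reverse primer on mate 2.  Under the standard FR paired-end layout the mate-2
sequence as read already points back toward mate 1, so the reverse primer is
taken verbatim from the mate-2 read.  A pair for which a constraint-
satisfying primer pair exists is a *potentially amplifiable locus* (PAL).
Because the two primers sit in non-overlapping mates of an unsequenced
fragment, the amplicon length is unknown by construction.

The designer is self-contained and deterministic: candidate windows are
enumerated on each mate, filtered by length, melting temperature, GC content,
homopolymer runs, 3'-end self-complementarity, absence of N, and
non-overlap with every detected repeat locus on that mate, then the pair with
the minimal penalty

    |Tm_f - Tm_opt| + |Tm_r - Tm_opt| + |len_f - len_opt| + |len_r - len_opt|
        + |Tm_f - Tm_r|

is returned (ties to the leftmost forward window, then leftmost reverse).

Melting temperatures use unified nearest-neighbor thermodynamics
(SantaLucia, PNAS 1998) with a 0.368·N·ln[Na+] entropic salt correction and
total strand concentration C_T/4 for non-self-complementary duplexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .fastq_io import ReadPair
from .ssr_detect import SSRLocus, revcomp

__all__ = [
    "PrimerParams",
    "PrimerPair",
    "PALRecord",
    "melting_temperature",
    "gc_fraction",
    "design_primer_pair",
    "classify_pal",
]

# Unified nearest-neighbor parameters (SantaLucia 1998): dH kcal/mol, dS cal/(mol·K).
NN_DH = {
    "AA": -7.9, "TT": -7.9,
    "AT": -7.2,
    "TA": -7.2,
    "CA": -8.5, "TG": -8.5,
    "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8,
    "GA": -8.2, "TC": -8.2,
    "CG": -10.6,
    "GC": -9.8,
    "GG": -8.0, "CC": -8.0,
}
NN_DS = {
    "AA": -22.2, "TT": -22.2,
    "AT": -20.4,
    "TA": -21.3,
    "CA": -22.7, "TG": -22.7,
    "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0,
    "GA": -22.2, "TC": -22.2,
    "CG": -27.2,
    "GC": -24.4,
    "GG": -19.9, "CC": -19.9,
}
# Duplex initiation with a terminal G·C vs A·T pair.
INIT_DH = {"G": 0.1, "C": 0.1, "A": 2.3, "T": 2.3}
INIT_DS = {"G": -2.8, "C": -2.8, "A": 4.1, "T": 4.1}

R_GAS = 1.987  # cal/(mol·K)


def melting_temperature(
    seq: str, salt_mM: float = 50.0, primer_nM: float = 50.0
) -> float:
    """Nearest-neighbor duplex melting temperature in °C.

    Tm = 1000·ΔH / (ΔS + 0.368·(len-1)·ln[Na+] + R·ln(C_T/x)) − 273.15,
    with ΔH in kcal/mol, ΔS in cal/(mol·K), x = 4 (x = 1 and a −1.4 cal/(mol·K)
    symmetry term for self-complementary sequences).  Deterministic; the
    reverse complement of a sequence has the identical Tm.
    """
    if not 10 <= len(seq) <= 36:
        raise ValueError(f"primer length {len(seq)} outside 10..36")
    if any(c not in "ACGT" for c in seq):
        raise ValueError("Tm defined for ACGT sequences only")
    dh = INIT_DH[seq[0]] + INIT_DH[seq[-1]]
    ds = INIT_DS[seq[0]] + INIT_DS[seq[-1]]
    for i in range(len(seq) - 1):
        step = seq[i : i + 2]
        dh += NN_DH[step]
        ds += NN_DS[step]
    selfcomp = seq == revcomp(seq)
    if selfcomp:
        ds += -1.4
    ds += 0.368 * (len(seq) - 1) * math.log(salt_mM / 1000.0)
    ct = primer_nM * 1e-9
    x = 1.0 if selfcomp else 4.0
    return 1000.0 * dh / (ds + R_GAS * math.log(ct / x)) - 273.15


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


@dataclass(frozen=True)
class PrimerParams:
    """Primer3-style design constraints and the uniqueness-filter switch."""

    len_min: int = 18
    len_opt: int = 20
    len_max: int = 27
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    gc_min: float = 20.0
    gc_max: float = 80.0
    max_homopolymer_run: int = 4
    max_3prime_self_comp: int = 3
    salt_mM: float = 50.0
    require_ssr_one_mate_only: bool = False

    def __post_init__(self) -> None:
        if not (self.len_min <= self.len_opt <= self.len_max):
            raise ValueError("length bounds must satisfy min <= opt <= max")
        if not (self.tm_min <= self.tm_opt <= self.tm_max):
            raise ValueError("Tm bounds must satisfy min <= opt <= max")


@dataclass(frozen=True)
class PrimerPair:
    fwd_seq: str
    rev_seq: str
    fwd_span: tuple[int, int]
    rev_span: tuple[int, int]
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float
    penalty: float


@dataclass
class PALRecord:
    """An SSR-positive pair with its design outcome and uniqueness counts."""

    pair_id: str
    loci: list[SSRLocus]
    motif_class: str | None
    primer_pair: PrimerPair | None = None
    fwd_copies: int | None = None
    rev_copies: int | None = None
    is_ppal: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def is_pal(self) -> bool:
        return self.primer_pair is not None


_KMER_BITS = {c: i for i, c in enumerate("ACGT")}


def _kmer_code(kmer: str) -> int:
    code = 0
    for c in kmer:
        code = code * 4 + _KMER_BITS[c]
    return code


def window_passes(cand: str, params: PrimerParams) -> tuple[float, float] | None:
    """Check one window against the per-primer constraints.

    Returns (Tm, GC%) when the window is an acceptable primer on its own
    (composition, Tm, GC, homopolymer, 3' self-fold), else None.  The
    pairwise 3'-complementarity check happens at pair-assembly time.
    """
    if "N" in cand:
        return None
    gc = 100.0 * gc_fraction(cand)
    if not params.gc_min <= gc <= params.gc_max:
        return None
    if max_homopolymer(cand) > params.max_homopolymer_run:
        return None
    tm = melting_temperature(cand, params.salt_mM)
    if not params.tm_min <= tm <= params.tm_max:
        return None
    if revcomp(cand[-params.max_3prime_self_comp :]) in cand:
        return None  # 3' end folds back on the primer itself
    return tm, gc


def _candidate_windows(
    seq: str, loci: Sequence[SSRLocus], params: PrimerParams
) -> list[dict]:
    """Constraint-satisfying windows on one mate, ordered by (start, end).

    Each candidate carries its Tm, GC, penalty components, and a bitmask of
    the k-mers it contains (k = max_3prime_self_comp) for the pairwise
    3'-complementarity check.
    """
    n = len(seq)
    k = params.max_3prime_self_comp
    blocked = [(l.start, l.end) for l in loci]
    out = []
    for start in range(n - params.len_min + 1):
        for length in range(params.len_min, params.len_max + 1):
            end = start + length
            if end > n:
                break
            if any(start < be and bs < end for bs, be in blocked):
                continue
            cand = seq[start:end]
            checked = window_passes(cand, params)
            if checked is None:
                continue
            tm, gc = checked
            tail_rc = revcomp(cand[-k:])
            kmers = 0
            for i in range(len(cand) - k + 1):
                kmers |= 1 << _kmer_code(cand[i : i + k])
            out.append(
                {
                    "seq": cand,
                    "span": (start, end),
                    "tm": tm,
                    "gc": gc,
                    "pen": abs(tm - params.tm_opt) + abs(length - params.len_opt),
                    "kmers": kmers,
                    "tail_bit": 1 << _kmer_code(tail_rc),
                }
            )
    return out


def design_primer_pair(
    pair: ReadPair, loci: Sequence[SSRLocus], params: PrimerParams = PrimerParams()
) -> PrimerPair | None:
    """Best constraint-satisfying primer pair for one SSR-positive read pair.

    Returns None when no valid pair exists (a normal outcome on short
    flanks), or when ``require_ssr_one_mate_only`` is set and both mates
    carry repeat loci (the short-insert guard: a repeat visible in both
    mates signals an insert so short the amplicon is likely unsizeable).
    """
    mate1_loci = [l for l in loci if l.mate == 1]
    mate2_loci = [l for l in loci if l.mate == 2]
    if params.require_ssr_one_mate_only and mate1_loci and mate2_loci:
        return None
    fwd = _candidate_windows(pair.seq1, mate1_loci, params)
    rev = _candidate_windows(pair.seq2, mate2_loci, params)
    if not fwd or not rev:
        return None

    f_pen = np.array([c["pen"] for c in fwd])
    r_pen = np.array([c["pen"] for c in rev])
    f_tm = np.array([c["tm"] for c in fwd])
    r_tm = np.array([c["tm"] for c in rev])
    penalty = f_pen[:, None] + r_pen[None, :] + np.abs(f_tm[:, None] - r_tm[None, :])

    # Cross 3'-complementarity: the reverse complement of one primer's 3'
    # tail must not occur anywhere in the partner.  Few distinct tails exist,
    # so membership vectors are computed once per tail value.
    f_kmers = [c["kmers"] for c in fwd]
    r_kmers = [c["kmers"] for c in rev]
    rev_has: dict[int, np.ndarray] = {}
    fwd_has: dict[int, np.ndarray] = {}
    clash = np.zeros_like(penalty, dtype=bool)
    for i, c in enumerate(fwd):
        tail = c["tail_bit"]
        if tail not in rev_has:
            rev_has[tail] = np.fromiter(((rk & tail) != 0 for rk in r_kmers), bool)
        clash[i, :] |= rev_has[tail]
    for j, c in enumerate(rev):
        tail = c["tail_bit"]
        if tail not in fwd_has:
            fwd_has[tail] = np.fromiter(((fk & tail) != 0 for fk in f_kmers), bool)
        clash[:, j] |= fwd_has[tail]
    penalty = np.where(clash, np.inf, penalty)

    flat = int(np.argmin(penalty))  # row-major: leftmost fwd, then leftmost rev
    best = penalty.flat[flat]
    if not np.isfinite(best):
        return None
    fi, ri = divmod(flat, penalty.shape[1])
    f, r = fwd[fi], rev[ri]
    return PrimerPair(
        fwd_seq=f["seq"],
        rev_seq=r["seq"],
        fwd_span=f["span"],
        rev_span=r["span"],
        fwd_tm=round(f["tm"], 2),
        rev_tm=round(r["tm"], 2),
        fwd_gc=round(f["gc"], 2),
        rev_gc=round(r["gc"], 2),
        penalty=float(best),
    )


def classify_pal(records: Iterable[PALRecord]) -> dict:
    """Tallies over design outcomes: SSR-positive, PAL, and per-class counts."""
    n_pos = n_pal = 0
    by_class_pos: dict[str, int] = {}
    by_class_pal: dict[str, int] = {}
    for rec in records:
        n_pos += 1
        if rec.motif_class:
            by_class_pos[rec.motif_class] = by_class_pos.get(rec.motif_class, 0) + 1
        if rec.is_pal:
            n_pal += 1
            if rec.motif_class:
                by_class_pal[rec.motif_class] = (
                    by_class_pal.get(rec.motif_class, 0) + 1
                )
    return {
        "n_ssr_positive": n_pos,
        "n_pal": n_pal,
        "ssr_by_class": by_class_pos,
        "pal_by_class": by_class_pal,
    }
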