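"""Synthetic paired-end datasets with a ground-truth manifest.

The generator emulates the data regime of shotgun marker development:
100 bp paired-end reads sampled sparsely (well below 1x) from a large
genome, so that a single-copy genomic site is typically seen in one read
pair, while sites residing in repetitive elements are seen once per genomic
copy.  Concretely:

* A random background genome is generated and perfect SSRs are planted in
  dedicated contexts (repeat plus private flanks), each context copied to
  ``copy_number`` distinct genomic positions to model repeat-family loci.
* Each context copy is covered by a configurable number of anchored read
  pairs (default 1) whose mate 1 contains the repeat with a generous flank;
  the rest of the dataset is background pairs drawn from outside the
  contexts.  Keeping background reads off the contexts makes a primer's copy
  number reflect its genomic copy number rather than Poisson coverage noise,
  which is the sparse-coverage behaviour the uniqueness filter relies on.
* Reads follow the FR layout (mate 1 = fragment 5' end, forward strand;
  mate 2 = fragment 3' end, reverse complement), with Gaussian insert sizes.
* Qualities are two-state: high-quality bases with optional Illumina
  1.5-style trailing "B-tails" (runs of Q2) of random length; substitution
  errors are applied at ``base_error_rate``.

Everything is deterministic given the seed; identical parameters produce
byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .fastq_io import ReadPair
from .primer_design import PALRecord, PrimerParams, window_passes
from .ssr_detect import RepeatParams, find_perfect_repeats, revcomp

__all__ = [
    "SimParams",
    "PlantedLocus",
    "ReadTruth",
    "TruthManifest",
    "simulate_genome",
    "simulate_reads",
    "simulate_dataset",
    "score_recovery",
]

#: One canonical motif per unit length, cycled over planted loci by default.
DEFAULT_MOTIF_POOL = ("AC", "AG", "ATG", "AAG", "AGAT", "AAAC", "AATAG", "AATCAG")

DEFAULT_REPEAT_RANGE = {2: (8, 14), 3: (5, 9), 4: (4, 7), 5: (4, 6), 6: (4, 5)}


@dataclass(frozen=True)
class SimParams:
    """Study-condition knobs for the generator.

    The defaults emulate the validated data shape: 100 bp paired-end reads,
    ~180 bp inserts, Q38 base calls, sparse single-pass coverage of planted
    loci.  ``copy_number_spec`` maps locus index -> genomic copies (default 1
    for every locus), creating non-unique primer contexts on demand.
    """

    seed: int = 0
    genome_len: int = 1_000_000
    n_loci: int = 20
    motif_pool: tuple[str, ...] = DEFAULT_MOTIF_POOL
    repeat_count_range: dict[int, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REPEAT_RANGE)
    )
    copy_number_spec: dict[int, int] = field(default_factory=dict)
    read_len: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    n_pairs: int = 10_000
    coverage_per_locus: int = 1
    btail_prob: float = 0.0
    btail_maxlen: int = 40
    base_error_rate: float = 0.0
    base_quality: int = 38
    gc_content: float = 0.5
    context_len: int = 560
    flank_in_read: tuple[int, int] = (30, 55)

    def __post_init__(self) -> None:
        if self.read_len > self.insert_mean:
            raise ValueError("read_len must not exceed insert_mean")
        if self.context_len < 2 * self.read_len + 60:
            raise ValueError(
                "context_len too small to host a fragment with disjoint mates"
            )
        total_copies = sum(
            self.copy_number_spec.get(i, 1) for i in range(self.n_loci)
        )
        needed = total_copies * (self.context_len + 2 * self.read_len)
        if self.genome_len < needed:
            raise ValueError(
                f"genome_len {self.genome_len} cannot host {total_copies} "
                f"contexts with 2x read-length spacing (need >= {needed})"
            )


@dataclass(frozen=True)
class PlantedLocus:
    """Ground truth for one planted SSR (all its genomic copies)."""

    locus_id: str
    motif: str
    n_repeats: int
    copy_number: int
    context_positions: tuple[int, ...]  # genome offset of each context copy
    repeat_offset: int  # repeat start within the context
    left_flank: str
    right_flank: str

    @property
    def repeat_len(self) -> int:
        return self.n_repeats * len(self.motif)


@dataclass(frozen=True)
class ReadTruth:
    """Provenance of one simulated pair."""

    pair_id: str
    frag_start: int
    insert: int
    locus_id: str | None  # None for background pairs
    copy_index: int | None
    btail1: int
    btail2: int
    n_errors: int


@dataclass
class TruthManifest:
    loci: list[PlantedLocus]
    reads: list[ReadTruth] = field(default_factory=list)

    def locus(self, locus_id: str) -> PlantedLocus:
        return next(l for l in self.loci if l.locus_id == locus_id)


_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Constraint set used to certify planted contexts as amplifiable.
_DESIGN_CHECK = PrimerParams()

_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _has_fwd_window(flank_tail: str, check: PrimerParams) -> bool:
    """Any acceptable primer window wholly inside the flank tail?"""
    n = len(flank_tail)
    for a in range(n - check.len_min + 1):
        for length in range(check.len_min, check.len_max + 1):
            if a + length > n:
                break
            if window_passes(flank_tail[a : a + length], check) is not None:
                return True
    return False


def _rev_windows_dense(
    context: str, rep_offset: int, rep_len: int, params: SimParams,
    check: PrimerParams,
) -> bool:
    """Every possible mate-2 placement must contain a reverse-primer window.

    Mate 2 is the reverse complement of a 100 bp slice whose start ranges
    from just past the repeat (shortest fragment, deepest flank) to the end
    of the context; acceptable windows (on the reverse strand) must leave no
    100 bp slice without one.
    """
    rl = params.read_len
    lo_m = rep_offset - params.flank_in_read[1] + (rl + 10)
    lo_m = max(lo_m, rep_offset + rep_len)
    hi_m = params.context_len - rl
    if hi_m < lo_m:
        return False
    covered = np.zeros(hi_m - lo_m + 1, dtype=bool)
    for a in range(lo_m, params.context_len - check.len_min + 1):
        for length in range(check.len_min, check.len_max + 1):
            b = a + length
            if b > params.context_len:
                break
            if window_passes(revcomp(context[a:b]), check) is None:
                continue
            # this window serves every mate-2 start m with m <= a, b <= m+rl
            mlo, mhi = max(b - rl, lo_m), min(a, hi_m)
            if mlo <= mhi:
                covered[mlo - lo_m : mhi - lo_m + 1] = True
            break
        if covered.all():
            return True
    return bool(covered.all())


def _build_context_flanks(
    rng: np.random.Generator, params: SimParams, motif: str, n_rep: int
) -> tuple[str, str, int]:
    """Draw flanks for one planted repeat until the context is certified.

    Certification: the context contains exactly the planted repeat and no
    chance SSR; the 30 bp of flank immediately 5' of the repeat admit a
    forward primer; reverse-primer windows are dense enough downstream that
    any fragment geometry leaves mate 2 with a valid window.  This is what
    "clean, amplifiable flanks" means as ground truth — a planted locus is
    guaranteed recoverable when sequenced without artifacts.
    """
    rep = motif * n_rep
    flank_total = params.context_len - len(rep)
    left_len = flank_total // 2
    right_len = flank_total - left_len
    rparams = RepeatParams()
    for _ in range(500):
        left = list(_random_dna(rng, left_len, params.gc_content))
        right = list(_random_dna(rng, right_len, params.gc_content))
        # break the repeat period at both boundaries so the planted run is
        # maximal exactly as recorded
        if left and left[-1] == motif[-1]:
            left[-1] = _TRANSVERSION[motif[-1]]
        if right and right[0] == motif[0]:
            right[0] = _TRANSVERSION[motif[0]]
        left_s, right_s = "".join(left), "".join(right)
        context = left_s + rep + right_s
        found = find_perfect_repeats(context, rparams)
        if len(found) != 1:
            continue
        f = found[0]
        if not (f.start == left_len and f.end == left_len + len(rep)):
            continue
        if not _has_fwd_window(left_s[-30:], _DESIGN_CHECK):
            continue
        if not _rev_windows_dense(
            context, left_len, len(rep), params, _DESIGN_CHECK
        ):
            continue
        return left_s, right_s, left_len
    raise ValueError(
        f"could not certify an amplifiable context for motif {motif} x {n_rep}; "
        "loosen the design constraints or enlarge context_len"
    )


def simulate_genome(params: SimParams) -> tuple[str, TruthManifest]:
    """Random background genome with planted perfect-repeat contexts.

    Each locus context is (left flank | repeat | right flank) with the flank
    bases adjacent to the repeat forced to break the repeat period, so the
    planted run is exactly maximal with the recorded coordinates and repeat
    count.  A locus with copy number k has its whole context written to k
    well-separated genomic positions.
    """
    rng = np.random.default_rng(params.seed)
    genome = np.frombuffer(
        _random_dna(rng, params.genome_len, params.gc_content).encode(), dtype="S1"
    ).copy()

    total_copies = sum(params.copy_number_spec.get(i, 1) for i in range(params.n_loci))
    # lay contexts on an evenly spaced grid with >= 2*read_len guard gaps
    slot = params.context_len + 2 * params.read_len
    n_slots = params.genome_len // slot
    slot_ids = rng.choice(n_slots, size=total_copies, replace=False)

    loci: list[PlantedLocus] = []
    copy_cursor = 0
    for i in range(params.n_loci):
        motif = params.motif_pool[i % len(params.motif_pool)]
        lo, hi = params.repeat_count_range[len(motif)]
        n_rep = int(rng.integers(lo, hi + 1))
        rep = motif * n_rep
        left_s, right_s, left_len = _build_context_flanks(
            rng, params, motif, n_rep
        )
        context = left_s + rep + right_s
        k = params.copy_number_spec.get(i, 1)
        positions = []
        for _ in range(k):
            pos = int(slot_ids[copy_cursor]) * slot + params.read_len
            copy_cursor += 1
            genome[pos : pos + len(context)] = np.frombuffer(
                context.encode(), dtype="S1"
            )
            positions.append(pos)
        loci.append(
            PlantedLocus(
                locus_id=f"locus{i:04d}",
                motif=motif,
                n_repeats=n_rep,
                copy_number=k,
                context_positions=tuple(positions),
                repeat_offset=left_len,
                left_flank=left_s,
                right_flank=right_s,
            )
        )
    return genome.tobytes().decode(), TruthManifest(loci=loci)


def _context_intervals(manifest: TruthManifest, context_len: int) -> list[tuple[int, int]]:
    iv = []
    for loc in manifest.loci:
        for pos in loc.context_positions:
            iv.append((pos, pos + context_len))
    iv.sort()
    return iv


def simulate_reads(
    genome: str, params: SimParams, manifest: TruthManifest
) -> list[ReadPair]:
    """Draw anchored and background read pairs; record per-read truth.

    Anchored pairs (``coverage_per_locus`` per context copy) place the
    planted repeat inside mate 1 with a clean left flank drawn from
    ``flank_in_read``; the whole fragment stays inside the context so that
    multi-copy loci yield identical fragments up to insert jitter.
    Background pairs are drawn uniformly from outside every context.
    Truth records are appended to ``manifest.reads``.
    """
    rng = np.random.default_rng(params.seed + 1)
    pairs: list[ReadPair] = []
    rl = params.read_len

    def _quals_and_tail(seq: str) -> tuple[str, list[int], int]:
        qual = [params.base_quality] * len(seq)
        tail = 0
        if params.btail_prob > 0 and rng.random() < params.btail_prob:
            tail = int(rng.integers(1, params.btail_maxlen + 1))
            tail = min(tail, len(seq))
            for j in range(len(seq) - tail, len(seq)):
                qual[j] = 2
        return seq, qual, tail

    def _with_errors(seq: str) -> tuple[str, int]:
        if params.base_error_rate <= 0:
            return seq, 0
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        hits = np.nonzero(rng.random(len(arr)) < params.base_error_rate)[0]
        for j in hits:
            cur = arr[j]
            choices = [b for b in b"ACGT" if bytes([b]) != cur]
            arr[j] = bytes([choices[int(rng.integers(3))]])
        return arr.tobytes().decode(), len(hits)

    def _emit(pair_id: str, frag_start: int, insert: int,
              locus_id: str | None, copy_index: int | None) -> None:
        frag_end = frag_start + insert
        m1 = genome[frag_start : frag_start + rl]
        m2 = revcomp(genome[frag_end - rl : frag_end])
        m1, e1 = _with_errors(m1)
        m2, e2 = _with_errors(m2)
        m1, q1, t1 = _quals_and_tail(m1)
        m2, q2, t2 = _quals_and_tail(m2)
        pairs.append(ReadPair(pair_id, m1, q1, m2, q2))
        manifest.reads.append(
            ReadTruth(pair_id, frag_start, insert, locus_id, copy_index,
                      t1, t2, e1 + e2)
        )

    # Anchored pairs: `coverage_per_locus` fragment layouts per locus, each
    # layout replayed identically at every genomic copy so that a k-copy
    # locus yields k occurrences of every primer-sized subsequence.
    n_anchored = 0
    for loc in manifest.loci:
        rep_in_ctx = loc.repeat_offset
        for cov in range(params.coverage_per_locus):
            fl_lo, fl_hi = params.flank_in_read
            fl_hi = min(fl_hi, rl - loc.repeat_len - 1)
            fl_lo = min(fl_lo, fl_hi)
            flank = int(rng.integers(fl_lo, fl_hi + 1))
            off = rep_in_ctx - flank  # fragment start within the context
            insert = int(round(rng.normal(params.insert_mean, params.insert_sd)))
            # keep the fragment inside the context and the mates disjoint
            # (overlapping mates would double-count every primer they share)
            lo = max(2 * rl + 10, rep_in_ctx + loc.repeat_len - off + 8)
            hi = params.context_len - off
            insert = max(lo, min(insert, hi))
            for ci, ctx_pos in enumerate(loc.context_positions):
                pid = f"{loc.locus_id}:{ci}:{cov}"
                _emit(pid, ctx_pos + off, insert, loc.locus_id, ci)
                n_anchored += 1

    # background pairs, rejected out of every context interval
    intervals = _context_intervals(manifest, params.context_len)
    starts = np.array([s for s, _ in intervals])
    ends = np.array([e for _, e in intervals])
    n_bg = max(0, params.n_pairs - n_anchored)
    made = 0
    while made < n_bg:
        insert = int(round(rng.normal(params.insert_mean, params.insert_sd)))
        insert = max(rl, min(insert, 4 * rl))
        f = int(rng.integers(0, params.genome_len - insert))
        # overlap test against context intervals
        j = int(np.searchsorted(ends, f, side="right"))
        if j < len(starts) and starts[j] < f + insert:
            continue
        _emit(f"bg{made:07d}", f, insert, None, None)
        made += 1
    return pairs


def simulate_dataset(params: SimParams) -> tuple[list[ReadPair], TruthManifest, str]:
    """Genome + reads in one call; returns (pairs, manifest, genome)."""
    genome, manifest = simulate_genome(params)
    pairs = simulate_reads(genome, params, manifest)
    return pairs, manifest, genome


def score_recovery(
    records: Iterable[PALRecord],
    manifest: TruthManifest,
    qc_passed_ids: set[str] | None = None,
) -> dict:
    """Compare pipeline output against the planted truth.

    A locus is *covered* if at least one of its anchored pairs survived QC
    (all anchored pairs, if ``qc_passed_ids`` is not given).  Recall figures
    are over covered single-copy loci; multi-copy loci are scored separately
    for pPAL specificity (their primers repeat in the genome, so they must
    not be called premium).
    """
    records = list(records)
    by_pair: dict[str, PALRecord] = {r.pair_id: r for r in records}
    truth_by_pair: dict[str, ReadTruth] = {rt.pair_id: rt for rt in manifest.reads}
    anchored: dict[str, list[str]] = {l.locus_id: [] for l in manifest.loci}
    for rt in manifest.reads:
        if rt.locus_id is not None:
            anchored[rt.locus_id].append(rt.pair_id)

    n_cov = n_ssr = n_pal = n_ppal = 0
    n_multi = n_multi_ppal = 0
    for loc in manifest.loci:
        pids = anchored[loc.locus_id]
        if qc_passed_ids is not None:
            pids = [p for p in pids if p in qc_passed_ids]
        if not pids:
            continue
        recs = [by_pair[p] for p in pids if p in by_pair]
        if loc.copy_number == 1:
            n_cov += 1
            if recs:
                n_ssr += 1
            if any(r.is_pal for r in recs):
                n_pal += 1
            if any(r.is_ppal for r in recs):
                n_ppal += 1
        else:
            n_multi += 1
            if any(r.is_ppal for r in recs):
                n_multi_ppal += 1
    # true amplicon sizes: the fragment is known, so the distance from the
    # forward primer's 5' end to the reverse primer's 5' end is exact —
    # ground truth for the quantity the assay itself cannot predict
    amplicons = [
        truth_by_pair[r.pair_id].insert
        - r.primer_pair.fwd_span[0]
        - r.primer_pair.rev_span[0]
        for r in records
        if r.is_pal and r.pair_id in truth_by_pair
    ]
    return {
        "n_loci_covered": n_cov,
        "ssr_recall": n_ssr / n_cov if n_cov else float("nan"),
        "pal_recall": n_pal / n_cov if n_cov else float("nan"),
        "ppal_recall": n_ppal / n_cov if n_cov else float("nan"),
        "n_multicopy_covered": n_multi,
        "multicopy_ppal_calls": n_multi_ppal,
        "amplicon_bp": {
            "n": len(amplicons),
            "mean": sum(amplicons) / len(amplicons) if amplicons else float("nan"),
            "min": min(amplicons, default=None),
            "max": max(amplicons, default=None),
        },
    }
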