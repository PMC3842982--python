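"""Perfect-repeat detection: canonical motifs, maximal runs, pair classes."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipemsat.fastq_io import ReadPair
from ipemsat.ssr_detect import (
    RepeatParams,
    canonical_motif,
    classify_pair,
    find_perfect_repeats,
    is_primitive,
    revcomp,
)


# ---------------------------------------------------------------- oracle ---
def _primitive(unit):
    return all(
        unit != unit[:d] * (len(unit) // d)
        for d in range(1, len(unit))
        if len(unit) % d == 0
    )


def brute_force_repeats(seq, min_by_unit):
    """Independent enumeration of maximal perfect primitive repeat runs.

    For every (start, unit-length), extend by whole units as far as possible;
    keep runs meeting the minimum count that cannot be extended by a full
    unit on the left; then collapse rotated re-anchorings of the same tandem
    region (same unit length, span overlap >= unit length) onto the leftmost.
    """
    cands = []
    for u, min_rep in min_by_unit.items():
        for start in range(len(seq) - u + 1):
            unit = seq[start : start + u]
            if "N" in unit or len(unit) < u or not _primitive(unit):
                continue
            n = 0
            while seq[start + n * u : start + (n + 1) * u] == unit:
                n += 1
            if n < min_rep:
                continue
            if start - u >= 0 and seq[start - u : start] == unit:
                continue  # left-extendable: not the leftmost anchoring
            cands.append((start, start + n * u, unit, n))
    kept = []
    for c in sorted(cands, key=lambda c: (c[0], c[1])):
        s, e, unit, n = c
        u = len(unit)
        if any(
            len(ku) == u and min(e, ke) - max(s, ks) >= u
            for ks, ke, ku, kn in kept
        ):
            continue
        kept.append(c)
    return {(s, e, unit, n) for s, e, unit, n in kept}


def _as_tuples(loci):
    return {(l.start, l.end, l.unit, l.n_repeats) for l in loci}


# ---------------------------------------------------------------- motifs ---
class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "unit,expected",
        [("GT", "AC"), ("AC", "AC"), ("GAT", "ATC"), ("TG", "AC"),
         ("AGAT", "AGAT"), ("TCTA", "AGAT")],
    )
    def test_examples(self, unit, expected):
        assert canonical_motif(unit) == expected

    @pytest.mark.parametrize("bad", ["ACAC", "AA", "A", "ANC"])
    def test_rejects_non_primitive_or_invalid(self, bad):
        with pytest.raises(ValueError):
            canonical_motif(bad)

    @given(st.text(alphabet="ACGT", min_size=2, max_size=6))
    @settings(max_examples=300, deadline=None)
    def test_invariant_under_rotation_and_revcomp(self, unit):
        if not is_primitive(unit):
            return
        canon = canonical_motif(unit)
        for k in range(len(unit)):
            rot = unit[k:] + unit[:k]
            assert canonical_motif(rot) == canon
            assert canonical_motif(revcomp(rot)) == canon


# ------------------------------------------------------------- detection ---
class TestFindPerfectRepeats:
    def test_simple_dinucleotide_run(self):
        (locus,) = find_perfect_repeats("ACACACACACAC")
        assert (locus.start, locus.end, locus.unit, locus.n_repeats) == (
            0, 12, "AC", 6,
        )
        assert locus.canonical_unit == "AC"

    def test_homopolymer_is_not_an_ssr(self):
        assert find_perfect_repeats("A" * 30) == []

    def test_trinucleotide_with_flanks(self):
        (locus,) = find_perfect_repeats("TTATGATGATGATGCC")
        assert (locus.start, locus.end, locus.unit, locus.n_repeats) == (
            2, 14, "ATG", 4,
        )

    def test_n_breaks_a_run(self):
        assert find_perfect_repeats("ACACACNACACAC") == []

    def test_below_minimum_count_not_reported(self):
        assert find_perfect_repeats("ACACACACAC") == []  # AC x5 < 6

    def test_run_not_rereported_as_its_own_multiple(self):
        loci = find_perfect_repeats("ACACACACACACACAC")  # AC x8
        assert len(loci) == 1 and loci[0].unit == "AC"

    def test_custom_minimums(self):
        params = RepeatParams(min_repeats_by_unit={2: 5})
        (locus,) = find_perfect_repeats("ACACACACAC", params)
        assert locus.n_repeats == 5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_repeat_rich_strings(self, seed):
        rng = random.Random(seed)
        params = RepeatParams()
        for _ in range(40):
            n = rng.randint(10, 150)
            s = "".join(rng.choice("ACGT") for _ in range(n))
            # plant a repeat to make hits common
            unit = rng.choice(["AC", "AT", "ATG", "AAG", "AGAT", "AATAG"])
            rep = unit * rng.randint(3, 8)
            pos = rng.randint(0, max(0, len(s) - len(rep)))
            s = s[:pos] + rep + s[pos + len(rep):]
            expected = brute_force_repeats(s, params.min_repeats_by_unit)
            assert _as_tuples(find_perfect_repeats(s, params)) == expected

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=60))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_on_small_alphabet_noise(self, s):
        params = RepeatParams(min_repeats_by_unit={2: 3, 3: 2, 4: 2, 5: 2, 6: 2})
        assert _as_tuples(find_perfect_repeats(s, params)) == brute_force_repeats(
            s, params.min_repeats_by_unit
        )

    def test_revcomp_mirrors_loci(self):
        s = "TTATGATGATGATGCCGGACACACACACACACGG"
        fwd = find_perfect_repeats(s)
        rev = find_perfect_repeats(revcomp(s))
        assert len(fwd) == len(rev)
        mirrored = {
            (len(s) - l.end, len(s) - l.start, l.canonical_unit, l.n_repeats)
            for l in rev
        }
        assert mirrored == {
            (l.start, l.end, l.canonical_unit, l.n_repeats) for l in fwd
        }


# ------------------------------------------------------------ pair class ---
def _pair(seq1, seq2):
    return ReadPair("p", seq1, [40] * len(seq1), seq2, [40] * len(seq2))


class TestClassifyPair:
    def test_longest_run_sets_the_class(self):
        pair = _pair("GG" + "AC" * 8 + "GG", "TT" + "ATG" * 4 + "TT")
        positive, loci, cls = classify_pair(pair)
        assert positive and cls == "2mer"  # 16 bp beats 12 bp
        assert len(loci) == 2

    def test_tie_broken_by_larger_unit(self):
        pair = _pair("G" + "AC" * 6 + "G", "T" + "AGAT" * 3 + "T")
        # AGAT x3 is below the 4-mer minimum: only the AC locus exists
        positive, loci, cls = classify_pair(pair)
        assert positive and cls == "2mer" and len(loci) == 1

    def test_equal_length_prefers_larger_unit(self):
        params = RepeatParams(min_repeats_by_unit={2: 6, 3: 4})
        pair = _pair("G" + "AC" * 6 + "G", "T" + "ATG" * 4 + "TT")
        positive, loci, cls = classify_pair(pair, params)
        assert cls == "3mer"  # both 12 bp, trinucleotide wins

    def test_negative_pair(self):
        # repeat-free 100 bp sequences (verified against the brute-force oracle)
        s1 = ("TGGCTAGTGTCACTGCGCACAGTAAACATTATCGCACATTTTTAACGGGTGAGC"
              "GGGCATTAACTATCACCAGATGTGATGCGGTTTCCTGCCCAGGCCA")
        s2 = ("ACAGCAGGACTTGGTCTGAGGTCGGAAACGTCCCTTAGATTATCGGTCACAAAT"
              "CTAGCGGTACTCATGGAGCAGGCTGCACTTTCAGTCGACAGGGCTG")
        assert brute_force_repeats(s1, RepeatParams().min_repeats_by_unit) == set()
        positive, loci, cls = classify_pair(_pair(s1, s2))
        assert not positive and loci == [] and cls is None

    def test_class_counts_partition_positive_pairs(self, small_sim):
        _, _, _, _, result = small_sim
        by_class = {}
        for rec in result.records:
            by_class[rec.motif_class] = by_class.get(rec.motif_class, 0) + 1
        assert sum(by_class.values()) == result.summary.n_ssr_pairs
        assert None not in by_class
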