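"""Nearest-neighbor Tm, design constraints, and PAL classification."""

import random

import pytest
from Bio.SeqUtils import MeltingTemp as mt

from ipemsat.fastq_io import ReadPair
from ipemsat.primer_design import (
    PALRecord,
    PrimerParams,
    classify_pal,
    design_primer_pair,
    gc_fraction,
    max_homopolymer,
    melting_temperature,
)
from ipemsat.ssr_detect import classify_pair, find_perfect_repeats, revcomp

# Unified nearest-neighbor table, re-keyed by duplex step for an independent
# hand-summed check (dH kcal/mol, dS cal/mol/K; SantaLucia's unified set).
_ORACLE = {
    "AA/TT": (-7.9, -22.2), "AT/AT": (-7.2, -20.4), "TA/TA": (-7.2, -21.3),
    "CA/GT": (-8.5, -22.7), "GT/CA": (-8.4, -22.4), "CT/GA": (-7.8, -21.0),
    "GA/CT": (-8.2, -22.2), "CG/CG": (-10.6, -27.2), "GC/GC": (-9.8, -24.4),
    "GG/CC": (-8.0, -19.9),
}
_STEP_KEY = {
    "AA": "AA/TT", "TT": "AA/TT", "AT": "AT/AT", "TA": "TA/TA",
    "CA": "CA/GT", "TG": "CA/GT", "GT": "GT/CA", "AC": "GT/CA",
    "CT": "CT/GA", "AG": "CT/GA", "GA": "GA/CT", "TC": "GA/CT",
    "CG": "CG/CG", "GC": "GC/GC", "GG": "GG/CC", "CC": "GG/CC",
}


def oracle_tm(seq, salt_mM=50.0, ct_nM=50.0):
    import math

    dh = ds = 0.0
    for i in range(len(seq) - 1):
        h, s = _ORACLE[_STEP_KEY[seq[i : i + 2]]]
        dh += h
        ds += s
    for term in (seq[0], seq[-1]):
        dh += 0.1 if term in "GC" else 2.3
        ds += -2.8 if term in "GC" else 4.1
    selfcomp = seq == revcomp(seq)
    if selfcomp:
        ds -= 1.4
    ds += 0.368 * (len(seq) - 1) * math.log(salt_mM / 1000.0)
    x = 1.0 if selfcomp else 4.0
    return 1000.0 * dh / (ds + 1.987 * math.log(ct_nM * 1e-9 / x)) - 273.15


class TestMeltingTemperature:
    def test_frozen_hand_summed_values(self):
        # values frozen from the hand-summed oracle above
        assert melting_temperature("ACGTACGTACGTACGTACGT") == pytest.approx(
            oracle_tm("ACGTACGTACGTACGTACGT"), abs=0.1
        )
        assert melting_temperature("AGCTTGCATGCAAGGTCCAT") == pytest.approx(
            54.70, abs=0.1
        )

    def test_matches_reference_nn_implementation(self):
        rng = random.Random(7)
        checked = 0
        while checked < 100:
            n = rng.randint(15, 27)
            s = "".join(rng.choice("ACGT") for _ in range(n))
            if s == revcomp(s):
                continue  # reference uses a different self-complementary convention
            ref = mt.Tm_NN(s, nn_table=mt.DNA_NN3, Na=50, dnac1=25, dnac2=25,
                           saltcorr=5)
            assert melting_temperature(s) == pytest.approx(ref, abs=0.1)
            checked += 1

    def test_reverse_complement_symmetry(self):
        rng = random.Random(3)
        for _ in range(50):
            s = "".join(rng.choice("ACGT") for _ in range(20))
            assert melting_temperature(s) == pytest.approx(
                melting_temperature(revcomp(s)), abs=1e-9
            )

    def test_salt_monotonicity(self):
        s = "AGCTTGCATGCAAGGTCCAT"
        tms = [melting_temperature(s, salt_mM=c) for c in (10, 50, 100, 500)]
        assert tms == sorted(tms) and len(set(tms)) == 4

    @pytest.mark.parametrize("bad", ["ACGT", "A" * 40, "ACGTACGTACGTACGTACGN"])
    def test_rejects_out_of_contract_sequences(self, bad):
        with pytest.raises(ValueError):
            melting_temperature(bad)


def _balanced_flank(rng, n):
    # alternating-ish composition keeps Tm of 20-mers near 60C
    return "".join(rng.choice(["A", "C", "G", "T"]) for _ in range(n))


def _designable_pair(seed=0):
    """A synthetic SSR-positive pair with generous balanced flanks."""
    rng = random.Random(seed)
    for _ in range(100):
        flank_l = _balanced_flank(rng, 60)
        flank_r = _balanced_flank(rng, 60 - 16)
        seq1 = flank_l + "AC" * 8 + flank_r[: 100 - 60 - 16]
        seq2 = _balanced_flank(rng, 100)
        pair = ReadPair("d", seq1, [40] * 100, seq2, [40] * 100)
        positive, loci, _ = classify_pair(pair)
        if positive and design_primer_pair(pair, loci) is not None:
            return pair, loci
    raise AssertionError("could not build a designable pair")


class TestDesignPrimerPair:
    def test_no_room_for_forward_primer_returns_none(self):
        seq1 = "ACGTACGTACGT" + "AC" * 6  # 12 bp flank only
        seq2 = "ACGT" * 25
        pair = ReadPair("p", seq1, [40] * len(seq1), seq2, [40] * 100)
        positive, loci, _ = classify_pair(pair)
        assert positive
        assert design_primer_pair(pair, loci) is None

    def test_returned_primers_satisfy_every_bound(self):
        params = PrimerParams()
        pair, loci = _designable_pair(seed=2)
        pp = design_primer_pair(pair, loci, params)
        for seq, span, mate_seq, tm, gc in (
            (pp.fwd_seq, pp.fwd_span, pair.seq1, pp.fwd_tm, pp.fwd_gc),
            (pp.rev_seq, pp.rev_span, pair.seq2, pp.rev_tm, pp.rev_gc),
        ):
            assert mate_seq[span[0] : span[1]] == seq
            assert params.len_min <= len(seq) <= params.len_max
            assert params.tm_min <= tm <= params.tm_max
            assert params.gc_min <= gc <= params.gc_max
            assert "N" not in seq
            assert max_homopolymer(seq) <= params.max_homopolymer_run
            assert melting_temperature(seq) == pytest.approx(tm, abs=0.01)
            assert 100.0 * gc_fraction(seq) == pytest.approx(gc, abs=0.01)
        # primers avoid every repeat locus on their own mate
        for l in loci:
            span = pp.fwd_span if l.mate == 1 else pp.rev_span
            assert span[1] <= l.start or span[0] >= l.end
        # penalty recomputes from its definition
        expected = (
            abs(pp.fwd_tm - params.tm_opt)
            + abs(pp.rev_tm - params.tm_opt)
            + abs(len(pp.fwd_seq) - params.len_opt)
            + abs(len(pp.rev_seq) - params.len_opt)
            + abs(pp.fwd_tm - pp.rev_tm)
        )
        assert pp.penalty == pytest.approx(expected, abs=0.05)

    def test_one_mate_only_filter_rejects_double_ssr_pairs(self):
        rng = random.Random(5)
        seq1 = _balanced_flank(rng, 50) + "AC" * 8 + _balanced_flank(rng, 34)
        seq2 = _balanced_flank(rng, 50) + "ATG" * 5 + _balanced_flank(rng, 35)
        pair = ReadPair("p", seq1, [40] * 100, seq2, [40] * 100)
        positive, loci, _ = classify_pair(pair)
        assert {l.mate for l in loci} == {1, 2}
        on = PrimerParams(require_ssr_one_mate_only=True)
        assert design_primer_pair(pair, loci, on) is None
        assert design_primer_pair(pair, loci, PrimerParams()) is not None

    def test_relaxing_bounds_never_loses_pals(self, small_sim):
        params, pairs, manifest, genome, result = small_sim
        strict = PrimerParams()
        loose = PrimerParams(tm_min=52.0, tm_max=68.0, gc_min=10.0, gc_max=90.0,
                             len_min=17, len_opt=20, len_max=28)
        from ipemsat.read_qc import QCParams, run_qc

        qcd = list(run_qc(pairs, QCParams()))
        n_strict = n_loose = 0
        for p in qcd:
            positive, loci, _ = classify_pair(p)
            if not positive:
                continue
            if design_primer_pair(p, loci, strict):
                n_strict += 1
            if design_primer_pair(p, loci, loose):
                n_loose += 1
        assert n_loose >= n_strict > 0


class TestClassifyPal:
    def test_counts(self):
        from ipemsat.primer_design import PrimerPair

        dummy = PrimerPair("ACGTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA",
                           (0, 20), (0, 20), 60.0, 60.0, 50.0, 50.0, 0.0)
        recs = []
        for i in range(10):
            rec = PALRecord(pair_id=f"p{i}", loci=[], motif_class="2mer")
            if i < 3:
                rec.primer_pair = dummy
            recs.append(rec)
        out = classify_pal(recs)
        assert out["n_ssr_positive"] == 10
        assert out["n_pal"] == 3
        assert out["ssr_by_class"] == {"2mer": 10}

    def test_empty(self):
        out = classify_pal([])
        assert out["n_pal"] == out["n_ssr_positive"] == 0
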