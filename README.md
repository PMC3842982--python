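# ipemsat

Microsatellite marker development from Illumina paired-end (IPE) shotgun
reads: quality control, perfect-repeat detection, cross-mate primer design,
and a primer-uniqueness filter — with a seeded simulator so every stage is
verifiable without external data.

## The problem

Microsatellites (simple sequence repeats, SSRs) remain a workhorse genetic
marker in ecology, conservation and population genetics, but developing new
species-specific loci by enrichment + cloning + Sanger sequencing is slow and
expensive. A far cheaper route is to shotgun-sequence a genome shallowly with
100 bp paired-end reads and mine the reads directly:

1. **QC** — trim the trailing low-quality run of each read (the "B-tail":
   the maximal 3' suffix with quality < Q15), drop pairs in which either
   trimmed mate is < 50 bp, and cap the dataset at 5 million QC-passed pairs.
2. **SSR detection** — find every *perfect* tandem repeat of a *primitive*
   2–6 bp unit (di- through hexanucleotide; homopolymers excluded) that is
   *maximal* and meets a per-unit-length minimum repeat count. Motifs are
   grouped by canonical class (lexicographic minimum over cyclic rotations
   and the reverse complement, so AC/CA/GT/TG are one class).
3. **Primer design** — for each SSR-positive pair, place a forward primer in
   mate 1 and a reverse primer in mate 2 (which, in FR layout, already points
   back toward mate 1) under Primer3-style constraints on length, melting
   temperature (nearest-neighbor thermodynamics), GC content, homopolymer
   runs and 3' self-complementarity, never overlapping a detected repeat.
   A pair with a valid design is a **PAL** — a potentially amplifiable locus.
4. **Uniqueness filter** — count each primer's exact occurrences (either
   strand, overlaps included) across *all* reads with one streaming
   multi-pattern pass. A PAL whose forward and reverse primers each occur
   exactly once is a **pPAL** (premium PAL): its primers are very unlikely to
   sit in a repetitive element, the classic cause of multi-locus
   amplification that makes markers unscorable.
5. **Summaries** — per-dataset table rows (totals and per-motif-class
   counts) and cross-dataset aggregates: means, ranges, mean per-species
   PAL/SSR and pPAL/PAL proportions, and counts of species clearing pPAL
   yield thresholds.

The package also ships a verbatim transcription of a published 32-species
development table set, so the headline cross-species statistics can be
recomputed from data (see *Reproducing the results*).

## Worked example

Simulate a dataset with 15 planted loci, then run the full pipeline:

```bash
ipemsat simulate --seed 11 --n-pairs 10000 --n-loci 15 \
    --genome-len 1000000 --out-dir sim
# wrote 10000 pairs, 15 loci -> sim

ipemsat run-all --in1 sim/reads_R1.fastq --in2 sim/reads_R2.fastq --out-dir run
# 20 SSR-positive pairs, 20 PALs, 15 pPALs -> run
```

Twenty read pairs carried a detectable repeat with a designable primer pair:
the 15 planted loci plus five chance repeats in the random background. Only
the 15 planted loci survive the uniqueness filter — the background loci sit
in multiply-sequenced background, so their primers occur more than once.
`run/summary.json` holds the counts, the per-class breakdown and the
forward-primer copy-number histogram (here: 16 primers seen once, 4 seen
2–10 times); `run/pals.tsv` lists every locus with its primers, Tm/GC,
copy numbers and pPAL flag. Each stage is also available as its own
subcommand (`qc`, `find-ssrs`, `design`, `filter-ppals`, `summarize`) for
file-to-file use on real FASTQ data (Phred-33 or Phred-64, plain or gzip,
two-file or interleaved).

Aggregating the packaged 32-species tables:

```bash
ipemsat summarize --paper-tables
```

```json
{
  "mean_ssr_pairs": 128485,
  "mean_pals": 19072,
  "mean_pal_per_ssr_pct": 17,
  "mean_ppal_per_pal_pct": 25,
  "min_ppals": 136,
  "max_ppals": 52682,
  "species_over_ppal_threshold": {"100": 32, "500": 27, "1000": 19},
  ...
}
```

i.e. a mean of 128,485 SSR-positive pairs per species (range 2,541–644,886);
17% of SSR-positive pairs support primer design on average; about 25% of
PALs pass the uniqueness filter; 27 of 32 species yield over 500 pPALs and
19 over 1,000.

## Layout

- `src/ipemsat/fastq_io.py` — paired FASTQ I/O, quality-encoding handling
- `src/ipemsat/read_qc.py` — B-tail trimming, length filter, dataset cap
- `src/ipemsat/ssr_detect.py` — perfect-repeat finder, canonical motifs
- `src/ipemsat/primer_design.py` — NN melting temperature, primer-pair search
- `src/ipemsat/pal_uniqueness.py` — Aho–Corasick occurrence counting, pPALs
- `src/ipemsat/summarize.py` — table rows, aggregates, packaged tables
- `src/ipemsat/simulate.py` — synthetic genomes/reads with truth manifest
- `src/ipemsat/pipeline.py`, `cli.py` — orchestration and the `ipemsat` CLI
- `docs/methods.md` — models, conventions, parameter defaults, limitations
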