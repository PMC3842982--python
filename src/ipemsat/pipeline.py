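"""End-to-end orchestration: QC -> repeat detection -> primer design ->
uniqueness filtering -> summary.

:func:`run_pipeline` is the in-memory engine used by the command-line
``run-all`` subcommand, the test suite, and the recovery scoring on
simulated data.  Stage outputs are mutually consistent by construction
(every PAL row has a primer pair; every pPAL is a PAL) and the whole run is
deterministic for a fixed input stream and parameter set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Iterable

from .fastq_io import ReadPair
from .pal_uniqueness import (
    HistogramBins,
    OccurrenceTable,
    copy_number_histogram,
    count_occurrences,
    flag_premium,
)
from .primer_design import PALRecord, PrimerParams, design_primer_pair
from .read_qc import QCParams, QCReport, run_qc
from .ssr_detect import RepeatParams, classify_pair
from .summarize import SpeciesSummary, summarize_species

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters in one serialisable block."""

    qc: QCParams = field(default_factory=QCParams)
    repeats: RepeatParams = field(default_factory=RepeatParams)
    primers: PrimerParams = field(default_factory=PrimerParams)
    species_label: str = ""
    library_prep: str = "truseq"

    def to_json(self) -> str:
        d = {
            "qc": asdict(self.qc),
            "repeats": {
                "min_repeats_by_unit": {
                    str(k): v for k, v in self.repeats.min_repeats_by_unit.items()
                }
            },
            "primers": asdict(self.primers),
            "species_label": self.species_label,
            "library_prep": self.library_prep,
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        qc = QCParams(**d.get("qc", {}))
        rep_block = d.get("repeats", {})
        reps = RepeatParams(
            min_repeats_by_unit={
                int(k): int(v)
                for k, v in rep_block.get(
                    "min_repeats_by_unit", RepeatParams().min_repeats_by_unit
                ).items()
            }
        )
        primers = PrimerParams(**d.get("primers", {}))
        return cls(
            qc=qc,
            repeats=reps,
            primers=primers,
            species_label=d.get("species_label", ""),
            library_prep=d.get("library_prep", "truseq"),
        )

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    qc_report: QCReport
    qc_pair_ids: set[str]
    records: list[PALRecord]
    table: OccurrenceTable | None
    forward_histogram: HistogramBins | None
    summary: SpeciesSummary

    @property
    def pals(self) -> list[PALRecord]:
        return [r for r in self.records if r.is_pal]

    @property
    def ppals(self) -> list[PALRecord]:
        return [r for r in self.records if r.is_ppal]


def run_pipeline(
    pairs: Iterable[ReadPair], config: RunConfig = RunConfig()
) -> PipelineResult:
    """Run every stage over a pair stream, holding QC-passed pairs in memory
    (they are needed twice: once for detection/design, once for the
    uniqueness scan)."""
    report = QCReport()
    qcd = list(run_qc(pairs, config.qc, report))

    records: list[PALRecord] = []
    for pair in qcd:
        positive, loci, cls = classify_pair(pair, config.repeats)
        if not positive:
            continue
        rec = PALRecord(pair_id=pair.pair_id, loci=loci, motif_class=cls)
        rec.primer_pair = design_primer_pair(pair, loci, config.primers)
        records.append(rec)

    table = None
    hist = None
    pal_records = [r for r in records if r.primer_pair is not None]
    if pal_records:
        primers = {r.primer_pair.fwd_seq for r in pal_records} | {
            r.primer_pair.rev_seq for r in pal_records
        }
        table = count_occurrences(primers, qcd)
        flag_premium(records, table)
        hist = copy_number_histogram(table, pal_records, which="forward")

    summary = summarize_species(records, config.species_label, config.library_prep)
    return PipelineResult(
        qc_report=report,
        qc_pair_ids={p.pair_id for p in qcd},
        records=records,
        table=table,
        forward_histogram=hist,
        summary=summary,
    )
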