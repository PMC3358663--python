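"""End-to-end prediction: cluster of transcripts -> consensus gene structure.

Stages: per transcript, maximal pairings -> embedding graph -> retained
compositions; across transcripts, MFA consensus; finally intron
extraction, classification and reduction. Per-transcript failures are
isolated and reported, never fatal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .consensus import GeneStructure, consensus_gene_structure
from .embedding_graph import build_from_sequences
from .introns import IntronRecord, extract_introns, reduce_introns
from .io import (TranscriptInput, compositions_to_json, introns_to_json,
                 read_sequences, write_bed12, write_gtf, write_introns_gff3)
from .params import Parameters
from .spliced_alignment import Composition, enumerate_compositions

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RunConfig:
    genome_path: Path
    transcripts_path: Path
    out_dir: Path
    params: Parameters = field(default_factory=Parameters)
    exact_mfa: bool = True
    try_revcomp: bool = False
    debug_dumps: bool = False
    seed: int = 0


@dataclass
class RunReport:
    params: Parameters
    seed: int
    per_transcript: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    counters: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        import json
        from dataclasses import asdict
        return json.dumps(
            {
                "params": asdict(self.params),
                "seed": self.seed,
                "per_transcript": self.per_transcript,
                "warnings": sorted(self.warnings),
                "counters": self.counters,
            },
            indent=2, sort_keys=True,
        )


def align_transcript(
    tid: str, seq: str, genome: str, params: Parameters,
    try_revcomp: bool = False,
) -> tuple[list[Composition], dict]:
    """Compositions of one transcript, with per-stage counters."""
    def one(p_seq: str) -> tuple[list[Composition], dict]:
        g = build_from_sequences(p_seq, genome, params)
        comps = enumerate_compositions(g, p_seq, genome, params, tid)
        stats = {"vertices": len(g.vertices), "edges": len(g.edges),
                 "compositions": len(comps)}
        return comps, stats

    comps, stats = one(seq)
    stats["orientation"] = "+"
    if try_revcomp:
        rc_comps, rc_stats = one(revcomp(seq))
        fwd_best = min((c.total_edit for c in comps), default=None)
        rc_best = min((c.total_edit for c in rc_comps), default=None)
        if rc_best is not None and (fwd_best is None or rc_best < fwd_best):
            comps, stats = rc_comps, rc_stats
            stats["orientation"] = "-"
    return comps, stats


def predict_gene_structure(
    genome: str,
    transcripts: list[TranscriptInput],
    params: Parameters = Parameters(),
    try_revcomp: bool = False,
    seed: int = 0,
) -> tuple[GeneStructure | None, list[IntronRecord], RunReport]:
    """The full pipeline on in-memory sequences.

    Returns (structure, reduced introns, report); structure is None when
    no transcript yields a retained composition.
    """
    report = RunReport(params=params, seed=seed)
    all_comps: dict[str, list[Composition]] = {}
    p_map: dict[str, str] = {}
    refseq_ids = {t.id for t in transcripts if t.is_refseq}
    for t in sorted(transcripts, key=lambda t: t.id):
        try:
            comps, stats = align_transcript(t.id, t.sequence, genome, params,
                                            try_revcomp)
        except Exception as exc:  # pragma: no cover - defensive isolation
            log.exception("alignment failed for %s", t.id)
            report.warnings.append(f"{t.id}: alignment failed: {exc}")
            comps, stats = [], {"error": str(exc)}
        all_comps[t.id] = comps
        p_map[t.id] = (t.sequence if stats.get("orientation", "+") == "+"
                       else revcomp(t.sequence))
        report.per_transcript[t.id] = stats
    report.counters["transcripts"] = len(transcripts)
    report.counters["transcripts_aligned"] = sum(
        1 for c in all_comps.values() if c)
    if report.counters["transcripts_aligned"] == 0:
        report.warnings.append("no transcript produced a retained composition")
        return None, [], report

    structure = consensus_gene_structure(all_comps, params)
    for tid in structure.uncovered:
        report.warnings.append(f"{tid}: excluded from consensus (no composition)")
    report.counters["mfa_factors"] = len(structure.selected_factors)
    report.counters["mfa_exact"] = int(structure.exact)

    introns = extract_introns(structure.chosen, genome, refseq_ids)
    report.counters["introns_before_reduction"] = len(introns)
    reduced, chosen = reduce_introns(introns, structure.chosen, p_map, genome,
                                     params, refseq_ids)
    structure.chosen = chosen
    report.counters["introns_after_reduction"] = len(reduced)
    return structure, reduced, report


def run_pipeline(config: RunConfig) -> tuple[GeneStructure | None,
                                             list[IntronRecord], RunReport]:
    """File-to-file pipeline: read FASTA inputs, write all outputs."""
    genome, transcripts = read_sequences(config.genome_path,
                                         config.transcripts_path)
    structure, introns, report = predict_gene_structure(
        genome, transcripts, config.params, config.try_revcomp, config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if structure is not None:
        (out / "consensus.gtf").write_text(write_gtf(structure))
        (out / "transcripts.bed").write_text(write_bed12(structure.chosen))
        (out / "introns.gff3").write_text(write_introns_gff3(introns))
        (out / "introns.json").write_text(introns_to_json(introns))
        (out / "compositions.json").write_text(compositions_to_json(
            [structure.chosen[tid] for tid in sorted(structure.chosen)]))
    if config.debug_dumps:
        from .embedding_graph import build_from_sequences as _build
        for t in sorted(transcripts, key=lambda t: t.id):
            g = _build(t.sequence, genome, config.params)
            (out / f"graph_{t.id}.tsv").write_text(g.to_tsv())
    (out / "report.json").write_text(report.to_json())
    return structure, introns, report
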