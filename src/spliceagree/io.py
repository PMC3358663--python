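"""FASTA input and GTF/BED12/GFF3/JSON output.

Internal coordinates are 0-based half-open; GTF/GFF3 are written 1-based
closed and BED12 0-based half-open, per their specifications.
"""
from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass

from Bio import SeqIO

from .consensus import GeneStructure
from .introns import IntronRecord
from .spliced_alignment import Composition

REFSEQ_HEADER_RE = re.compile(r"^(NM_|NR_)")


@dataclass
class TranscriptInput:
    id: str
    sequence: str
    is_refseq: bool


def to_gxf_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based closed (GTF/GFF3)."""
    return start + 1, end


def from_gxf_interval(start: int, end: int) -> tuple[int, int]:
    """1-based closed -> 0-based half-open."""
    return start - 1, end


def read_sequences(
    genome_path,
    transcripts_path,
    refseq_ids: set[str] | None = None,
    refseq_pattern: re.Pattern = REFSEQ_HEADER_RE,
) -> tuple[str, list[TranscriptInput]]:
    """Load the genomic record and the transcript cluster.

    The genome FASTA must contain exactly one record. Sequences are
    uppercased (soft-masking ignored); duplicate transcript IDs are
    suffixed with ``.1``, ``.2``, ... with a warning. A transcript is
    RefSeq-flagged when its ID matches ``refseq_pattern`` or appears in
    ``refseq_ids``.
    """
    genome_records = list(SeqIO.parse(str(genome_path), "fasta"))
    if len(genome_records) != 1:
        raise ValueError(f"genome FASTA must have exactly one record, "
                         f"found {len(genome_records)}")
    genome = str(genome_records[0].seq).upper()
    transcripts: list[TranscriptInput] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(transcripts_path), "fasta"):
        tid = rec.id
        if tid in seen:
            seen[tid] += 1
            new_tid = f"{tid}.{seen[tid]}"
            warnings.warn(f"duplicate transcript ID {tid!r} renamed to {new_tid!r}")
            tid = new_tid
        else:
            seen[tid] = 0
        is_refseq = bool(refseq_pattern.match(tid)) or (
            refseq_ids is not None and rec.id in refseq_ids)
        transcripts.append(TranscriptInput(tid, str(rec.seq).upper(), is_refseq))
    if not transcripts:
        raise ValueError("transcript FASTA is empty")
    return genome, transcripts


def write_gtf(structure: GeneStructure, seqname: str = "locus",
              gene_id: str = "consensus") -> str:
    """Consensus factors as GTF exon lines."""
    lines = []
    for i, (s, e) in enumerate(structure.selected_factors, 1):
        g1, g2 = to_gxf_interval(s, e)
        attrs = f'gene_id "{gene_id}"; transcript_id "{gene_id}"; exon_number "{i}";'
        lines.append("\t".join([seqname, "spliceagree", "exon", str(g1), str(g2),
                                ".", "+", ".", attrs]))
    return "\n".join(lines) + ("\n" if lines else "")


def write_bed12(chosen: dict[str, Composition], seqname: str = "locus") -> str:
    """Per-transcript chosen composition as BED12 (blocks = genomic factors)."""
    lines = []
    for tid in sorted(chosen):
        comp = chosen[tid]
        start = comp.factors[0].t_start
        end = comp.factors[-1].t_end
        sizes = ",".join(str(f.t_len) for f in comp.factors) + ","
        starts = ",".join(str(f.t_start - start) for f in comp.factors) + ","
        lines.append("\t".join([
            seqname, str(start), str(end), tid, "0", "+",
            str(start), str(end), "0", str(len(comp.factors)), sizes, starts,
        ]))
    return "\n".join(lines) + ("\n" if lines else "")


def write_introns_gff3(introns: list[IntronRecord], seqname: str = "locus") -> str:
    lines = ["##gff-version 3"]
    for i, rec in enumerate(introns, 1):
        g1, g2 = to_gxf_interval(rec.t_start, rec.t_end)
        attrs = (f"ID=intron{i};pattern={rec.pattern};u_type={rec.u_type};"
                 f"supports={len(rec.supports)};"
                 f"refseq_supported={'true' if rec.refseq_supported else 'false'}")
        lines.append("\t".join([seqname, "spliceagree", "intron", str(g1), str(g2),
                                ".", "+", ".", attrs]))
    return "\n".join(lines) + "\n"


def introns_to_json(introns: list[IntronRecord]) -> str:
    return json.dumps(
        [
            {
                "start": r.t_start,
                "end": r.t_end,
                "length": r.length,
                "donor": r.donor,
                "acceptor": r.acceptor,
                "pattern": r.pattern,
                "u_type": r.u_type,
                "classification": "pattern-based",
                "supports": [list(s) for s in r.supports],
                "refseq_supported": r.refseq_supported,
            }
            for r in introns
        ],
        indent=2, sort_keys=True,
    )


def compositions_to_json(comps: list[Composition]) -> str:
    return json.dumps(
        [
            {
                "transcript_id": c.transcript_id,
                "total_edit": c.total_edit,
                "factors": [
                    {"p_start": f.p_start, "p_end": f.p_end,
                     "t_start": f.t_start, "t_end": f.t_end, "edit": f.edit}
                    for f in c.factors
                ],
            }
            for c in comps
        ],
        indent=2, sort_keys=True,
    )
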