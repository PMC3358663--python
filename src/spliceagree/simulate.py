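"""Synthetic gene loci, isoforms and EST/mRNA clusters.

The generator emulates the input a UniGene-style cluster provides for a
single gene locus: a genomic sequence with planted exons and canonical
splice dinucleotides, a set of isoforms exercising alternative-splicing
events (cassette exons, mutually exclusive exons), and transcripts that
are either full-length error-free mRNAs (RefSeq-like) or truncated,
error-perturbed single-pass ESTs. Every draw is deterministic in the
seed, and the planted truth (exons, isoforms, introns) is retained so
downstream predictions can be scored exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_INTRON_FLANKS = {"GT-AG": ("GT", "AG"), "GC-AG": ("GC", "AG"), "AT-AC": ("AT", "AC")}


@dataclass
class SimulatedGene:
    genome: str
    exons: list[tuple[int, int]]
    isoforms: list[list[int]]
    seed: int
    flank: int = 0

    def isoform_introns(self, iso: list[int]) -> list[tuple[int, int]]:
        return [(self.exons[a][1], self.exons[b][0])
                for a, b in zip(iso, iso[1:])]

    @property
    def splice_truth(self) -> list[list[tuple[int, int]]]:
        return [self.isoform_introns(iso) for iso in self.isoforms]

    def true_introns(self) -> set[tuple[int, int]]:
        return {iv for per_iso in self.splice_truth for iv in per_iso}

    def mature_mrna(self, isoform_index: int) -> str:
        return "".join(self.genome[s:e]
                       for s, e in (self.exons[i]
                                    for i in self.isoforms[isoform_index]))

    def truth_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "exons": [list(e) for e in self.exons],
                "isoforms": self.isoforms,
                "introns": sorted([list(i) for i in self.true_introns()]),
            },
            indent=2, sort_keys=True,
        )


@dataclass
class SimulatedTranscript:
    id: str
    sequence: str
    isoform_index: int
    is_refseq: bool
    error_positions: list[tuple[int, str]] = field(default_factory=list)

    @property
    def fasta_header(self) -> str:
        prefix = "NM_" if self.is_refseq else "EST_"
        return f"{prefix}{self.id} isoform={self.isoform_index}"


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode("ascii")


DEFAULT_ISOFORMS_6EXON = [
    [0, 1, 2, 4, 5],  # uses competing exon C, skips nothing else
    [0, 3, 4, 5],     # competing exon C' + cassette skip of B
    [0, 1, 2, 5],     # cassette skip of D
]


def generate_gene(
    seed: int,
    n_exons: int = 6,
    exon_len_range: tuple[int, int] = (90, 250),
    intron_len_range: tuple[int, int] = (80, 400),
    canonical_fraction: float = 0.9,
    isoforms: list[list[int]] | None = None,
    flank: int = 100,
    crisp_boundaries: bool = True,
) -> SimulatedGene:
    """Plant a gene locus with the requested exon/intron geometry.

    ``canonical_fraction`` of the introns get GT-AG flanks; the rest are
    split between GC-AG and AT-AC. With ``crisp_boundaries`` the single
    genomic base on each side of every planted junction is regenerated so
    that an exact match can never extend across the junction by chance;
    without it, junction placement on error-free data can be genuinely
    ambiguous (a repeated flank admits several zero-cost placements).
    Isoforms default to the three-isoform structure over six exons with a
    mutually exclusive pair (indices 2, 3) and two cassette exons.
    """
    if n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    if exon_len_range[0] > exon_len_range[1] or intron_len_range[0] > intron_len_range[1]:
        raise ValueError("invalid length range")
    if intron_len_range[0] < 4:
        raise ValueError("introns must fit their terminal dinucleotides")
    rng = np.random.default_rng(seed)
    exon_lens = rng.integers(exon_len_range[0], exon_len_range[1] + 1, n_exons)
    intron_lens = rng.integers(intron_len_range[0], intron_len_range[1] + 1,
                               max(n_exons - 1, 0))
    pieces: list[str] = [_random_dna(rng, flank)]
    exons: list[tuple[int, int]] = []
    pos = flank
    intron_spans: list[tuple[int, int]] = []
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pieces.append(_random_dna(rng, int(el)))
        pos += int(el)
        if i < n_exons - 1:
            il = int(intron_lens[i])
            if rng.random() < canonical_fraction:
                pat = "GT-AG"
            else:
                pat = "GC-AG" if rng.random() < 0.5 else "AT-AC"
            d, a = _INTRON_FLANKS[pat]
            body = d + _random_dna(rng, il - 4) + a
            intron_spans.append((pos, pos + il))
            pieces.append(body)
            pos += il
    pieces.append(_random_dna(rng, flank))
    genome = list("".join(pieces))

    if isoforms is None:
        if n_exons == 6:
            isoforms = [list(i) for i in DEFAULT_ISOFORMS_6EXON]
        else:
            isoforms = [list(range(n_exons))]
    for iso in isoforms:
        if any(b <= a for a, b in zip(iso, iso[1:])):
            raise ValueError("isoform exon indices must strictly increase")
        if max(iso) >= n_exons:
            raise ValueError("isoform references a missing exon")

    if crisp_boundaries and n_exons > 1:
        # For every junction any isoform can splice (adjacent or
        # exon-skipping), the exonic base flanking the junction must
        # differ from the intronic base it faces, so that an exact match
        # can never creep across the junction. Only exon-side bases are
        # regenerated; intron dinucleotides stay as planted.
        junctions = {(exons[a][1], exons[b][0])
                     for iso in isoforms for a, b in zip(iso, iso[1:])}
        forbid: dict[int, set[str]] = {}
        for d, a in junctions:
            forbid.setdefault(a, set()).add(genome[d])        # exon first base
            forbid.setdefault(d - 1, set()).add(genome[a - 1])  # exon last base
        for pos, bad in sorted(forbid.items()):
            if genome[pos] in bad:
                choices = [c for c in "ACGT" if c not in bad]
                genome[pos] = choices[int(rng.integers(len(choices)))]

    return SimulatedGene("".join(genome), exons, isoforms, seed, flank)


def _perturb(rng: np.random.Generator, seq: str,
             error_rate: float) -> tuple[str, list[tuple[int, str]]]:
    out: list[str] = []
    events: list[tuple[int, str]] = []
    for i, c in enumerate(seq):
        if rng.random() >= error_rate:
            out.append(c)
            continue
        kind = ("sub", "ins", "del")[int(rng.integers(3))]
        events.append((i, kind))
        if kind == "sub":
            out.append([b for b in "ACGT" if b != c][int(rng.integers(3))])
        elif kind == "ins":
            out.append("ACGT"[int(rng.integers(4))])
            out.append(c)
        # del: emit nothing
    return "".join(out), events


def generate_transcripts(
    gene: SimulatedGene,
    n_per_isoform: int = 15,
    error_rate: float = 0.0,
    truncation_mean: float = 20.0,
    refseq_per_isoform: int = 1,
    seed: int = 0,
) -> list[SimulatedTranscript]:
    """EST/mRNA cluster for a simulated gene.

    Each EST is a contiguous fragment of a mature mRNA: geometric 5'/3'
    truncations (mean ``truncation_mean`` nt per end, jointly capped at
    40% of the transcript) followed by i.i.d. substitution/insertion/
    deletion errors at ``error_rate`` (one third each). RefSeq-like
    transcripts are exact and full length.
    """
    if not 0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    out: list[SimulatedTranscript] = []
    for iso_idx in range(len(gene.isoforms)):
        mrna = gene.mature_mrna(iso_idx)
        for r in range(refseq_per_isoform):
            out.append(SimulatedTranscript(
                f"{iso_idx:02d}{r:04d}", mrna, iso_idx, True))
        for k in range(n_per_isoform):
            cap = int(0.4 * len(mrna))
            t5 = int(rng.geometric(1.0 / (1.0 + truncation_mean)) - 1) if truncation_mean > 0 else 0
            t3 = int(rng.geometric(1.0 / (1.0 + truncation_mean)) - 1) if truncation_mean > 0 else 0
            if t5 + t3 > cap:
                scale = cap / (t5 + t3)
                t5, t3 = int(t5 * scale), int(t3 * scale)
            frag = mrna[t5:len(mrna) - t3 if t3 else len(mrna)]
            seq, events = _perturb(rng, frag, error_rate)
            out.append(SimulatedTranscript(
                f"{iso_idx:02d}{refseq_per_isoform + k:04d}",
                seq, iso_idx, False, events))
    return out


def perturb_junctions(
    chosen: dict,
    P_map: dict[str, str],
    T: str,
    fraction: float,
    max_shift: int,
    rng: np.random.Generator,
    refseq_ids: set[str] | None = None,
) -> tuple[dict, list[tuple[str, int, tuple[int, int]]]]:
    """Shift a fraction of non-RefSeq junction calls by up to ``max_shift`` nt.

    Emulates systematic splice-site placement errors upstream of intron
    reduction: a chosen junction [s, e) becomes [s+d, e+d) (both
    boundaries move, so intron length is preserved), the flanking factor
    intervals and edit distances are recomputed, and the shift direction/
    magnitude is chosen so the perturbed intron no longer matches a
    U2/U12 dinucleotide rule (a perturbation that lands on a canonical
    pattern would be indistinguishable from a genuine alternative
    junction). Returns the perturbed compositions and the list of
    (transcript_id, junction_index, original_interval) actually moved.
    """
    from .introns import classify_intron
    from .spliced_alignment import AlignedFactor, Composition, edit_distance

    refseq_ids = refseq_ids or set()
    out = dict(chosen)
    moved: list[tuple[str, int, tuple[int, int]]] = []
    for tid in sorted(chosen):
        if tid in refseq_ids:
            continue
        comp = chosen[tid]
        for j in range(len(comp.factors) - 1):
            if rng.random() >= fraction:
                continue
            f1, f2 = out[tid].factors[j], out[tid].factors[j + 1]
            s, e = f1.t_end, f2.t_start
            cands = [d for d in (-3, -2, -1, 1, 2, 3) if abs(d) <= max_shift
                     and f1.t_start < s + d and e + d < f2.t_end
                     and f1.p_start < f1.p_end + d and f2.p_end > f2.p_start + d]
            cands = [d for d in cands
                     if classify_intron(T[s + d:s + d + 2],
                                        T[e + d - 2:e + d])[0] == "other"]
            if not cands:
                continue
            d = cands[int(rng.integers(len(cands)))]
            P = P_map[tid]
            g1 = AlignedFactor(f1.p_start, f1.p_end + d, f1.t_start, s + d,
                               edit_distance(P[f1.p_start:f1.p_end + d],
                                             T[f1.t_start:s + d]))
            g2 = AlignedFactor(f2.p_start + d, f2.p_end, e + d, f2.t_end,
                               edit_distance(P[f2.p_start + d:f2.p_end],
                                             T[e + d:f2.t_end]))
            factors = list(out[tid].factors)
            factors[j], factors[j + 1] = g1, g2
            out[tid] = Composition(tid, tuple(factors),
                                   sum(f.edit for f in factors))
            moved.append((tid, j, (s, e)))
    return out, moved


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_cluster(gene: SimulatedGene, transcripts: list[SimulatedTranscript],
                  genome_path, transcripts_path, truth_path) -> None:
    write_fasta(genome_path, [(f"locus seed={gene.seed}", gene.genome)])
    write_fasta(transcripts_path,
                [(t.fasta_header, t.sequence) for t in transcripts])
    with open(truth_path, "w") as fh:
        fh.write(gene.truth_json())
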