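"""Spliced-align one transcript against its locus.

Shows the three per-transcript stages: maximal pairings (exact-match
anchors), the embedding graph over them, and the retained compositions
(spliced alignments) with their exon/intron layout.
"""
from spliceagree import (Parameters, build_from_sequences,
                         enumerate_compositions, generate_gene,
                         generate_transcripts)

gene = generate_gene(seed=42)
est = next(t for t in generate_transcripts(gene, n_per_isoform=3, seed=43)
           if not t.is_refseq)
params = Parameters()

graph = build_from_sequences(est.sequence, gene.genome, params)
print(f"transcript {est.fasta_header.split()[0]}: {len(est.sequence)} nt, "
      f"isoform {est.isoform_index}")
print(f"embedding graph: {len(graph.vertices)} maximal pairings, "
      f"{len(graph.edges)} edges")

comps = enumerate_compositions(graph, est.sequence, gene.genome, params,
                               est.fasta_header.split()[0])
print(f"retained compositions: {len(comps)}")
best = comps[0]
print(f"best composition: {len(best.factors)} exons, "
      f"total edit distance {best.total_edit}")
for f in best.factors:
    print(f"  transcript[{f.p_start}:{f.p_end}] ~ "
          f"genome[{f.t_start}:{f.t_end}]  (edit {f.edit})")
for s, e in best.introns():
    print(f"  intron genome[{s}:{e}]  ({gene.genome[s:s+2]}.."
          f"{gene.genome[e-2:e]})")
# Each factor pairs a transcript interval with a genomic exon; gaps
# between consecutive genomic factors are the introns this EST supports.
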