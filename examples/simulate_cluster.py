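"""Generate a synthetic gene locus and its EST/mRNA cluster.

Builds the default six-exon gene (three isoforms: one cassette-exon
skip, one mutually exclusive exon pair), then draws a transcript cluster
with 1% sequencing errors and one error-free full-length RefSeq-like
mRNA per isoform.
"""
from spliceagree import generate_gene, generate_transcripts

gene = generate_gene(seed=42)
transcripts = generate_transcripts(gene, n_per_isoform=15, error_rate=0.01,
                                   refseq_per_isoform=1, seed=43)

print(f"genome length: {len(gene.genome)} nt")
print(f"exons: {gene.exons}")
print(f"isoforms (exon indices): {gene.isoforms}")
print(f"distinct planted introns: {len(gene.true_introns())}")
n_ref = sum(t.is_refseq for t in transcripts)
print(f"transcripts: {len(transcripts)} ({n_ref} RefSeq-like, "
      f"{len(transcripts) - n_ref} error-prone ESTs)")
# Each planted intron is a genomic interval the pipeline should recover
# exactly; the truth is retained so predictions can be scored.
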