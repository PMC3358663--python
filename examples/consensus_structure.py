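"""Full pipeline: cluster in, consensus gene structure out.

Aligns every transcript, solves the minimum-factorization-agreement
problem for the smallest exon set explaining the whole cluster, and
extracts/classifies the supported introns. The prediction is compared
against the simulator's planted truth.
"""
from spliceagree import generate_gene, generate_transcripts, predict_gene_structure
from spliceagree.io import TranscriptInput

gene = generate_gene(seed=42)
transcripts = generate_transcripts(gene, n_per_isoform=15, error_rate=0.01,
                                   refseq_per_isoform=1, seed=43)
inputs = [TranscriptInput(t.fasta_header.split()[0], t.sequence, t.is_refseq)
          for t in transcripts]

structure, introns, report = predict_gene_structure(gene.genome, inputs)

print(f"transcripts aligned: {report.counters['transcripts_aligned']}"
      f"/{report.counters['transcripts']}")
print(f"consensus exons (MFA, exact={bool(report.counters['mfa_exact'])}): "
      f"{len(structure.selected_factors)}")
for s, e in structure.selected_factors:
    mark = "=" if (s, e) in set(gene.exons) else "?"
    print(f"  exon [{s}, {e})  {mark}")
print("predicted introns (pattern, spliceosome, #supporting transcripts):")
for r in introns:
    mark = "=" if (r.t_start, r.t_end) in gene.true_introns() else "?"
    print(f"  [{r.t_start}, {r.t_end})  {r.pattern}  {r.u_type}  "
          f"x{len(r.supports)}  {mark}")
# '=' marks agreement with the planted truth. The MFA consensus keeps the
# fewest exons such that every transcript retains one spliced alignment
# built only from those exons.
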