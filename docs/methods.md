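# Methods

This note records the model implemented by `spliceagree`, the numerical
and design choices that were genuinely open, what the simulator does and
does not emulate, and the known limitations.

## Model and assumptions

The input is one genomic sequence, assumed to span a single gene locus
on the coding strand, and a cluster of transcripts (ESTs/mRNAs) assumed
to derive from that locus. A spliced alignment (*composition*) of a
transcript *P* factorizes it as *P* = *f*₁…*f*ₖ with each factor aligned
to a genomic interval (exon), consecutive exons separated by introns,
and each factor-to-exon edit distance small. The method assumes:

* transcript errors are point events (substitutions, short indels), so
  every true exon of length ≥ ~3·ℓ_E contains exact matches long enough
  to anchor it;
* mismatch runs inside one exon span at most ℓ_D nucleotides, while true
  introns are at least ℓ_I nucleotides — the two gap regimes are
  separated by construction (ℓ_I > ℓ_D);
* splice junctions preferentially follow the canonical dinucleotide
  patterns GT–AG, GC–AG (U2-type spliceosome) and AT–AC (U12-type);
* RefSeq-flagged transcripts are full-length and error-free, so their
  junctions are trusted.

## Parameters

| name | meaning | default | rationale |
| --- | --- | --- | --- |
| ℓ_E | minimum anchor (pairing) length, nt | 15 | seeds short enough to survive ~1–2% error rates on exons ≥ ~45 nt, long enough to keep the embedding graph small |
| ℓ_D | maximum mismatch-gap span inside an exon, nt | 20 | bounds clustered-error bridging; also bounds the strings compared during gap scoring |
| ℓ_I | minimum intron length, nt | 60 | approximate minimal human intron |
| max_factor_edit | per-factor edit ceiling | 5% of factor length, floor 2 | tolerates EST error rates up to a few percent |
| gap_edit_fraction | local ceiling for the gap joining two anchors of one exon | 30% of gap length, floor 2 | gaps are where errors cluster (that is why the anchors broke), so the local filter must be lenient; unrelated DNA still fails it, since random 4-letter strings differ by roughly half their length, and the per-factor ceiling remains the final arbiter |
| b | intron-reduction error budget, edit ops | 4 | covers boundary shifts of ≤ 3 nt plus one residual mismatch |
| shift_window | junction shift search radius, nt | 2·b + 6 | small multiple of the budget; reduction is meant for near-miss calls |
| min_factor_len | minimum retained factor length, nt | 10 | drops degenerate slivers created by trimming |
| end_clip | unaligned nt tolerated at transcript ends | 30 | EST ends are low quality; clipped ends are excluded from the contiguity requirement |
| source_window | transcript-start window for visit sources, nt | 50 | must be ≥ end_clip so every emitted chain starts at a source |
| exact_limit | largest universe for the exact consensus solver | 24 | bounded subset search stays interactive; greedy fallback above |

All are overridable from the CLI and the `Parameters` dataclass.

## Numerical and algorithmic choices

**Maximal pairing enumeration.** Implemented as a vectorized
longest-common-extension dynamic programming scan (O(|P|·|T|) time,
O(|T|) memory): a triple (p, t, l) with l the full forward extension is
maximal exactly when the match is left-blocked. At the locus and cluster
sizes this package targets (kilobase loci, hundreds of transcripts) the
vectorized scan outperforms a pure-Python linear-time suffix structure;
the enumerated set is checked against a definitional brute force in the
test suite. `N` bases never match (including `N` vs `N`), so low-quality
stretches split anchors instead of bridging them.

**Edge orientation.** The printed edge conditions admit edges moving
backwards along the transcript; a forward-orientation constraint
(p₁ < p₂, ties by t) is added, matching the semantics of an embedding.
Directed cycles among overlapping anchors remain possible and are
tolerated; the visit walks simple paths only, which terminates and, on
repeat-bearing test instances, emits the same factor sets as the
acyclic restriction.

**Extended sources.** Defined as the union of in-degree-0 vertices and
vertices anchored within `source_window` of the transcript 5' end. Since
an emitted chain must start within `end_clip` ≤ `source_window`, every
reportable chain starts at a source.

**Overlap resolution.** Two same-exon anchors that overlap are trimmed
to the shortest admissible prefix of the left anchor and the longest
admissible suffix of the right one, both at least ℓ_E; sequence released
by trimming is re-scored later as part of the merged factor, so the trim
rule affects only anchor bookkeeping, not the final alignment.

**Junction placement.** When a junction is ambiguous (the anchors
overlap on the transcript, or a genomic gap must be split), the
placement minimizes the edit distance between the transcript gap and the
retained genomic flanks; ties are broken by the splice pattern of the
excised interval in the priority order GT–AG > GC–AG > AT–AC > other,
then leftmost. The split search may keep at most 2·|G_P| genomic
characters — any longer retention is provably suboptimal
(edit ≥ kept − |G_P|), so the cap does not change the optimum.

**Tandem repeats.** When two anchors overlap on both sequences with
intron-sized drift, the situation is genuinely ambiguous between an
intron and a tandem repeat absorbed into one exon; both interpretations
are emitted and the consensus stage disambiguates (the absorbed variant
survives only if its factor-level edit distance, which includes the
surplus repeat copy, stays under the ceiling).

**Edit distances** are unit-cost Levenshtein, computed with edlib.

**Visit guards.** Chains per source are capped at 10,000 and retained
compositions per transcript at 500 (kept by lowest total edit, then
fewer factors, then leftmost); the caps exist to bound adversarial
repeat structures and are not reached in any test or simulation in this
repository.

**Factor universe and soft boundaries.** The outer boundary of a
transcript's first/last factor is a sequencing artifact (truncation),
not a splice site. Factor occurrences are therefore grouped by their
*anchored* junction coordinates; soft (transcript-end) boundaries unify
into the group sharing their anchored junction, and a group's
representative interval takes the widest observed extent on each soft
side, so one full-length transcript pins the true exon boundaries.
Without this, every truncated EST would contribute private terminal
factors and the consensus universe would grow with cluster size instead
of gene complexity. An optional `boundary_tol` additionally clusters
junction coordinates within a small distance (default 0: junctions are
already canonicalized by the edit-minimizing placement).

**Exact consensus solver.** Factors present in every factor set of some
transcript are forced into the solution; the remainder is found by
iterative deepening over subset size in lexicographic order with bitmask
feasibility tests, so the first valid solution is a minimum-cardinality,
lexicographically-smallest agreement set. The greedy fallback adds, at
each step, the factor completing the most currently-unsatisfied
transcripts' cheapest remaining factor sets (ties: lowest index); it is
always valid but not necessarily minimal, and results are flagged with
the solver used.

**Intron reduction** moves one junction support at a time, scanning
target tiers in trust order (RefSeq, GT–AG, GC–AG, AT–AC; within a tier,
nearest interval, ties leftmost) and accepting the first target
reachable within `shift_window` at ≤ b extra edits. The procedure
iterates to a fixpoint, so applying it twice changes nothing; support
count is asserted conserved on every run. Canonical (U2/U12-rule) and
RefSeq-supported introns are never modified. U-type classification is
pattern-based (dinucleotide rules only) and labelled as such in the JSON
output; position-weight-matrix U12 discrimination is out of scope.

**Degenerate inputs.** Empty sequences and non-IUPAC characters are
rejected; a transcript with no retained composition is excluded from the
consensus with a warning (one unalignable EST must not block the gene);
a cluster with no alignable transcript yields an empty structure and a
non-zero CLI exit.

## The simulator

`generate_gene` plants exons (default lengths U[90, 250] nt) and introns
(U[80, 400] nt, each ≥ ℓ_I) in i.i.d. uniform ACGT background, with a
configurable fraction of GT–AG introns (default 0.9; remainder split
GC–AG / AT–AC). The default six-exon, three-isoform structure exercises
a cassette-exon skip and a mutually exclusive exon pair.
`generate_transcripts` emits, per isoform, full-length error-free
RefSeq-like mRNAs plus ESTs that are geometrically truncated at both
ends (mean 20 nt, jointly capped at 40% of the transcript) and carry
i.i.d. substitution/insertion/deletion errors (one third each).

With `crisp_boundaries` (default on), the single exonic base flanking
every junction any isoform can splice is regenerated so it differs from
the intronic base it faces; an exact match therefore never extends
across a junction by chance. This makes error-free junction placement
information-theoretically unambiguous — without it, a repeated flank
admits several zero-cost placements and *no* method could guarantee
exact recovery, so the generator's default models the identifiable case
while leaving the ambiguous one reachable by flag.

What the simulator does **not** emulate: base-quality structure
(errors are i.i.d., not end-biased), polyA tails and priming artifacts,
chimeric or antisense ESTs, paralogous loci, genomic repeat families
(tandem repeats are planted only in dedicated test instances), and
intron-length or splice-site sequence biases beyond the terminal
dinucleotides. Passing the round-trip suites therefore demonstrates the
combinatorial machinery is correct under the stated error model, not
performance on real cDNA libraries.

## Problem sizes used in the checks

The test-suite and acceptance-script studies use clusters of ~48
transcripts (15 ESTs + 1 RefSeq per isoform) on ~2–3 kb loci, 10–20
replicates per condition; oracle comparisons use 50–200 random or
planted instances per stage with sequences up to 200 nt (the exhaustive
oracles are exponential or quartic, which sets the instance sizes).

## Known limitations

* Single-locus assumption: no multi-gene partitioning of large regions.
* Full-length isoform reconstruction, CDS/UTR annotation and polyA
  detection are out of scope; the output is the exon set, the per-
  transcript compositions, and the intron catalogue.
* The per-gap and per-factor edit ceilings are heuristics; pathological
  error clustering beyond ℓ_D drops the transcript (reported, never
  silently bridged).
* Orientation handling is a convenience (`--try-revcomp` aligns both
  strands and keeps the better one); there is no splice-aware strand
  inference.
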