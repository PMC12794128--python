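# Methods

## Pipeline model

`protannot` treats annotation as evidence projection: every gene model must
be anchored in a spliced protein-to-genome alignment. The pipeline is a
deterministic function of (genome, alignment set, configuration); there is
no stochastic training step, so identical inputs give byte-identical
outputs.

**Alignment ingestion.** One alignment chain per aligner `mRNA` record, with
its `CDS` children as exon blocks and the `Identity` attribute (fraction of
matching residues) as the chain's quality. A protein hitting several loci
contributes several independent chains. Chains with identity below
`min_identity` are discarded; the comparison is inclusive (≥), so a 0.8
threshold admits exactly-0.8 chains. Frameshift or in-frame-stop flags the
aligner may emit do not reject a chain here — the ORF model arbitrates
downstream.

**Locus assembly.** Chains sharing seqid and strand join one locus iff at
least one pair of their exon blocks overlaps by ≥ 1 bp (single linkage).
The overlap test is block-level, not span-level: a gene nested inside
another gene's intron must remain a separate locus. Member blocks are
unioned (coalescing overlapping or book-ended intervals), and the two
outermost edges are extended by `terminal_flank`, clipped to the contig and
to the nearest block of the neighbouring same-strand locus, exclusive —
flanks never create new overlaps between loci. Internal block boundaries
are putative splice junctions and are never moved. The merged blocks are
spliced into the pseudo-transcript; the coordinate map is kept explicitly
(the array of genome positions in transcript order) so that projection back
to the genome is exact by construction, splitting only at block junctions.

**ORF enumeration.** All maximal ORFs in the three forward frames (the
strand is fixed by the protein evidence; scanning the reverse strand would
reintroduce the false positives the design avoids). Within one
stop-to-stop segment the 5'-most ATG defines the reported ORF. ORFs
truncated by the transcript ends are labelled `5prime_partial`,
`3prime_partial` or `internal` and are reported only when partials are
allowed; they rank below complete ORFs at equal score.

**Coding model.** A frame-periodic hexamer log-odds model, self-trained:

- positives: the `train_top_n` (default 500) longest complete ORFs across
  all pseudo-transcripts, deduplicated by exact nucleotide sequence;
- background: all pseudo-transcript sequence, frame-free.

For each base b with 5-base context c and codon frame f (position mod 3
from the ORF start) the score contribution is
log P_coding(b | c, f) − log P_background(b | c). Scores are summed over
positions (nats) and are additive over in-frame concatenation. At the 5'
end, and wherever the context window contains a non-ACGT character, the
model backs off to the longest clean shorter context.

Conditional probabilities are estimated with *count-adaptive interpolation
across orders* (in the spirit of interpolated Markov models): the order-k
estimate for a context is a mixture of its own pseudocount-smoothed
maximum-likelihood estimate, weighted n/(n + ridge) where n is the context's
observation count (ridge = 100 counts), and the order-(k−1) estimate of the
context's suffix. Plain additive smoothing alone is miscalibrated at typical
training sizes: when the coding table's context rows hold far fewer counts
than the background's, every rare hexamer receives a spurious positive
log-odds of roughly log(n_bg/n_coding) regardless of whether it came from
coding sequence, which erases the contrast between coding and flanking
sequence. Interpolation lets sparse rows defer to well-estimated shorter
contexts in both models symmetrically, which removes the artifact while
converging to the full hexamer model as data grow.

With fewer than 50 training ORFs the model degrades to a zero-information
model (all log-odds 0, with a warning); selection then ranks by length
alone. With identical coding and background training data, scores are near
zero (exactly zero only in the infinite-data limit, because the
interpolation weights depend on per-row counts).

**Start refinement.** Enumeration's "5'-most ATG" rule absorbs upstream
flank sequence whenever a chance in-frame ATG precedes the true start
without an intervening stop (for 300 bp flanks this happens at roughly one
locus in three). Before selection, each ATG-initiated ORF's start is
therefore moved to the in-frame ATG that maximises the coding score of the
remaining ORF, among candidates that keep the peptide above `min_orf_aa`
(ties go to the 5'-most, i.e. longest). This is the same idea as the start
refinement of transcript coding-region finders. It can be disabled with
`--no-start-refine`.

**Selection, splitting, filtering, deduplication.** Scored ORFs passing
`min_score` and `min_orf_aa` are selected greedily by descending score
(complete before partial at equal score, then longer, then leftmost) under
a no-overlap constraint in transcript coordinates. Each retained ORF
becomes one gene — a pseudo-transcript with two or more retained ORFs is
thereby split, which resolves fused neighbouring genes. Projection computes
GFF3 phases cumulatively (phase_i = (3 − L_i mod 3) mod 3, L_i = preceding
CDS length) and re-translates the projected chain against the ORF peptide;
a mismatch or internal stop is a hard error, not a warning, because it can
only indicate a coordinate-map defect. Filtering logs every rejection
(gene, criterion, value, threshold) to a first-class TSV output.
Deduplication collapses identical (seqid, strand, CDS chain) models,
pooling their supporting proteins, and resolves residual same-strand
CDS-chain overlaps in favour of the higher score, then length, then
leftmost position. Output genes get positional IDs (`{prefix}gene-N`)
regenerated each run.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `min_identity` | 0.9 | minimum alignment identity (fraction). Conservative default favouring precision; lower to 0.8 for distant references. Inclusive comparison. |
| `terminal_flank` | 300 bp | outward extension of each locus, giving the ORF search room to recover start/stop codons just outside the homology blocks; ~100 codons covers most terminal truncation. |
| `min_orf_aa` | 100 aa | minimum peptide length — the conventional long-ORF cutoff; applied to peptide length (not CDS nt), the least ambiguous reading of a "length" filter. |
| `min_score` | 0 nats | the log-odds must favour coding. |
| `markov_order` | 5 | hexamer model. |
| `train_top_n` | 500 | training positives; longest-first selects the ORFs least likely to be spurious. |
| `pseudocount` | 1 | additive smoothing within a context row. |
| ridge | 100 counts | interpolation scale; rows with ≫100 observations trust their own statistics — see above. |

## Evaluation definitions

A genome base is coding on a strand if covered by ≥ 1 CDS on that strand;
bases coding on both strands count once per strand. TP is the size of the
strand-aware intersection of predicted and reference coding base sets;
Sn = TP/ref, Sp (precision) = TP/pred, F1 = 2·Sn·Sp/(Sn+Sp) (defined 0 when
both are 0; Sp is flagged undefined when there are no predicted bases). The
denominator is whole-genome: reference genes on contigs the prediction
never touches still count against sensitivity. Statistics use CDS segments
as the exon proxy (pseudo-transcripts carry no UTRs), and the mono/multi
ratio is mono-exonic/multi-exonic gene counts (∞ flagged when no
multi-exonic genes exist). Evaluation is base-level only; exon- and
transcript-level matching codes are out of scope.

## Synthetic data

The generator plants `n_genes` genes (default 50) on `n_contigs` contigs of
`contig_length` bp (default one 500 kb contig): 2–5 exons of 180–450 bp,
introns of 80–500 bp beginning GT and ending AG, ≥ 800 bp between gene
bodies, random strands. CDS codons are drawn from a fixed position-biased
codon table (GC-rich third positions), so planted coding sequence is
statistically separable from the iid intergenic background (GC 0.42) — the
signal the hexamer model exploits. Homolog proteins are derived by per-site
substitution at rate `protein_divergence`; the realized identity is recorded
and becomes the alignment's `Identity` attribute, optionally with Gaussian
reporting noise. Alignments are emitted at the exact truth coordinates:
this isolates pipeline correctness from aligner behaviour, which is the
point of the fixture — it does *not* exercise aligner-induced block-boundary
error, frameshifts, paralog cross-mapping, repeats or pseudogenes, so
passing tests bound coordinate-handling and model-selection correctness,
not robustness to noisy real alignments. A single seed drives one generator
stream through genome, mutation and alignment simulation.

Default problem sizes keep the full test suite fast: 50-gene/500 kb runs
for recovery and threshold behaviour, 1,000 random loci for coordinate-map
fuzzing, 200 random annotation pairs on 100 kb contigs against the per-base
brute-force oracle, and model recovery from 500 sequences of 2,500 codons
sampled from a known random frame-periodic hexamer table (count-weighted
mean total variation ≤ 0.05 per frame).

## Numerical and degenerate-input choices

- Coordinates are GFF3 1-based inclusive at every interface; CDS chains of
  complete models include the stop codon; chains are stored 5'→3' in
  transcript sense and writers re-sort to ascending genomic order.
- Translation uses the standard nuclear code (NCBI table 1, configurable);
  codons containing non-ACGT characters translate to X; soft-masked
  sequence is uppercased for analysis but preserved in output extraction.
- Longest-isoform ties break to the lexicographically smallest transcript
  id; all other tie-breaks are stated with their operations above.
- Empty post-filter chain sets produce valid empty outputs with a warning;
  an empty annotation is an error for statistics (no meaningful means) but
  a flagged result for evaluation.
- Gene counts are monotonically non-increasing in `min_identity` and
  `min_orf_aa` (regression-tested).

## Known limitations

- One isoform per locus by construction; alternative splicing is out of
  scope (inputs can be pre-reduced with the longest-isoform utility).
- Genes without homology support in the reference protein set cannot be
  predicted; completeness is bounded by the reference panel.
- UTRs are never modelled.
- The coding model is trained on the input loci themselves; on very small
  alignment sets (< 50 training ORFs) selection degrades to length ranking.
- Scoring against pre-trained protein models (for example re-scoring ORFs
  against external databases) is noted as future work.
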