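# Methods

This note documents the models, parameter defaults and numerical choices
behind `ambistop`, and what the synthetic-data tests do and do not
demonstrate about real data.

## The biological setting

The package targets assemblies from organisms with an *ambiguous* genetic
code: all three canonical stop codons are contextually translated
(UAA/UAG as glutamine via suppressor tRNAs with anticodons UUA/CUA, UGA as
tryptophan via a Trp-CCA tRNA with a shortened anticodon stem), while eRF1
still terminates at the same codons. Conventional annotators refuse gene
models with in-frame stops, so a conservative two-pass strategy is used:
an ordinary annotation first (supplied to the pipeline as GFF3), then a
homology-driven search of the *unannotated* remainder for stop-codon-
containing genes (SCGs). The same assemblies are cultured metagenomes
(parasite + host + bacteria) and carry a fragmented, repeat-laden
organellar genome, hence the binning and mitochondrial stages.

## Contig binning

A contig is `bacterial` if an external rRNA screen flagged it (the screen
itself is out of scope — a boolean table is consumed instead of bundling a
16S database); else `parasite_nuclear` iff depth ≥ 20×, transcript coverage
≥ 50% and AT ∈ [63%, 67%]; else `organelle_candidate` iff AT lies above the
nuclear window and depth ∈ [1.0, 8.05]×; else `unassigned`. The nuclear
rule is the published threshold set for this kind of assembly; the
organelle rule is this package's formalization of the visually separated
low-coverage AT-rich cloud in the (AT, depth) scatter — the source analysis
gives no explicit organelle thresholds, so the rule is documented as an
interpretation. Transcript coverage is the per-base union fraction of the
contig covered by transcript alignments (strand-agnostic); AT fractions
exclude N from the denominator.

## Seeded, stop-tolerant codon alignment

*Seeding.* Exact amino-acid k-mers (k = 4) between the query proteome and
all six readthrough-frame translations of a window, merged per diagonal; a
(query, strand, frame) triple is aligned when some diagonal covers ≥ 40
query residues (`min_diag_score`). Readthrough translation (UAA/UAG → Q,
UGA → W, N-codons → X) lets seeds cross in-frame stops.

*DP.* Smith–Waterman with Gotoh affine gaps over query residues × target
codons in a fixed frame. BLOSUM62 (from Biopython's embedded tables);
gap of length L costs `open + extend·L` — 11 + L for proteins, 5 + 2L for
nucleotides (match +1, mismatch −2; N matches nothing). Stop codons enter
as X and score through the matrix's X column by default; a flat
`stop_penalty` alternative is configurable. Identity is matches / aligned
columns (gaps excluded); stop columns are never matches. Alignments below
`min_score` = 60 are dropped. The published analysis gated candidate hits
at BLAST e-value 1e-5 (and mitochondrial labelling at 1e-75); e-values are
tool- and database-size-specific, so this package replaces them with the
raw-score and identity gates above — Karlin–Altschul calibration is out of
scope.

*Determinism.* The best cell is the first maximum in row-major order
(smallest query end, then target end); the traceback prefers diagonal over
query-gap over target-gap; frame ties resolve to the lowest frame. Every
downstream stage sorts its outputs canonically, so results are invariant to
input ordering.

*Frameshifts are not modelled in the DP.* This keeps the recursion exact
and oracle-testable (the test suite checks it cell-for-cell against a
brute-force cubic DP); frameshift handling moves to the discovery stage.

## SCG discovery

1. `extract_unannotated`: per-contig complement of annotated `gene`
   features, dropping segments < 300 bp; each region is windowed with
   2 kb flanks (clipped at contig ends) for alignment context.
2. Seeded DP of the proteome against each window, per seeded frame.
3. Routing: alignments whose genomic footprint overlaps annotated genes by
   more than 20% go to a stop-free side channel (the search is confined to
   unannotated space; windows merely reintroduce annotated sequence as
   context, and a query bridging its own annotated intron would otherwise
   masquerade as an SCG). Stop-free alignments in unannotated space go to
   the same side channel for re-annotation review. Only alignments with
   ≥ 1 in-frame stop continue.
4. `resolve_overlaps`: greedy by descending score — an alignment is kept
   iff it does not overlap (same contig/strand, ≥ 1 bp) an already-kept
   one. This matches the published wording ("only the best-scoring
   alignment was kept"); the test suite compares it against the exhaustive
   maximum-weight independent set as a diagnostic, not a contract.
5. `flag_frameshifts`: a kept model is discarded when another alignment of
   the same query, on the same contig and strand but in a different
   *genomic* frame, lies within 100 bp (overlap or gap) and covers an
   essentially disjoint query segment (≥ 20 unique residues each side,
   allowing ≤ 15 residues of overlap, since local alignment extends a few
   chance matches past an indel breakpoint). The published pipeline
   discarded its aligner's frameshift-containing alignments; that aligner's
   internal definition is not recoverable, so this two-partial-alignments
   rule is an operational proxy.
6. `check_transcript_support`: supported iff the best-scoring transcript
   alignment has identity ≥ 0.90 and covers ≥ 0.80 *of the model* (the
   coverage is read as coverage of the model, per the rule's subject). An
   exact 21-mer sharing prefilter (≥ 3 shared k-mers, top 5 candidates)
   keeps the all-vs-all alignment tractable; at 90% identity an overlap of
   a few hundred bp still shares dozens of 21-mers, so the prefilter does
   not bite at the thresholds that matter.
7. `mask_stops`: readthrough translation of the model's codons with every
   standard-code stop rendered as X; `compute_scg_stats` reports model
   count, transcript-supported count, mean stops per model, pooled
   TAA/TAG/TGA composition and mean masked length.

Ortholog length ratios (`length_ratio_report`) take each protein's length
over its best-scoring orthogroup member's length (ties to the longer
member, then id; singleton groups skipped and counted). `scan_erf1_motif`
reports the tetrapeptide at the eRF1 stop-recognition site, preferring
N/R-initial matches of x-IKS in the N-terminal half.

## tRNA analysis

Suppressor classification is purely anticodon-based (gene-sense TTA → UAA,
CTA → UAG, TCA → UGA); pseudo-tRNAs are tallied separately and never veto
or count. The anticodon stem is measured structurally: locate the unique
fully-unpaired occurrence of the anticodon whose enclosing loop is closed
by a stem, then count consecutive nested base pairs from the loop outward.
The unpaired bases immediately outside a shortened (4 bp) stem are reported
as RNA letters; their canonical position labels (26 and 42) come from a
fixed cloverleaf template mapped by stem boundaries — full Sprinzl
alignment machinery is out of scope, and the two flanking bases are
structurally determined.

## Mitochondrial analysis

Identification is reciprocal: distant reference proteins (cox1/cox3/cob)
are aligned across the whole assembly under the protozoan mitochondrial
code (NCBI table 4; UGA = Trp); each reference's best hit is translated
into a species-specific query; every contig with a hit at ≥ 95% identity
over ≥ 100 codons to a species query is labelled mitochondrial. A hit is a
fragment when its aligned length falls below 90% of the longest copy found
in the assembly (fallback: the reference length).

Inverted repeats are *exact maximal* pairs: two windows with
`window_a = revcomp(window_b)`, length ≥ 50 (the published run reports
pairs of exactly 50 bp, so the bound is inclusive), not extendable outward
on either flank. Implementation: seeded runs on the diagonals of the
sequence against its reverse complement; the suite checks equality with a
full O(n²) enumeration. Overlapping (palindromic) pairs are included by
default behind a flag, with the first window required to start before the
second; a window paired with itself is excluded. Near-identical family
variation is deliberately left to the *clustering* step, mirroring the
two-stage exact-repeat + 95%-identity-cluster design of the original
analysis: units sorted by length descending, each joining the first
cluster whose (longest-member) representative it matches at ≥ 95%
matched-columns over the shorter sequence, in either orientation — as
fixed-threshold nucleotide clustering tools do by default.

## Splice junctions

Junctions arrive in a BED12-like dialect (two anchor blocks around one
intron; score = supporting reads; anchor length = block size). Filtering
keeps anchor ≥ 30 and support ≥ 3. Donor/acceptor dinucleotides are read
on the annotated strand (minus strand via reverse complement) and mapped
to GT/AG, GC/AG, AT/AC, AT/TC or "other". The motif matrix tallies 16
positions (E4..E1, I1..I4, −I4..−I1, −E1..−E4), strand-normalized;
junctions whose 4-bp exonic flanks leave the contig are skipped and
counted. The matrix is tallied post-filter.

## The synthetic generator

`SyntheticConfig` defaults *are* the emulated study conditions:

| parameter | default | basis |
| --- | --- | --- |
| `n_genes` | 600 | desk-scale stand-in for the real gene count |
| `scg_fraction` | 0.44 | ≈ fraction of predicted genes that are SCGs |
| `stop_mix` | 0.58 / 0.323 / 0.097 | published pooled TAA/TAG/TGA composition |
| `mean_stops_per_scg` | 13.6 | published mean; per-gene counts Poisson, truncated ≥ 1 |
| `mean_scg_len_aa` | 549 (min 100) | published mean; geometric-like lengths |
| `mean_gene_len_aa` | 331 | published mean ordinary-gene protein length |
| `nuclear_at` | 0.652 | published assembly AT content |
| `nuclear_depth_mean` | 60× (SD 6, clipped ≥ 20) | well above the 20× bin threshold |
| `mito_depth_range` | 1.0–8.05× | published organellar coverage band |
| `mito_at` | 0.75 | above the nuclear AT window, per the binning geometry |
| `intron_mix` | GT/AG .97, GC/AG .01, AT/AC .01, AT/TC .01 | GT/AG-dominated splicing |
| `mean_introns_per_gene` | 1.6 | ≈ 2.6 exons per ordinary gene |
| `scg_transcript_fraction` | 0.679 | ≈ 2462 / 3627 transcript-supported SCGs |
| spacers | ≥ 200 bp, mean 250 | a compact genome with little intergenic space |
| tRNAs | 2×TTA, 2×CTA, 0×TCA, 7×Trp-CCA (one 4-bp stem), 3 pseudo | published suppressor inventory |

Coding sequence is built by back-translating random proteins with
synonymous-codon weights `θ^(#AT)`; θ is solved by bisection so the
expected coding AT equals the target, and intergenic spacers use the same
AT target, so composition alone cannot separate genes from background.
Stops are planted by substituting sense codons (Gln → TAA/TAG, Trp → TGA)
at uniformly chosen internal positions — never the final codon, never two
adjacent codons — so ORF-end semantics stay unambiguous for the aligner.
Introns go only into non-SCG genes by default (`scg_introns` flips this),
isolating SCG discovery from splice modelling. SCGs are withheld from the
emitted annotation; every planted fact is recorded in `truth/` tables and
re-derived from the emitted FASTA/GFF3 by the test suite. Mito contigs
carry full and fragmented (≥ 150 bp) template-gene copies — every contig
keeps at least one full copy so the labelling rule can reach it — plus
exact inverted-repeat pairs from families planted at most once per contig
(two same-family pairs on one contig would create cross-pairs absent from
the truth table); pair flanks are adjusted so planted pairs are maximal.
Reference organellar proteins are template translations mutated at 8% of
residues, emulating a cross-genus query. All randomness flows from one
seeded generator; identical config + seed reproduce byte-identical files.

**What the generator does not emulate:** sequencing error and read-level
artifacts (no FASTQ), real codon-usage and amino-acid composition,
paralogy and gene families, repeats in the nuclear background, RNA editing,
and genuinely ambiguous stop/sense context. Zero-noise precision/recall of
1.0 therefore demonstrates the *rules* are implemented faithfully, not that
the pipeline would achieve those figures on a real assembly — the published
counts on real data depend on the deposited assembly and tool-specific
aligner internals and are explicitly not reproduction targets.

## Problem sizes and runtime

The default bundle (~1.2 Mb across 14 contigs, 600 genes, 264 SCGs) was
chosen so a full generate-plus-discover cycle completes in about a minute
on one CPU; unit tests run a 40-gene bundle. The DP kernel is numba-jitted
and recompiles once per process. With ~264 SCGs the recovered mean-length
estimate carries a standard error of about 28 aa (geometric lengths, SD ≈
450), the mean-stop estimate about 0.23, and the pooled composition about
0.8 percentage points — the tolerances used in the acceptance tests sit at
2–3 of these standard errors.

## Known limitations

* The aligner is unspliced; candidates overlapping annotated introns are
  routed out rather than stitched per-exon, so an SCG interrupted by a real
  intron would be recovered as partial models.
* Greedy overlap resolution can differ from the optimal independent set on
  adversarial score patterns (logged by the diagnostic test, by design).
* The frameshift proxy needs both partial alignments to clear the seed and
  score gates; a frameshift within ~20 residues of a gene end is invisible.
* Anticodon-stem position labels use a fixed template, not Sprinzl
  numbering; unusual D-arm architectures would mislabel the flanks (the
  stem *count* remains correct).
* E-value gates are replaced by score/identity gates; threshold-level
  agreement with BLAST-based pipelines is guaranteed only on synthetic
  data.
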