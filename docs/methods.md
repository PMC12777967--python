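# Methods

## Model and assumptions

A gene's splicing graph is a DAG over the union of its transcripts' exon
intervals; edges are intron connections observed in at least one transcript
or supplied as novel junctions. The model assumes

* exons of one transcript are disjoint and ordered; consecutive exons define
  its edges;
* vertices with identical intervals are merged; exons sharing one boundary
  but not the other (alternative 3'/5' splice sites) remain distinct
  vertices, and the resulting output overlap is handled by the redundancy
  rule at output time;
* novel junctions reuse existing exon boundaries — junction insertion never
  invents vertices. Junctions matching no boundary are rejected and counted.
  Graph construction from read alignments is out of scope; the graph is
  built from the annotation plus a junction list.

All internal coordinates are 0-based half-open on the forward genomic
strand; GTF (1-based closed) and VCF (1-based) are converted at the I/O
boundary only. Minus-strand genes are traversed in reverse genomic order on
reverse-complemented sequence; a strand-symmetry test asserts that mirroring
the genome yields the identical peptide multiset.

## Reading frames

A reading frame r ∈ {0,1,2} is the offset at which codon chunking starts
within an exon, in the translation direction. Annotated frames come from CDS
starts: a translation start site anchors frame 0 (or the GTF phase, when
nonzero) at its offset inside every exon containing it. A TSS equal to an
exon's half-open end is treated as outside that exon; on the minus strand
the TSS is an interval end and anchors to the exon it closes.

Propagation across an edge: with coding length L and frame r,
res = (L − r) mod 3 bases remain and r′ = (3 − res) mod 3 is propagated.
The textbook form r′ = 3 − res would yield 3 at res = 0, so it is reduced
mod 3 to keep frames in {0,1,2}. Within one vertex, entries are keyed by
frame (start offset mod 3); when the same frame arrives twice, the smaller
start offset wins and annotated provenance dominates propagated — a frame
reachable from an annotated TSS counts as annotated for the negative-control
flag. Translation of a start exon begins at the TSS, not the exon start:
translating 5'UTR would emit non-coding peptides. In all-frames mode every
vertex is additionally seeded with frames {0,1,2} at offsets 0–2.

A stop codon truncates the emitted peptide (flagged `stop_interrupted`) and
blocks propagation of that frame across the edge. Frame propagation is
decided on the germline/reference base sequence (the empty somatic subset):
somatic combinations affect the emitted peptides but not the per-gene frame
state, which keeps the traversal linear in graph size instead of exponential
in mutation count. Peptides containing an ambiguous amino acid (X, from N
bases) are dropped with a logged count.

## Personalization

Germline SNVs are applied jointly (all present) or not at all; zygosity is
read but not modelled — phased application is a known limitation. Somatic
SNVs are enumerated per exon-pair span [g_vi^start, g_vj^end) in all 2ⁿ
subset combinations, lazily, in binary-counting order over mutations sorted
by position. A cap (default n ≤ 10, i.e. 1024 sequences) guards the
combinatorial blow-up; exceeding it is an error instructing the user to
raise the cap. Same-position collisions: overlapping variants within one set
are rejected at load; a somatic variant overrides a germline one with a log
line. Variant mode `all` unions the outputs of the four settings
(ref / germline / somatic / germline+somatic).

## k-mers, expression and filtering

Each peptide of length L yields its ≤ L − k + 1 windows (k = 9 default,
matching MHC-I ligand length; 8–11 are reasonable alternatives). A window is
a junction k-mer iff its codons cover bases on both sides of a junction.
Exon triplets are translated whenever an exon pair is shorter than 3k bases,
so no junction window is lost to short exons; pair records are still emitted
alongside (triplets supplement, never replace). Quadruplets are not
implemented — with the default exon-length regime triplets always suffice.

Junction k-mers are quantified by their junction read count, with the
minimum across junctions for windows spanning two; non-junction k-mers take
the minimum segment count over covered positions. The minimum is the most
conservative aggregator; the choice matters only for multi-segment windows.
When one k-mer string arises from several records, its per-sample expression
is the maximum over source contexts (most favorable evidence).

Filters are pure set operations on k-mer records, so annotation and
background subtraction commute. Presence ("any read level") is evaluated on
raw counts; the numeric thresholds R, T, t compare normalized values when
normalization is enabled (factor = library size / median foreground library
size). The background read-level clause removes a k-mer expressed with ≥ R
reads in ≥ 1 background sample by default; a recurrence variant
(`r_recurrence`) is exposed because the contract is ambiguous between one
and u samples. The MHC rank comparison is inclusive at the boundary
(rank ≤ threshold).

Background strategies: *re-quant* removes junction k-mers whose junction
position carries any background reads — junction-keyed and frame-blind, so
it retains candidates on junctions the background never expresses, including
known junctions reached in a novel frame. *All-frames* removes k-mers whose
sequence occurs in the all-frames translation of the background graph —
sequence-keyed, so it retains only candidates from junctions absent from the
background graph. Every all-frames survivor also survives re-quant: a
sequence that the background graph cannot produce implies its junction is
not in that graph and hence unread. The background graph is the annotation
augmented with exactly the novel junctions that background samples read.

## Tryptic digestion

Cleavage follows the Keil rule (after K or R, not before P), implemented via
pyteomics with offset tracking; zero missed cleavages by default
(configurable 0–2). Fragments tile the peptide; terminal fragments (peptide
start to first site, last site to end) are included, and a fragment spanning
the whole peptide is labeled n-terminal by convention. A fragment overlaps a
junction when it contains both codons flanking it (one codon when a codon
straddles the junction); a cleavage site coinciding exactly with a
codon-aligned junction therefore yields no junction fragment, which is the
faithful reading of "overlapping the junction position". The 7-aa minimum
fragment length (a common search-engine floor) applies only at FASTA export.

## Synthetic data

The generator emulates the pipeline's inputs at desk scale: by default 5
genes of 3–5 exons (45–90 nt, introns 30–60 nt), one coding transcript per
gene, 4 tumor and 8 normal samples, and one planted tumor-specific
exon-skipping junction per gene connecting existing exon boundaries. Read
counts are negative-binomial-shaped integers (mean 50, dispersion 0.3) —
purely to exercise thresholds, with no claim of distributional realism.
Planted junctions receive nonzero counts only in tumor samples
(`plant_in_background` leaks them into normals for negative tests). Library
sizes are column sums of the count table by construction.

Planted skips are in-frame (the skipped exon's length is a multiple of 3),
so the skip path translates in the annotated frame and the novel k-mers a
junction creates are exactly its junction-spanning windows; the truth table
is derived by direct string chunking of the skip path, independent of the
graph code, minus any window the annotated proteome also encodes (degenerate
straddling codons can reproduce an annotated string — such windows are not
novel and are excluded from truth). Two sequence guards keep the truth
well-defined: CDS codons are sampled stop-free, and the short 5'UTR and the
acceptor's first base are chosen so that neither UTR read-through in the
all-frames background nor the straddling codon can create a spurious stop.
Frame-shifting junctions, mid-exon TSS, planted stops, triplet-forcing short
exons, alternative 3' exons, isolated exons and the strategy-difference case
are covered by deterministic hand-built fixtures instead.

What passing these tests does not show: performance on real cohorts —
real splicing graphs are larger and noisier, frame shifts and truncations
are common, variants are not stop-free, and background cohorts are far from
exhaustive. The synthetic precision/recall of 1.0 certifies the mechanics of
generation and filtering, not biological discovery rates.

## Numerical and design choices

* Iteration order is fixed everywhere (vertices by coordinate in translation
  order, frames ascending, somatic subsets in binary-counting order, genes
  lexicographic), making outputs byte-identical across runs; all randomness
  lives in the synthetic-data seed.
* The redundancy rule drops a pair record whose exon pair is
  coordinate-dominated by another pair carrying the same frame set (its
  peptides are contained in the dominating pair's); applied per variant
  context, order-stable.
* Degenerate inputs: empty peptides (stop in the first codon) are not
  emitted; exons shorter than a frame offset simply carry no entry for that
  frame; junctions absent from count tables quantify as 0 with a log entry.
* Problem sizes in the bundled checks (200-gene oracle sweep, 9 × 1000
  frame-arithmetic pairs, 20-cohort nesting sweep) were chosen as the
  smallest scales at which every combinatorial case of the contracts is
  exercised.

## Known limitations

Single-nucleotide substitutions only (no indels, MNVs or phasing); no
4-exon peptides; no graph construction from BAM alignments; MHC binding and
MS search are consumed/exported as tables, never executed; heterozygous
germline variants are applied jointly rather than allele-resolved.
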