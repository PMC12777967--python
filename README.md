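# splicepep

Extraction of personalized, splicing-derived candidate peptides
(neoepitope candidates) from per-gene splicing graphs.

Tumor transcriptomes produce protein variability that goes beyond point
mutations: alternative exon and intron usage creates peptides that never
occur in the normal proteome. `splicepep` is for computational cancer
immunologists and proteogenomics analysts who want to turn RNA-seq evidence
of such splicing variation — together with a patient's germline and somatic
variants — into a filtered, MS-searchable set of candidate tumor-specific
peptides.

## The method

For a gene with transcripts t₁…t_k, the splicing graph is the DAG
G = (V, E) whose vertices are the distinct exons V = ⋃ᵢ Vᵢ (each exon an
interval [g_v^start, g_v^end)) and whose edges E = ⋃ᵢ Eᵢ are the observed
intron connections, optionally augmented with novel RNA-seq-supported
junctions. Translation is anchored at annotated CDS starts: each translation
start site g_t^start seeds a reading frame on every exon containing it.
Frames then propagate across edges: translating the coding span of exon v_i
at frame r leaves `res = (len − r) mod 3` residual bases, and the frame
propagated to the next exon is `r′ = (3 − res) mod 3` — the bases borrowed
from the acceptor exon to complete the straddling codon. Every connected
exon pair (and, when the pair is shorter than 3k bases, every exon triplet)
is translated in every active frame; a stop codon truncates the peptide and
blocks propagation of that frame.

Peptides are personalized by applying all germline variants jointly (g →
g^GM) and enumerating all 2ⁿ combinations of the n somatic mutations inside
each exon-pair span. Translated peptides are split into k-mers (k = 9 by
default; at most L − k + 1 per peptide) and filtered:

1. **annotation filter** — drop k-mers occurring in the annotated proteome;
2. **foreground rule** — keep k-mers read in the target sample or reaching
   ≥ 20 normalized reads anywhere in the tumor cohort (normalization factor
   = library size / median cohort library size);
3. **background subtraction** — either *re-quant* (drop junction k-mers
   whose junction carries any reads in the normal cohort) or *all-frames*
   (drop k-mers whose sequence occurs in the normal graph translated in all
   three frames); thresholds u (background recurrence) and R (background
   read level) give finer control, with u = 1 the strict complete-exclusion
   setting;
4. **cancer support** — keep k-mers with expression ≥ t in the target sample
   and ≥ T in at least l other tumor samples;
5. optional **MHC-binding rank** thresholding on an externally produced
   score table (top 2% by default).

Surviving junction k-mers are mapped back to their 2-/3-exon context
peptides and digested in silico with trypsin (cleavage after K/R, not before
P); the fragments covering a junction are exported as FASTA for
mass-spectrometry validation with external search engines.

## Worked example

`examples/03_cohort_filtering.py` simulates a small study — 5 genes, 4 tumor
and 8 normal samples, one planted tumor-specific exon-skipping junction per
gene — and runs the full filtering stack under both background strategies:

```
5 genes, 4 tumor + 8 normal samples, 41 planted tumor-specific junction 9-mers
  requant    41 candidates  precision=1.00 recall=1.00
  allframes  41 candidates  precision=1.00 recall=1.00
```

The 41 candidates are exactly the 9-mers spanning the planted junctions:
everything the annotation already encodes is removed by the annotation
filter, and junctions read in any normal sample are excluded by the
background step. `examples/04_tryptic_digestion.py` continues to the MS
export:

```
41 candidate junction 9-mers -> 5 tryptic junction-peptides
  FFPTYVEANAR                  junction=chr1:176:357 (internal)
  ...
```

one tryptic fragment per planted junction, each covering the codons that
straddle its splice site. The other examples show graph translation with a
novel junction (`01`) and variant personalization with 2ⁿ somatic
combinations (`02`).

The same pipeline is available from the shell:

```sh
splicepep simulate --seed 1 --n-genes 5 --out-dir data/
splicepep run-all --config config.yaml
```

where the YAML config lists the input paths (genome FASTA, annotation GTF,
count TSV, novel-junction TSV, optional VCFs and MHC score TSV) and any
parameter overrides (k, mode, variant_mode, strategy, u/R/T/l/t). Every run
writes a `manifest.json` recording input digests, parameters and per-stage
record counts.

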