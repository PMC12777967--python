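"""From candidate k-mers to MS-searchable tryptic junction-peptides.

Candidate junction 9-mers are mapped back to their 2-/3-exon context
peptides, digested with trypsin, and the fragments covering the junction are
exported for mass-spectrometry validation.
"""

from splicepep import FilterConfig, PipelineParams, run_pipeline_data
from splicepep.fixtures import SimulationConfig, simulate

data = simulate(SimulationConfig(seed=1, n_genes=5,
                                 germline_variants_per_gene=0,
                                 somatic_variants_per_gene=0))
params = PipelineParams(
    target_sample=data.foreground_samples[0],
    foreground_samples=data.foreground_samples,
    background_samples=data.background_samples,
    strategy="requant", variant_mode="ref",
    filter=FilterConfig(u=1, t=1.0))
res = run_pipeline_data(data.genome, data.genes, data.counts,
                        data.novel_junctions, None, params, stage="digest")

print(f"{len(res.candidates)} candidate junction 9-mers -> "
      f"{len(res.tryptic_entries)} tryptic junction-peptides")
for sample, key, context, frag in res.tryptic_entries[:5]:
    print(f"  {frag.sequence:<28} junction={key[0]}:{key[1]}:{key[2]} "
          f"({frag.terminal_kind})")
print("Each fragment is bounded by tryptic cleavage sites (or a peptide")
print("terminus) and covers the codons flanking its splice junction, so a")
print("spectral match would support the junction at the protein level.")
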