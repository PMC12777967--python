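"""Personalize translation with germline and somatic variants.

All germline variants are applied jointly; somatic mutations are enumerated
in every subset combination (2^n sequences for n mutations in a span).
"""

from splicepep import GenomeSequence, Transcript, Variant, build_graph
from splicepep.genome_io import VariantSet
from splicepep.frames import anchor_frames, collect_translation_tuples
from splicepep.translate import traverse
from splicepep.variants import VariantEngine

seq_i, seq_j = "ATGGCAGGATTCAAA", "TTTGGGAAACACGAG"
genome = GenomeSequence("chrT", seq_i + "G" * 10 + seq_j)
e1, e2 = (0, 15), (25, 40)
tx = Transcript("t1", "demo", "chrT", "+", exons=(e1, e2),
                cds_regions=(e1, e2), cds_frames=(0, 0))
graph = build_graph([tx])
state = anchor_frames(graph, collect_translation_tuples([tx])[0])

variants = VariantSet(
    sample_id="patient_1",
    germline=[Variant("chrT", 4, "C", "T")],
    somatic=[Variant("chrT", 7, "G", "C"), Variant("chrT", 27, "T", "A")],
)

for mode in ("ref", "germline", "somatic", "germline_somatic"):
    engine = VariantEngine(genome, variants, mode)
    records = traverse(graph, state, engine, mode="annotated", k=9)
    peptides = sorted({r.peptide for r in records})
    print(f"{mode:<17} {len(records)} records -> {peptides}")
print("ref/germline give one sequence each; the somatic modes enumerate")
print("2^2 = 4 mutation subsets, so 4 records per traversal of the pair.")
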