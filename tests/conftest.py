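"""Shared fixtures and independent oracles for the test suite.

The oracle translator below uses only the standard codon table data and plain
string chunking; it deliberately shares no code path with the package's
translation machinery.
"""

from __future__ import annotations

import pytest
from Bio.Data.CodonTable import standard_dna_table

from splicepep.fixtures import SimulationConfig, make_edge_cases, simulate
from splicepep.frames import anchor_frames, collect_translation_tuples
from splicepep.splice_graph import build_graph
from splicepep.translate import traverse
from splicepep.variants import VariantEngine

CODON = dict(standard_dna_table.forward_table)
STOPS = set(standard_dna_table.stop_codons)
_COMP = str.maketrans("ACGTN", "TGCAN")


def oracle_translate(dna: str) -> str:
    """Chunk codons from the front, stop at the first stop codon."""
    out = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i : i + 3]
        if codon in STOPS:
            break
        out.append(CODON.get(codon, "X"))
    return "".join(out)


def oracle_revcomp(dna: str) -> str:
    return dna.translate(_COMP)[::-1]


def oracle_windows(protein: str, k: int) -> set[str]:
    return {protein[w : w + k] for w in range(max(0, len(protein) - k + 1))}


def run_annotated(ns, mode: str = "annotated", k: int = 9, graph=None):
    """Build graph + frames for an edge-case namespace and traverse it."""
    graph = graph if graph is not None else build_graph(ns.transcripts)
    tuples, _ = collect_translation_tuples(ns.transcripts)
    state = anchor_frames(graph, tuples)
    contig = ns.transcripts[0].contig
    engine = VariantEngine(ns.genome[contig], None, "ref")
    return traverse(graph, state, engine, mode=mode, k=k)


@pytest.fixture(scope="session")
def edge_cases():
    return make_edge_cases()


@pytest.fixture(scope="session")
def sim_noiseless():
    """Small noiseless cohort: no variants, one planted skip per gene."""
    return simulate(SimulationConfig(
        seed=1, n_genes=3, germline_variants_per_gene=0,
        somatic_variants_per_gene=0))


@pytest.fixture(scope="session")
def sim_default():
    return simulate(SimulationConfig(seed=11, n_genes=3))
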