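"""Graph translation against independent string-chunking oracles."""

from collections import Counter

import numpy as np
import pytest

from splicepep.frames import PROPAGATED, FrameEntry
from splicepep.genome_io import GenomeSequence, Transcript
from splicepep.splice_graph import build_graph
from splicepep.translate import (
    remove_redundant,
    translate_dna,
    translate_pair,
    translate_transcript,
    traverse,
)
from splicepep.variants import PersonalizedSequence, VariantEngine

from conftest import oracle_translate, oracle_windows, run_annotated

BASES = np.array(list("ACGT"))


def _random_dna(rng, n):
    return "".join(rng.choice(BASES, size=n))


def _pair_setup(seq_i, seq_j, intron=20):
    """Two-exon plus-strand graph over an explicit genome."""
    genome = GenomeSequence("chrT", seq_i + "G" * intron + seq_j)
    e1 = (0, len(seq_i))
    e2 = (len(seq_i) + intron, len(seq_i) + intron + len(seq_j))
    t = Transcript("t", "g", "chrT", "+", exons=(e1, e2))
    return genome, build_graph([t])


class TestTranslateDna:
    @pytest.mark.parametrize("dna,expected", [
        ("ATGGCA", ("MA", False)),
        ("ATGTAA", ("M", True)),
        ("", ("", False)),
        ("ATGGC", ("M", False)),        # trailing bases ignored
        ("ATGNNNGCA", ("MXA", False)),  # ambiguity -> X
    ])
    def test_examples(self, dna, expected):
        assert translate_dna(dna) == expected


class TestTranslatePair:
    def test_simple_junction_peptide(self):
        genome, graph = _pair_setup("ATGGCA", "TTTGGG")
        view = PersonalizedSequence(genome)
        rec, r_next = translate_pair(graph, view, 0, 1,
                                     FrameEntry(0, 0, PROPAGATED))
        assert rec.peptide == "MAFG"
        assert r_next == 0

    def test_straddling_codon_borrows_bases(self):
        genome, graph = _pair_setup("ATGGCAT", "TTTGGG")
        view = PersonalizedSequence(genome)
        rec, r_next = translate_pair(graph, view, 0, 1,
                                     FrameEntry(0, 0, PROPAGATED))
        # oracle: chunk the concatenated coding string
        assert rec.peptide == oracle_translate("ATGGCAT" + "TTTGGG")
        assert r_next == 2

    def test_equals_concatenation_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            li = int(rng.integers(3, 60))
            lj = int(rng.integers(3, 60))
            r = int(rng.integers(0, 3))
            if r >= li:
                continue
            seq_i, seq_j = _random_dna(rng, li), _random_dna(rng, lj)
            genome, graph = _pair_setup(seq_i, seq_j)
            view = PersonalizedSequence(genome)
            rec, r_next = translate_pair(graph, view, 0, 1,
                                         FrameEntry(r, r, PROPAGATED))
            expected = oracle_translate(seq_i[r:] + seq_j)
            if expected == "":
                assert rec is None
            else:
                assert rec.peptide == expected
            stopped = "*" in _naive_aa(seq_i[r:] + seq_j)
            assert (r_next is None) == stopped

    def test_planted_stop_truncates_and_blocks_propagation(self, edge_cases):
        ns = edge_cases["stop_at_junction"]
        records = run_annotated(ns)
        (rec,) = records
        assert rec.peptide == "MA"
        assert rec.stop_interrupted
        # the downstream exon never becomes a donor: no record starts there
        assert all(r.exon_coords[0][0] < ns.exon_intervals[1][0]
                   for r in records)


def _naive_aa(dna):
    from conftest import CODON, STOPS
    out = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        c = dna[i : i + 3]
        out.append("*" if c in STOPS else CODON.get(c, "X"))
    return "".join(out)


class TestTriplets:
    def test_triplet_generated_when_pair_short(self, edge_cases):
        records = run_annotated(edge_cases["short_pair_triplet"])
        by_len = Counter(len(r.exon_coords) for r in records)
        assert by_len[3] == 1 and by_len[2] == 2

    def test_triplet_equals_concatenation_oracle(self, edge_cases):
        ns = edge_cases["short_pair_triplet"]
        (triplet,) = [r for r in run_annotated(ns) if len(r.exon_coords) == 3]
        genome = ns.genome["chrT"].sequence
        coding = "".join(genome[s:e] for s, e in ns.exon_intervals)
        assert triplet.peptide == oracle_translate(coding)
        assert len(triplet.junction_coords) == 2

    def test_no_triplet_when_pair_suffices(self):
        rng = np.random.default_rng(7)
        seq_i, seq_j = _random_dna(rng, 45), _random_dna(rng, 45)
        genome, graph = _pair_setup("ATG" + seq_i, seq_j)
        t = Transcript("t", "g", "chrT", "+", exons=tuple(
            v.interval for v in graph.vertices),
            cds_regions=tuple(v.interval for v in graph.vertices),
            cds_frames=(0, 0))
        records = run_annotated(
            type("NS", (), {"genome": {"chrT": genome},
                            "transcripts": [t]})())
        assert all(len(r.exon_coords) == 2 for r in records)


class TestTraverse:
    def test_annotated_covers_transcript_translation(self, sim_noiseless):
        d = sim_noiseless
        for gene_id, (tx,) in ((g, tuple(t)) for g, t in d.genes.items()):
            records = run_annotated(
                type("NS", (), {"genome": d.genome, "transcripts": [tx]})())
            covered = set()
            for rec in records:
                covered |= oracle_windows(rec.peptide, 9)
            protein, _ = translate_transcript(tx, d.genome[tx.contig])
            assert oracle_windows(protein, 9) <= covered

    def test_all_frames_superset_of_annotated(self, sim_noiseless):
        # compared on the k-mer window universe: the all-frames candidate
        # space contains everything the annotated frames produce
        d = sim_noiseless
        for gene_id, (tx,) in ((g, tuple(t)) for g, t in d.genes.items()):
            ns = type("NS", (), {"genome": d.genome, "transcripts": [tx]})()
            annotated = set()
            for r in run_annotated(ns):
                annotated |= oracle_windows(r.peptide, 9)
            allframes = set()
            for r in run_annotated(ns, mode="all_frames"):
                allframes |= oracle_windows(r.peptide, 9)
            assert annotated <= allframes

    def test_noncoding_gene_empty_in_annotated_mode(self):
        genome = {"chrT": GenomeSequence("chrT", "ATGGCAGGA" * 10)}
        t = Transcript("t", "g", "chrT", "+", exons=((0, 30), (50, 80)))
        graph = build_graph([t])
        from splicepep.frames import FrameState
        engine = VariantEngine(genome["chrT"], None, "ref")
        assert traverse(graph, FrameState(), engine, mode="annotated") == []
        assert traverse(graph, FrameState(), engine, mode="all_frames") != []

    def test_no_stop_symbols_and_truncation_flagged(self, sim_default):
        d = sim_default
        for gene_id, (tx,) in ((g, tuple(t)) for g, t in d.genes.items()):
            ns = type("NS", (), {"genome": d.genome, "transcripts": [tx]})()
            for rec in run_annotated(ns, mode="all_frames"):
                assert "*" not in rec.peptide

    def test_strand_symmetry(self, edge_cases):
        m = edge_cases["minus_strand"]
        minus = Counter(r.peptide for r in run_annotated(m.minus))
        plus = Counter(r.peptide for r in run_annotated(m.plus))
        assert minus == plus

    def test_isolated_exon_translated_alone(self, edge_cases):
        ns = edge_cases["isolated_exon"]
        singles = [r for r in run_annotated(ns) if len(r.exon_coords) == 1]
        assert [r.exon_coords[0] for r in singles] == [ns.isolated_interval]
        assert singles[0].junction_coords == ()

    def test_deterministic_output(self, sim_default):
        d = sim_default
        tx = d.genes["gene_0"][0]
        ns = type("NS", (), {"genome": d.genome, "transcripts": [tx]})()
        run1 = [(r.peptide, r.exon_coords, r.frame_used)
                for r in run_annotated(ns, mode="all_frames")]
        run2 = [(r.peptide, r.exon_coords, r.frame_used)
                for r in run_annotated(ns, mode="all_frames")]
        assert run1 == run2


class TestRedundancy:
    def test_dominated_pair_dropped(self, edge_cases):
        ns = edge_cases["alt_three_prime"]
        records = run_annotated(ns)
        kept = remove_redundant(records)
        pairs = {r.vertex_intervals for r in kept}
        assert ns.dominating in pairs
        assert ns.dominated not in pairs
        # dominated peptide windows are contained in the dominating record
        (dom,) = [r for r in records if r.vertex_intervals == ns.dominating]
        (sub,) = [r for r in records if r.vertex_intervals == ns.dominated]
        assert oracle_windows(sub.peptide, 6) <= oracle_windows(dom.peptide, 6)

    def test_different_frames_both_kept(self, edge_cases):
        ns = edge_cases["alt_three_prime"]
        records = run_annotated(ns, mode="all_frames")
        kept = remove_redundant(records)
        # all-frames assigns {0,1,2} everywhere: frame sets equal, dominance
        # still applies; annotated single-frame records differ per pair when
        # frames differ, so craft the direct check instead
        from splicepep.translate import PeptideRecord

        def rec(pair, frame):
            return PeptideRecord(
                gene_id="g", contig="c", strand="+", peptide="MKT",
                exon_coords=pair, vertex_intervals=pair,
                junction_coords=(("c", pair[0][1], pair[1][0]),),
                frame_used=frame, frame_annotated=True,
                junction_annotated=(True,), stop_interrupted=False,
                boundaries=(6,))
        a = rec(((10, 50), (100, 150)), 0)
        b = rec(((20, 50), (100, 140)), 1)
        assert remove_redundant([a, b]) == [a, b]

    def test_spec_dominance_example(self):
        from splicepep.translate import PeptideRecord

        def rec(pair):
            return PeptideRecord(
                gene_id="g", contig="c", strand="+", peptide="MKT",
                exon_coords=pair, vertex_intervals=pair,
                junction_coords=(("c", pair[0][1], pair[1][0]),),
                frame_used=0, frame_annotated=True,
                junction_annotated=(True,), stop_interrupted=False,
                boundaries=(6,))
        a = rec(((10, 50), (100, 150)))
        b = rec(((20, 50), (100, 140)))
        assert remove_redundant([a, b]) == [a]

    def test_no_dominance_identity(self):
        from splicepep.translate import PeptideRecord

        def rec(pair):
            return PeptideRecord(
                gene_id="g", contig="c", strand="+", peptide="MKT",
                exon_coords=pair, vertex_intervals=pair,
                junction_coords=(("c", pair[0][1], pair[1][0]),),
                frame_used=0, frame_annotated=True,
                junction_annotated=(True,), stop_interrupted=False,
                boundaries=(6,))
        a = rec(((10, 50), (100, 150)))
        b = rec(((60, 90), (100, 150)))
        assert remove_redundant([a, b]) == [a, b]
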