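"""Graph traversal and translation of exon pairs, triplets and isolated exons.

Connected exon pairs are translated in every active reading frame, with the
reading frame propagated across each junction as r' = (3 - res) mod 3 where
res is the leftover-base count of the donor exon. Codons straddling a
junction borrow their missing bases from the acceptor exon. Translation stops
at the first stop codon; a truncated frame is not propagated further.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .frames import ANNOTATED, PROPAGATED, FrameEntry, FrameState, propagate
from .kmers import needs_triplet
from .splice_graph import SplicingGraph, following_exons, isolated_exons
from .variants import PersonalizedSequence, VariantEngine

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate_dna(dna: str) -> tuple[str, bool]:
    """Translate DNA by the standard code, stopping at the first stop codon.

    Trailing 1-2 bases are ignored. Returns the peptide and a flag that is
    true iff a stop codon was reached. Ambiguity codes (N) yield 'X'.
    """
    usable = len(dna) - len(dna) % 3
    if usable == 0:
        return "", False
    aa = str(Seq(dna[:usable]).translate())
    stop = aa.find("*")
    if stop >= 0:
        return aa[:stop], True
    return aa, False


@dataclass(frozen=True)
class PeptideRecord:
    """A translated 1-, 2- or 3-exon peptide with its provenance metadata.

    ``exon_coords`` are the translated genomic spans (forward coordinates, in
    translation order); ``vertex_intervals`` the full exon intervals they come
    from. ``junction_coords`` hold one ``(contig, donor_end, acceptor_start)``
    key per junction (exon count - 1). ``boundaries`` are the cumulative base
    counts of the coding string at each junction, used to locate
    junction-straddling codons.
    """

    gene_id: str
    contig: str
    strand: str
    peptide: str
    exon_coords: tuple[tuple[int, int], ...]
    vertex_intervals: tuple[tuple[int, int], ...]
    junction_coords: tuple[tuple[str, int, int], ...]
    frame_used: int
    frame_annotated: bool
    junction_annotated: tuple[bool, ...]
    stop_interrupted: bool
    mutation_subset: tuple = ()
    variant_mode: str = "ref"
    boundaries: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if "*" in self.peptide:
            raise ValueError("peptide contains a stop symbol")
        if len(self.peptide) < 1:
            raise ValueError("empty peptide")
        if len(self.junction_coords) != len(self.exon_coords) - 1:
            raise ValueError("junction count must be exon count - 1")

    def junction_aa_span(self, m: int) -> tuple[int, int] | None:
        """Indices of the codons flanking junction ``m``: (last codon with
        donor bases, first codon with acceptor bases); equal for a straddling
        codon. None when the translated peptide does not reach across."""
        b = self.boundaries[m]
        if b == 0 or 3 * len(self.peptide) <= b:
            return None
        return ((b - 1) // 3, b // 3)

    def covers_junction(self, m: int) -> bool:
        return self.junction_aa_span(m) is not None

    def genomic_intervals(self, b0: int, b1: int) -> list[tuple[int, int]]:
        """Forward-genomic intervals covered by coding-string bases [b0, b1)."""
        out: list[tuple[int, int]] = []
        offset = 0
        for (gs, ge) in self.exon_coords:
            seg_len = ge - gs
            lo, hi = max(b0, offset), min(b1, offset + seg_len)
            if lo < hi:
                if self.strand == "+":
                    out.append((gs + (lo - offset), gs + (hi - offset)))
                else:
                    out.append((ge - (hi - offset), ge - (lo - offset)))
            offset += seg_len
        return out


class TranslationDropCounter:
    """Counts peptides dropped for containing ambiguous amino acids."""

    def __init__(self) -> None:
        self.ambiguous = 0


_drop_counter = TranslationDropCounter()


def _coding_segment(view: PersonalizedSequence, strand: str, vertex,
                    skip: int) -> tuple[str, tuple[int, int]]:
    """Sequence and forward-genomic span of a vertex's coding part, where
    ``skip`` bases are trimmed from the translation-direction start."""
    if strand == "+":
        span = (vertex.start + skip, vertex.end)
        return view.fetch(*span), span
    span = (vertex.start, vertex.end - skip)
    return reverse_complement(view.fetch(*span)), span


def translate_path(
    graph: SplicingGraph,
    view: PersonalizedSequence,
    vertex_ids: list[int],
    entry: FrameEntry,
    mutation_subset: tuple = (),
    variant_mode: str = "ref",
) -> tuple[PeptideRecord | None, bool]:
    """Translate a 1-, 2- or 3-exon path starting at ``entry`` on the first
    vertex. Returns (record or None, stop_flag)."""
    seqs: list[str] = []
    spans: list[tuple[int, int]] = []
    for idx, vid in enumerate(vertex_ids):
        v = graph.vertex(vid)
        skip = entry.start if idx == 0 else 0
        seq, span = _coding_segment(view, graph.strand, v, skip)
        seqs.append(seq)
        spans.append(span)
    coding = "".join(seqs)
    peptide, stop = translate_dna(coding)
    if not peptide:
        return None, stop
    if "X" in peptide:
        _drop_counter.ambiguous += 1
        logger.info("dropped peptide with ambiguous amino acid in %s",
                    graph.gene_id)
        return None, stop

    junctions = []
    annotated_flags = []
    for a, b in zip(vertex_ids, vertex_ids[1:]):
        va, vb = graph.vertex(a), graph.vertex(b)
        left, right = (va, vb) if va.start <= vb.start else (vb, va)
        junctions.append((graph.contig, left.end, right.start))
        annotated_flags.append((left.end, right.start) in graph.annotated_junctions)

    boundaries = []
    total = 0
    for seq in seqs[:-1]:
        total += len(seq)
        boundaries.append(total)

    record = PeptideRecord(
        gene_id=graph.gene_id,
        contig=graph.contig,
        strand=graph.strand,
        peptide=peptide,
        exon_coords=tuple(spans),
        vertex_intervals=tuple(graph.vertex(v).interval for v in vertex_ids),
        junction_coords=tuple(junctions),
        frame_used=entry.frame,
        frame_annotated=entry.provenance == ANNOTATED,
        junction_annotated=tuple(annotated_flags),
        stop_interrupted=stop,
        mutation_subset=mutation_subset,
        variant_mode=variant_mode,
        boundaries=tuple(boundaries),
    )
    return record, stop


def translate_pair(
    graph: SplicingGraph,
    view: PersonalizedSequence,
    v_i: int,
    v_j: int,
    entry: FrameEntry,
    mutation_subset: tuple = (),
    variant_mode: str = "ref",
) -> tuple[PeptideRecord | None, int | None]:
    """Translate connected pair (v_i, v_j); returns (record, propagated frame).

    The propagated frame is None when a stop codon truncates the translation.
    """
    record, stop = translate_path(graph, view, [v_i, v_j], entry,
                                  mutation_subset, variant_mode)
    if stop:
        return record, None
    coding_length = graph.vertex(v_i).length - entry.start
    _, r_next = propagate(coding_length, 0)
    return record, r_next


def translate_triplet(
    graph: SplicingGraph,
    view: PersonalizedSequence,
    v_i: int,
    v_j: int,
    v_l: int,
    entry: FrameEntry,
    mutation_subset: tuple = (),
    variant_mode: str = "ref",
) -> PeptideRecord | None:
    """Translate connected triplet (v_i, v_j, v_l); no frame is propagated
    here (pair translation owns propagation)."""
    record, _ = translate_path(graph, view, [v_i, v_j, v_l], entry,
                               mutation_subset, variant_mode)
    return record


def _span(graph: SplicingGraph, vertex_ids: list[int]) -> tuple[int, int]:
    starts = [graph.vertex(v).start for v in vertex_ids]
    ends = [graph.vertex(v).end for v in vertex_ids]
    return min(starts), max(ends)


def traverse(
    graph: SplicingGraph,
    frame_state: FrameState,
    variant_engine: VariantEngine,
    mode: str = "annotated",
    k: int = 9,
) -> list[PeptideRecord]:
    """Translate all connected pairs, triggered triplets and isolated exons.

    ``mode='annotated'`` seeds frames only from the given CDS-anchored state;
    ``mode='all_frames'`` additionally seeds {0,1,2} on every vertex (frames
    that coincide with an annotated anchor keep annotated provenance). The
    iteration order (translation-order vertices, ascending frames, successors
    in strand order, somatic subsets in binary-counting order) is fixed, so
    output is deterministic.
    """
    if mode not in ("annotated", "all_frames"):
        raise ValueError(f"mode {mode!r} not in {{'annotated', 'all_frames'}}")
    state = frame_state.copy()
    if mode == "all_frames":
        for v in graph.vertices:
            for r in range(3):
                if r < v.length:
                    state.add(v.vertex_id, FrameEntry(r, r, PROPAGATED))

    records: list[PeptideRecord] = []
    isolated = set(isolated_exons(graph))
    for v_i in graph.translation_order():
        succs = following_exons(graph, v_i)
        for entry in state.entries(v_i):
            if v_i in isolated:
                rec, _ = translate_path(
                    graph, variant_engine.base_view(), [v_i], entry,
                    (), variant_engine.mode)
                if rec is not None:
                    records.append(rec)
                continue
            for v_j in succs:
                propagated: int | None = None
                for subset, view in variant_engine.combinations(
                        *_span(graph, [v_i, v_j])):
                    rec, r_next = translate_pair(
                        graph, view, v_i, v_j, entry, subset,
                        variant_engine.mode)
                    if rec is not None:
                        records.append(rec)
                    if not subset:
                        propagated = r_next
                if propagated is not None:
                    state.add(v_j, FrameEntry(propagated, propagated, PROPAGATED))
                if needs_triplet(graph.vertex(v_i), graph.vertex(v_j), k):
                    for v_l in following_exons(graph, v_j):
                        for subset, view in variant_engine.combinations(
                                *_span(graph, [v_i, v_j, v_l])):
                            rec = translate_triplet(
                                graph, view, v_i, v_j, v_l, entry, subset,
                                variant_engine.mode)
                            if rec is not None:
                                records.append(rec)
    return records


def remove_redundant(records: list[PeptideRecord]) -> list[PeptideRecord]:
    """Drop pair records whose exon pair is coordinate-dominated by another
    pair carrying the same reading-frame set.

    Pair (v_i, v_j) is dominated by (v_s, v_t) when, in forward order,
    v_i.start >= v_s.start, v_i.end == v_s.end, v_j.start == v_t.start and
    v_j.end <= v_t.end: its peptides are suffix/prefix-contained in the
    dominating pair's. Output order is stable.
    """
    def forward_pair(rec: PeptideRecord):
        a, b = rec.vertex_intervals
        return (a, b) if a[0] <= b[0] else (b, a)

    frame_sets: dict[tuple, set[int]] = {}
    for rec in records:
        if len(rec.vertex_intervals) != 2:
            continue
        key = (rec.variant_mode, rec.mutation_subset, forward_pair(rec))
        frame_sets.setdefault(key, set()).add(rec.frame_used)

    dominated: set[tuple] = set()
    for key, frames in frame_sets.items():
        mode, subset, (left, right) = key
        for other, oframes in frame_sets.items():
            if other == key or other[0] != mode or other[1] != subset:
                continue
            oleft, oright = other[2]
            if (left[0] >= oleft[0] and left[1] == oleft[1]
                    and right[0] == oright[0] and right[1] <= oright[1]
                    and frames == oframes):
                dominated.add(key)
                break

    out = []
    for rec in records:
        if len(rec.vertex_intervals) == 2:
            key = (rec.variant_mode, rec.mutation_subset, forward_pair(rec))
            if key in dominated:
                continue
        out.append(rec)
    return out


def translate_transcript(tx, genome_or_view) -> tuple[str, bool]:
    """Linear translation of one annotated transcript's spliced CDS.

    Used to build the annotated-peptide background set. Accepts a
    GenomeSequence or a PersonalizedSequence.
    """
    view = (genome_or_view if isinstance(genome_or_view, PersonalizedSequence)
            else PersonalizedSequence(genome_or_view, {}))
    if not tx.is_coding:
        return "", False
    parts = [view.fetch(s, e) for s, e in tx.cds_regions]
    if tx.strand == "+":
        coding = "".join(parts)
        phase = tx.cds_frames[0] or 0
    else:
        coding = "".join(reverse_complement(p) for p in reversed(parts))
        phase = tx.cds_frames[-1] or 0
    return translate_dna(coding[phase:])


def annotated_proteins(genes: dict, genome: dict) -> list[str]:
    """Translations of all coding transcripts in the annotation."""
    proteins = []
    for gene_id in sorted(genes):
        for tx in genes[gene_id]:
            if tx.is_coding:
                protein, _ = translate_transcript(tx, genome[tx.contig])
                if protein:
                    proteins.append(protein)
    return proteins
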