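"""Translation-start anchoring and reading-frame propagation arithmetic.

A reading frame here is the offset in {0,1,2} at which codon chunking begins
within an exon, measured in the translation direction. Annotated frames come
from CDS starts (translation start sites, TSS); propagated frames arrive over
splice-graph edges. Each vertex holds at most three distinct frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

ANNOTATED = "annotated"
PROPAGATED = "propagated"


@dataclass(frozen=True)
class TranslationTuple:
    """A translation start site and its seed reading frames."""

    tss_position: int
    seed_frames: frozenset[int]

    def __post_init__(self) -> None:
        if not self.seed_frames:
            raise ValueError("seed_frames must be non-empty")
        if not self.seed_frames <= {0, 1, 2}:
            raise ValueError(f"frames outside {{0,1,2}}: {self.seed_frames}")


@dataclass(frozen=True)
class FrameEntry:
    """One active reading frame on a vertex.

    ``start`` is the offset (translation direction) within the vertex at which
    codon chunking begins: the TSS offset for annotated entries, the
    propagated frame r' for propagated ones. ``frame`` is ``start mod 3`` and
    is the identity under which entries are deduplicated.
    """

    frame: int
    start: int
    provenance: str

    def __post_init__(self) -> None:
        if self.frame != self.start % 3:
            raise ValueError("frame must equal start mod 3")


class FrameState:
    """Per-vertex sets of active reading frames; frames only accumulate.

    When the same frame reaches a vertex twice, the entry with the smaller
    start offset wins and annotated provenance dominates propagated (a frame
    reached both ways counts as annotated).
    """

    def __init__(self) -> None:
        self._by_vertex: dict[int, dict[int, FrameEntry]] = {}

    def add(self, vertex_id: int, entry: FrameEntry) -> None:
        slot = self._by_vertex.setdefault(vertex_id, {})
        current = slot.get(entry.frame)
        if current is None:
            slot[entry.frame] = entry
            return
        provenance = ANNOTATED if ANNOTATED in (current.provenance,
                                                entry.provenance) else PROPAGATED
        start = min(current.start, entry.start)
        slot[entry.frame] = FrameEntry(entry.frame, start, provenance)

    def entries(self, vertex_id: int) -> list[FrameEntry]:
        return sorted(self._by_vertex.get(vertex_id, {}).values(),
                      key=lambda e: e.frame)

    def frames(self, vertex_id: int) -> frozenset[int]:
        return frozenset(self._by_vertex.get(vertex_id, {}))

    def vertices(self) -> list[int]:
        return sorted(self._by_vertex)

    def copy(self) -> "FrameState":
        other = FrameState()
        other._by_vertex = {v: dict(slots) for v, slots in self._by_vertex.items()}
        return other


def collect_translation_tuples(transcripts) -> tuple[list[TranslationTuple], int]:
    """One translation tuple per coding transcript; non-coding are skipped.

    On the plus strand the TSS is the first CDS start, on the minus strand the
    last CDS end. The seed frame is 0 unless the GTF frame column of the
    translation-start CDS says otherwise.
    """
    tuples: list[TranslationTuple] = []
    skipped = 0
    for tx in transcripts:
        if not tx.is_coding:
            skipped += 1
            logger.info("transcript %s has no CDS; skipped", tx.transcript_id)
            continue
        if tx.strand == "+":
            tss = tx.cds_regions[0][0]
            phase = tx.cds_frames[0]
        else:
            tss = tx.cds_regions[-1][1]
            phase = tx.cds_frames[-1]
        frame = int(phase) if phase else 0
        tuples.append(TranslationTuple(tss, frozenset({frame})))
    return tuples, skipped


def anchor_frames(graph, tuples) -> FrameState:
    """Assign seed frames to every graph exon containing a TSS.

    Containment is half-open in the translation direction: on the plus strand
    a TSS equal to an exon end is outside the exon; on the minus strand the
    TSS is an interval end and anchors to the exon it closes.
    """
    state = FrameState()
    for tup in tuples:
        anchored = False
        pos = tup.tss_position if graph.strand == "+" else tup.tss_position - 1
        for v in graph.vertices:
            if not (v.start <= pos < v.end):
                continue
            offset = (tup.tss_position - v.start if graph.strand == "+"
                      else v.end - tup.tss_position)
            for seed in sorted(tup.seed_frames):
                start = offset + seed
                if start >= v.length:
                    continue
                state.add(v.vertex_id, FrameEntry(start % 3, start, ANNOTATED))
                anchored = True
        if not anchored:
            raise ValueError(
                f"TSS {tup.tss_position} of gene {graph.gene_id} lies outside "
                "every graph exon (annotation/graph mismatch)"
            )
    return state


def propagate(coding_length: int, r: int) -> tuple[int, int]:
    """Frame-propagation arithmetic for one vertex.

    ``coding_length`` is the translated span of the vertex (from its
    translation start to its end); ``r`` the active frame. Returns
    ``res = (coding_length - r) mod 3``, the number of leftover bases, and
    ``r_next = (3 - res) mod 3``, the frame propagated downstream (the bases
    borrowed from the next exon to complete the straddling codon).
    """
    if coding_length < 0:
        raise ValueError("coding_length must be >= 0")
    if r not in (0, 1, 2):
        raise ValueError(f"frame {r} outside {{0,1,2}}")
    res = (coding_length - r) % 3
    r_next = (3 - res) % 3
    return res, r_next
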