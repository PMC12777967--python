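"""Per-gene splicing graph: exon vertices, intron edges, strand-aware queries.

The graph is a DAG over the union of all exon intervals of a gene's
transcripts. Edges connect exons that appear consecutively in at least one
transcript, or that are joined by an observed novel junction. Edges are
stored in forward-genome order ``(left, right)`` with
``left.end <= right.start``; minus-strand traversal walks them in reverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)


class GraphError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class ExonVertex:
    start: int
    end: int
    vertex_id: int = field(compare=False, default=-1)

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise GraphError(f"exon [{self.start},{self.end}) has length < 1")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SplicingGraph:
    gene_id: str
    contig: str
    strand: str
    vertices: list[ExonVertex]
    edges: set[tuple[int, int]]          # (left_id, right_id), forward order
    annotated_junctions: set[tuple[int, int]]  # (donor_end, acceptor_start)

    def __post_init__(self) -> None:
        for i, j in self.edges:
            left, right = self.vertices[i], self.vertices[j]
            if left.end > right.start:
                raise GraphError(
                    f"edge ({left.interval},{right.interval}) violates "
                    "forward order (graph would be cyclic)"
                )

    def vertex(self, vertex_id: int) -> ExonVertex:
        return self.vertices[vertex_id]

    def junction_key(self, i: int, j: int) -> tuple[str, int, int]:
        """Junction key of edge (i, j) in forward coordinates."""
        return (self.contig, self.vertices[i].end, self.vertices[j].start)

    def translation_order(self) -> list[int]:
        """Vertex ids in read-strand (translation) order."""
        order = sorted(range(len(self.vertices)),
                       key=lambda i: self.vertices[i].interval)
        return order if self.strand == "+" else order[::-1]


def build_graph(transcripts) -> SplicingGraph:
    """Build the splicing graph from one gene's transcripts.

    Vertices are the distinct exon intervals across all transcripts; edges are
    exactly the consecutive-exon connections each transcript implies.
    """
    if not transcripts:
        raise GraphError("need at least one transcript")
    gene_ids = {t.gene_id for t in transcripts}
    strands = {t.strand for t in transcripts}
    contigs = {t.contig for t in transcripts}
    if len(gene_ids) != 1:
        raise GraphError(f"mixed genes {gene_ids}")
    if len(strands) != 1:
        raise GraphError(f"mixed strands {strands} in gene {gene_ids}")
    if len(contigs) != 1:
        raise GraphError(f"mixed contigs {contigs} in gene {gene_ids}")

    intervals = sorted({iv for t in transcripts for iv in t.exons})
    vertices = [ExonVertex(s, e, vertex_id=i) for i, (s, e) in enumerate(intervals)]
    index = {iv: i for i, iv in enumerate(intervals)}

    edges: set[tuple[int, int]] = set()
    junctions: set[tuple[int, int]] = set()
    for t in transcripts:
        for a, b in zip(t.exons, t.exons[1:]):
            if a[1] > b[0]:
                raise GraphError(
                    f"transcript {t.transcript_id} has overlapping consecutive exons"
                )
            edges.add((index[a], index[b]))
            junctions.add((a[1], b[0]))
    return SplicingGraph(
        gene_id=next(iter(gene_ids)),
        contig=next(iter(contigs)),
        strand=next(iter(strands)),
        vertices=vertices,
        edges=edges,
        annotated_junctions=junctions,
    )


def augment_graph(graph: SplicingGraph, novel_junctions) -> tuple[SplicingGraph, int]:
    """Insert novel junctions whose endpoints match existing exon boundaries.

    Junctions that match no vertex boundary are rejected (counted and logged),
    never invented as new vertices. Returns the augmented graph and the number
    of rejected junctions. Re-adding a present junction is a no-op.
    """
    edges = set(graph.edges)
    rejected = 0
    for entry in novel_junctions:
        if len(entry) == 3:
            contig, donor_end, acceptor_start = entry
            if contig != graph.contig:
                continue
        else:
            donor_end, acceptor_start = entry
        lefts = [v.vertex_id for v in graph.vertices if v.end == donor_end]
        rights = [v.vertex_id for v in graph.vertices if v.start == acceptor_start]
        added = False
        for i in lefts:
            for j in rights:
                if graph.vertices[i].end <= graph.vertices[j].start:
                    edges.add((i, j))
                    added = True
        if not added:
            rejected += 1
            logger.info(
                "augment_graph(%s): junction (%d,%d) matches no exon boundary",
                graph.gene_id, donor_end, acceptor_start,
            )
    return (
        SplicingGraph(graph.gene_id, graph.contig, graph.strand,
                      graph.vertices, edges, set(graph.annotated_junctions)),
        rejected,
    )


def following_exons(graph: SplicingGraph, vertex_id: int) -> list[int]:
    """Successor vertex ids of ``vertex_id`` in read-strand order."""
    if graph.strand == "+":
        succ = [j for (i, j) in graph.edges if i == vertex_id]
        return sorted(succ, key=lambda j: graph.vertices[j].interval)
    succ = [i for (i, j) in graph.edges if j == vertex_id]
    return sorted(succ, key=lambda i: graph.vertices[i].interval, reverse=True)


def isolated_exons(graph: SplicingGraph) -> list[int]:
    """Vertices with neither incoming nor outgoing edges."""
    touched = {i for e in graph.edges for i in e}
    return [v.vertex_id for v in graph.vertices if v.vertex_id not in touched]
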