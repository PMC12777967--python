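"""k-mer generation from translated peptides and expression attachment.

Every length-k window of a peptide becomes a candidate k-mer (at most
L - k + 1 per peptide). A k-mer is a junction k-mer when its codons cover
bases on both sides of at least one exon-exon junction; such k-mers are
quantified by their junction read counts, others by the read counts of the
segments they cover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import ExpressionTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KmerConfig:
    k: int = 9
    exclusion_database: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass(frozen=True)
class KmerRecord:
    kmer: str
    gene_id: str
    offset: int                       # window start within the source peptide
    is_junction: bool
    junction_keys: tuple[tuple[str, int, int], ...]
    genomic_positions: tuple[tuple[int, int], ...]
    frame_annotated: bool
    junction_annotated: tuple[bool, ...]
    stop_interrupted: bool
    has_somatic: bool
    variant_mode: str
    source: object = field(compare=False, default=None, hash=False)

    def __post_init__(self) -> None:
        if self.is_junction != (len(self.genomic_positions) > 1):
            raise ValueError("is_junction must match multi-interval coverage")


def window_count(peptide_length: int, k: int) -> int:
    """Number of k-windows of a length-L peptide before deduplication."""
    return max(0, peptide_length - k + 1)


def needs_triplet(v_i, v_j, config_or_k) -> bool:
    """True when an exon pair is too short to host all junction k-mers
    (cumulative length < 3k), so exon-triplets must supplement it."""
    k = config_or_k.k if isinstance(config_or_k, KmerConfig) else int(config_or_k)
    return v_i.length + v_j.length < 3 * k


def kmerize(record, config: KmerConfig) -> list[KmerRecord]:
    """All k-windows of one peptide record, deduplicated within the record.

    Windows whose string is in the exclusion database are dropped before
    output. The junction flag is set iff the window's codons overlap at least
    one junction (bases on both sides).
    """
    k = config.k
    peptide = record.peptide
    out: list[KmerRecord] = []
    seen: set[str] = set()
    for w in range(window_count(len(peptide), k)):
        s = peptide[w : w + k]
        if s in seen or s in config.exclusion_database:
            seen.add(s)
            continue
        seen.add(s)
        b0, b1 = 3 * w, 3 * (w + k)
        spanned = [m for m, b in enumerate(record.boundaries) if b0 < b < b1]
        keys = tuple(record.junction_coords[m] for m in spanned)
        intervals = tuple(record.genomic_intervals(b0, b1))
        out.append(KmerRecord(
            kmer=s,
            gene_id=record.gene_id,
            offset=w,
            is_junction=len(intervals) > 1,
            junction_keys=keys,
            genomic_positions=intervals,
            frame_annotated=record.frame_annotated,
            junction_annotated=tuple(record.junction_annotated[m]
                                     for m in spanned),
            stop_interrupted=record.stop_interrupted,
            has_somatic=len(record.mutation_subset) > 0,
            variant_mode=record.variant_mode,
            source=record,
        ))
    return out


def kmerize_all(records, config: KmerConfig) -> list[KmerRecord]:
    out: list[KmerRecord] = []
    for rec in records:
        out.extend(kmerize(rec, config))
    return out


def quantify(kmer_record: KmerRecord, table: ExpressionTable,
             sample: str) -> float:
    """Expression support of one k-mer in one sample.

    Junction k-mers take their junction read count (the minimum across
    junctions for k-mers spanning two); non-junction k-mers take the minimum
    segment count over the positions they cover. Missing keys count as 0.
    """
    col = table.column(sample)
    if kmer_record.is_junction:
        values = []
        for key in kmer_record.junction_keys:
            counts = table.junction_counts.get(key)
            if counts is None:
                logger.info("junction %s absent from count table", key)
                values.append(0.0)
            else:
                values.append(float(counts[col]))
        return min(values) if values else 0.0
    values = []
    for (a, b) in kmer_record.genomic_positions:
        covering = [
            float(counts[col])
            for (contig, s, e), counts in table.segment_counts.items()
            if s < b and a < e
        ]
        if not covering:
            logger.info("positions [%d,%d) covered by no segment", a, b)
            values.append(0.0)
        else:
            values.append(min(covering))
    return min(values) if values else 0.0


def expression_matrix(kmer_records, table: ExpressionTable,
                      samples: list[str] | None = None) -> pd.DataFrame:
    """Per-sample expression for a set of k-mer records, indexed by k-mer
    string. Records sharing a string are aggregated by max support (the most
    favorable evidence across source contexts)."""
    samples = samples if samples is not None else table.sample_ids
    values: dict[str, np.ndarray] = {}
    for rec in kmer_records:
        row = np.array([quantify(rec, table, s) for s in samples])
        if rec.kmer in values:
            values[rec.kmer] = np.maximum(values[rec.kmer], row)
        else:
            values[rec.kmer] = row
    if not values:
        return pd.DataFrame(columns=samples, dtype=float)
    return pd.DataFrame.from_dict(values, orient="index", columns=samples)
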