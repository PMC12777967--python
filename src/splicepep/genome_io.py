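"""Readers and writers for the external formats the pipeline touches.

All coordinates are normalized at these I/O boundaries to a single internal
convention: 0-based, half-open intervals on the forward genomic strand.
GTF input (1-based, closed) and VCF input (1-based positions) are converted
on read; nothing downstream ever sees a 1-based coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import gffutils
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when an input is well-formed but internally inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """One contig of the reference genome, uppercased."""

    contig_name: str
    sequence: str

    def fetch(self, start: int, end: int) -> str:
        """Return the bases of ``[start, end)``; out-of-range is an error."""
        if start < 0 or end > len(self.sequence) or start > end:
            raise ValidationError(
                f"interval [{start},{end}) outside contig "
                f"{self.contig_name} of length {len(self.sequence)}"
            )
        return self.sequence[start:end]

    def __len__(self) -> int:
        return len(self.sequence)


class Variant(NamedTuple):
    """A single-nucleotide substitution in 0-based coordinates."""

    contig: str
    position: int
    ref: str
    alt: str


@dataclass
class VariantSet:
    sample_id: str
    germline: list[Variant] = field(default_factory=list)
    somatic: list[Variant] = field(default_factory=list)
    skipped_non_snv: int = 0


@dataclass(frozen=True)
class Transcript:
    """An annotated transcript: ordered exons plus optional CDS regions.

    ``exons`` and ``cds_regions`` are sorted ascending by genomic coordinate
    regardless of strand; translation order on the minus strand is handled by
    consumers. ``cds_frames`` holds the GTF phase column per CDS region
    (``None`` when absent).
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_regions: tuple[tuple[int, int], ...] = ()
    cds_frames: tuple[int | None, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"bad strand {self.strand!r}")
        for start, end in self.exons + self.cds_regions:
            if end <= start:
                raise ValidationError(
                    f"negative- or zero-width interval [{start},{end}) in "
                    f"transcript {self.transcript_id}"
                )
        prev_end = -1
        for start, end in self.exons:
            if start < prev_end:
                raise ValidationError(
                    f"exons of {self.transcript_id} overlap or are unsorted"
                )
            prev_end = end
        for c in self.cds_regions:
            if not any(s <= c[0] and c[1] <= e for s, e in self.exons):
                raise ValidationError(
                    f"CDS [{c[0]},{c[1]}) of {self.transcript_id} is not "
                    "contained in any exon"
                )

    @property
    def is_coding(self) -> bool:
        return len(self.cds_regions) > 0


@dataclass
class ExpressionTable:
    """Junction and segment read counts for a cohort of samples.

    Junction keys are ``(contig, donor_end, acceptor_start)`` and segment keys
    ``(contig, start, end)``, both 0-based half-open forward coordinates.
    Counts are float arrays aligned with ``sample_ids``.
    """

    sample_ids: list[str]
    junction_counts: dict[tuple[str, int, int], np.ndarray]
    segment_counts: dict[tuple[str, int, int], np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for key, counts in list(self.junction_counts.items()) + list(
            self.segment_counts.items()
        ):
            if len(counts) != n:
                raise ValidationError(f"count row {key} has wrong width")
            if np.any(np.asarray(counts) < 0):
                raise ValidationError(f"negative count in row {key}")

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample totals (column sums over all junction+segment rows)."""
        total = np.zeros(len(self.sample_ids))
        for counts in self.junction_counts.values():
            total += counts
        for counts in self.segment_counts.values():
            total += counts
        return pd.Series(total, index=self.sample_ids)

    def column(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise ValidationError(f"sample {sample!r} not in table") from None

    def subset(self, samples: list[str]) -> "ExpressionTable":
        idx = [self.column(s) for s in samples]
        return ExpressionTable(
            sample_ids=list(samples),
            junction_counts={k: v[idx] for k, v in self.junction_counts.items()},
            segment_counts={k: v[idx] for k, v in self.segment_counts.items()},
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a genome FASTA into a map contig name -> GenomeSequence."""
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ParseError(f"{path}:{lineno}: expected FASTA header")
            break
    genome: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ParseError(
                f"{path}: record {rec.id} contains non-DNA characters {sorted(bad)}"
            )
        genome[rec.id] = GenomeSequence(rec.id, seq)
    return genome


def write_fasta(genome: dict[str, GenomeSequence], path: str | Path) -> None:
    with open(path, "w") as out:
        for name in genome:
            out.write(f">{name}\n")
            seq = genome[name].sequence
            for i in range(0, len(seq), 60):
                out.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> dict[str, list[Transcript]]:
    """Parse exon and CDS features of a GTF, grouped by gene.

    1-based closed GTF coordinates become 0-based half-open. Exons are sorted
    ascending; the CDS frame (phase) column is retained when present.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS"}:
            continue
        tx_id = feat.attributes["transcript_id"][0]
        gene_id = feat.attributes["gene_id"][0]
        entry = per_tx.setdefault(
            tx_id,
            {"gene_id": gene_id, "contig": feat.seqid, "strand": feat.strand,
             "exons": [], "cds": []},
        )
        interval = (feat.start - 1, feat.end)  # 1-based closed -> 0-based half-open
        if interval[1] <= interval[0]:
            raise ParseError(f"{path}: negative-width feature at {feat.start}")
        if feat.featuretype == "exon":
            entry["exons"].append(interval)
        else:
            frame = None if feat.frame in (None, ".") else int(feat.frame)
            entry["cds"].append((interval, frame))

    genes: dict[str, list[Transcript]] = {}
    for tx_id, entry in per_tx.items():
        exons = tuple(sorted(entry["exons"]))
        cds = sorted(entry["cds"], key=lambda item: item[0])
        tx = Transcript(
            transcript_id=tx_id,
            gene_id=entry["gene_id"],
            contig=entry["contig"],
            strand=entry["strand"],
            exons=exons,
            cds_regions=tuple(c for c, _ in cds),
            cds_frames=tuple(f for _, f in cds),
        )
        genes.setdefault(entry["gene_id"], []).append(tx)
    for txs in genes.values():
        txs.sort(key=lambda t: t.transcript_id)
    return genes


def write_gtf(genes: dict[str, list[Transcript]], path: str | Path) -> None:
    """Write transcripts back to GTF (0-based half-open -> 1-based closed)."""
    with open(path, "w") as out:
        for gene_id in genes:
            for tx in genes[gene_id]:
                attrs = f'gene_id "{gene_id}"; transcript_id "{tx.transcript_id}";'
                for start, end in tx.exons:
                    out.write(
                        f"{tx.contig}\tsplicepep\texon\t{start + 1}\t{end}\t.\t"
                        f"{tx.strand}\t.\t{attrs}\n"
                    )
                for (start, end), frame in zip(tx.cds_regions, tx.cds_frames):
                    fr = "." if frame is None else str(frame)
                    out.write(
                        f"{tx.contig}\tsplicepep\tCDS\t{start + 1}\t{end}\t.\t"
                        f"{tx.strand}\t{fr}\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    sample_id: str = "",
    genome: dict[str, GenomeSequence] | None = None,
) -> tuple[list[Variant], int]:
    """Read SNVs from one VCF; returns (variants, skipped-non-SNV count).

    Positions become 0-based. Non-SNV records (indels, MNVs, multi-allelic
    rows with any non-SNV allele) are skipped with a logged count. When a
    genome is given, REF bases are checked against it and mismatches raise.
    """
    variants: list[Variant] = []
    skipped = 0
    mismatches: list[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(rec.ref) != 1 or any(len(a) != 1 for a in alts) or not alts:
                skipped += 1
                continue
            for alt in alts:
                v = Variant(rec.contig, rec.start, rec.ref.upper(), alt.upper())
                if genome is not None:
                    actual = genome[v.contig].fetch(v.position, v.position + 1)
                    if actual != v.ref:
                        mismatches.append(
                            f"{v.contig}:{v.position + 1} REF={v.ref} genome={actual}"
                        )
                        continue
                variants.append(v)
    if mismatches:
        raise ValidationError(
            "VCF REF mismatches with genome: " + "; ".join(mismatches)
        )
    if skipped:
        logger.info("read_vcf(%s): skipped %d non-SNV records", path, skipped)
    positions = [(v.contig, v.position) for v in variants]
    if len(set(positions)) != len(positions):
        raise ValidationError(f"{path}: overlapping same-position variants")
    return variants, skipped


def load_variant_set(
    sample_id: str,
    germline_path: str | Path | None = None,
    somatic_path: str | Path | None = None,
    genome: dict[str, GenomeSequence] | None = None,
) -> VariantSet:
    """Load germline and somatic SNVs from two separate VCFs."""
    vs = VariantSet(sample_id=sample_id)
    if germline_path is not None:
        vs.germline, n = read_vcf(germline_path, sample_id, genome)
        vs.skipped_non_snv += n
    if somatic_path is not None:
        vs.somatic, n = read_vcf(somatic_path, sample_id, genome)
        vs.skipped_non_snv += n
    return vs


def write_vcf(variants: list[Variant], path: str | Path,
              contig_lengths: dict[str, int]) -> None:
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for contig, length in contig_lengths.items():
            out.write(f"##contig=<ID={contig},length={length}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants):
            out.write(f"{v.contig}\t{v.position + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# Count tables / novel junctions / k-mer and peptide output
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> ExpressionTable:
    """Read a TSV of junction and segment read counts.

    Columns: kind (junction|segment), contig, pos1, pos2, then one column per
    sample. For junctions pos1/pos2 are (donor_end, acceptor_start); for
    segments they are the segment interval.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    fixed = ["kind", "contig", "pos1", "pos2"]
    if list(df.columns[: len(fixed)]) != fixed:
        raise ParseError(f"{path}: expected leading columns {fixed}")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax())
        raise ParseError(f"{path}: ragged or missing values at row {bad}")
    samples = list(df.columns[len(fixed):])
    junctions: dict[tuple[str, int, int], np.ndarray] = {}
    segments: dict[tuple[str, int, int], np.ndarray] = {}
    for _, row in df.iterrows():
        key = (str(row["contig"]), int(row["pos1"]), int(row["pos2"]))
        counts = row[samples].to_numpy(dtype=float)
        if row["kind"] == "junction":
            junctions[key] = counts
        elif row["kind"] == "segment":
            segments[key] = counts
        else:
            raise ParseError(f"{path}: unknown row kind {row['kind']!r}")
    return ExpressionTable(samples, junctions, segments)


def write_counts(table: ExpressionTable, path: str | Path) -> None:
    rows = []
    for (contig, a, b), counts in sorted(table.junction_counts.items()):
        rows.append(["junction", contig, a, b, *counts])
    for (contig, a, b), counts in sorted(table.segment_counts.items()):
        rows.append(["segment", contig, a, b, *counts])
    df = pd.DataFrame(rows, columns=["kind", "contig", "pos1", "pos2",
                                     *table.sample_ids])
    df.to_csv(path, sep="\t", index=False)


def read_novel_junctions(path: str | Path) -> list[tuple[str, int, int]]:
    """Novel-junction TSV: contig, donor_end, acceptor_start (0-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    return [
        (str(r["contig"]), int(r["donor_end"]), int(r["acceptor_start"]))
        for _, r in df.iterrows()
    ]


def write_novel_junctions(junctions, path: str | Path) -> None:
    df = pd.DataFrame(junctions, columns=["contig", "donor_end", "acceptor_start"])
    df.to_csv(path, sep="\t", index=False)


def read_mhc_scores(path: str | Path) -> pd.DataFrame:
    """MHC score TSV with columns kmer, allele, rank_percent[, ic50]."""
    df = pd.read_csv(path, sep="\t")
    for col in ("kmer", "allele", "rank_percent"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df


def read_exclusion_database(path: str | Path) -> frozenset[str]:
    with open(path) as handle:
        return frozenset(line.strip() for line in handle if line.strip())


def _format_junction(key) -> str:
    contig, end, start = key
    return f"{contig}:{end}:{start}"


def write_peptides(records, fasta_path: str | Path, tsv_path: str | Path) -> None:
    """Write peptide FASTA plus a metadata TSV.

    The metadata carries the genomic coordinates the peptide derives from,
    the reading frame used, per-junction annotation flags, and whether
    translation was interrupted by a stop codon. Pair-derived rows fill two
    exon-coordinate fields; triplet-derived rows fill three.
    """
    rows = []
    with open(fasta_path, "w") as fa:
        for i, rec in enumerate(records):
            pid = f"pep_{i:06d}"
            fa.write(f">{pid} {rec.gene_id}\n{rec.peptide}\n")
            coords = ["", "", ""]
            for j, (s, e) in enumerate(rec.exon_coords):
                coords[j] = f"{s}-{e}"
            rows.append({
                "peptide_id": pid,
                "gene_id": rec.gene_id,
                "contig": rec.contig,
                "strand": rec.strand,
                "n_exons": len(rec.exon_coords),
                "exon1": coords[0],
                "exon2": coords[1],
                "exon3": coords[2],
                "junctions": ";".join(_format_junction(k) for k in rec.junction_coords),
                "frame": rec.frame_used,
                "frame_annotated": rec.frame_annotated,
                "junction_annotated": ";".join(
                    str(flag) for flag in rec.junction_annotated
                ),
                "stop_interrupted": rec.stop_interrupted,
                "variant_mode": rec.variant_mode,
                "somatic_subset": ";".join(
                    f"{v.position}{v.ref}>{v.alt}" for v in rec.mutation_subset
                ),
                "peptide": rec.peptide,
            })
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def write_kmers(records, path: str | Path,
                expression: pd.DataFrame | None = None) -> None:
    """Write k-mer TSV; optional per-sample expression columns are joined in."""
    rows = []
    for rec in records:
        row = {
            "kmer": rec.kmer,
            "gene_id": rec.gene_id,
            "is_junction": rec.is_junction,
            "junctions": ";".join(_format_junction(k) for k in rec.junction_keys),
            "frame_annotated": rec.frame_annotated,
            "junction_annotated": all(rec.junction_annotated)
            if rec.junction_annotated else True,
            "stop_interrupted": rec.stop_interrupted,
            "variant_mode": rec.variant_mode,
            "has_somatic": rec.has_somatic,
        }
        if expression is not None and rec.kmer in expression.index:
            for sample in expression.columns:
                row[f"expr_{sample}"] = expression.at[rec.kmer, sample]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
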