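"""Seeded synthetic genomes, annotations, variants and cohort count tables.

The generator emulates the pipeline's study conditions at desk scale: a small
set of multi-exon coding genes, a foreground (tumor) cohort and a background
(normal) cohort of junction/segment read counts, and one planted
tumor-specific exon-skipping junction per gene that only foreground samples
express. Planted skips are in-frame (the skipped exon length is a multiple of
3) so the set of novel k-mers a planted junction creates is exactly the
junction-spanning windows of the skip-path translation; that truth table is
derived here by direct string chunking, independently of the graph traversal.

Everything is generated from one integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .genome_io import (
    ExpressionTable,
    GenomeSequence,
    Transcript,
    Variant,
    VariantSet,
    write_counts,
    write_fasta,
    write_gtf,
    write_novel_junctions,
    write_vcf,
)

logger = logging.getLogger(__name__)

_CODON = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_NON_STOP_CODONS = sorted(set(_CODON) - _STOPS)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _chunk_translate(dna: str) -> str:
    """Plain codon-chunking translation, stopping at the first stop codon.

    Kept deliberately separate from the traversal code: truth tables must be
    derivable without it.
    """
    aas = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i : i + 3]
        if codon in _STOPS:
            break
        aas.append(_CODON.get(codon, "X"))
    return "".join(aas)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes: int = 5
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_length: tuple[int, int] = (45, 90)
    intron_length: tuple[int, int] = (30, 60)
    n_foreground_samples: int = 4
    n_background_samples: int = 8
    planted_junctions_per_gene: int = 1
    germline_variants_per_gene: int = 2
    somatic_variants_per_gene: int = 1
    mean_depth: float = 50.0
    dispersion: float = 0.3
    plant_in_background: int = 0
    k: int = 9

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_foreground_samples < 1:
            raise ValueError("need at least one gene and one foreground sample")
        if self.exon_length[0] < 9:
            raise ValueError("exons must allow at least three codons")
        if self.exons_per_gene[0] < 3 and self.planted_junctions_per_gene:
            raise ValueError("planting a skip junction needs >= 3 exons")
        if self.plant_in_background > self.n_background_samples:
            raise ValueError("cannot plant in more background samples than exist")
        for lo, hi in (self.exons_per_gene, self.exon_length, self.intron_length):
            if lo > hi or lo < 1:
                raise ValueError("invalid range")


@dataclass
class SimulatedData:
    config: SimulationConfig
    genome: dict[str, GenomeSequence]
    genes: dict[str, list[Transcript]]
    novel_junctions: list[tuple[str, int, int]]
    counts: ExpressionTable
    foreground_samples: list[str]
    background_samples: list[str]
    variant_sets: dict[str, VariantSet]
    truth: pd.DataFrame
    truth_kmers: frozenset[str] = field(default_factory=frozenset)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gtf",
            "counts": outdir / "counts.tsv",
            "novel_junctions": outdir / "novel_junctions.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        write_gtf(self.genes, paths["annotation"])
        write_counts(self.counts, paths["counts"])
        write_novel_junctions(self.novel_junctions, paths["novel_junctions"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        lengths = {name: len(seq) for name, seq in self.genome.items()}
        for sample, vs in self.variant_sets.items():
            gp = outdir / f"germline_{sample}.vcf"
            sp = outdir / f"somatic_{sample}.vcf"
            write_vcf(vs.germline, gp, lengths)
            write_vcf(vs.somatic, sp, lengths)
            paths[f"germline_{sample}"] = gp
            paths[f"somatic_{sample}"] = sp
        return paths


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float,
               size: int) -> np.ndarray:
    """Negative-binomial-shaped integer read counts (mean/dispersion)."""
    if dispersion <= 0:
        return np.full(size, round(mean), dtype=float)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size).astype(float)


def _sample_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


def simulate(config: SimulationConfig) -> SimulatedData:
    """Generate a full synthetic input set with planted ground truth.

    Each gene gets one coding transcript spanning all its exons; planted
    tumor-specific junctions skip one (in-frame) exon, reuse existing exon
    boundaries, and receive nonzero read counts only in foreground samples
    (unless ``plant_in_background`` > 0). Background samples express only
    annotated junctions.
    """
    rng = np.random.default_rng(config.seed)
    contig = "chr1"
    chars: list[str] = []
    genes: dict[str, list[Transcript]] = {}
    novel: list[tuple[str, int, int]] = []
    truth_rows: list[dict] = []
    annotated_protein_list: list[str] = []
    junction_rows: dict[tuple[str, int, int], np.ndarray] = {}
    segment_rows: dict[tuple[str, int, int], np.ndarray] = {}

    fg = [f"tumor_{i}" for i in range(config.n_foreground_samples)]
    bg = [f"normal_{i}" for i in range(config.n_background_samples)]
    samples = fg + bg
    n_fg, n_all = len(fg), len(samples)

    def pad(n: int) -> None:
        chars.extend("ACGT"[i] for i in rng.integers(0, 4, size=n))

    for gi in range(config.n_genes):
        gene_id = f"gene_{gi}"
        strand = "+" if gi % 2 == 0 else "-"
        pad(100)
        d = int(rng.integers(config.exons_per_gene[0],
                             config.exons_per_gene[1] + 1))
        lengths = [int(rng.integers(config.exon_length[0],
                                    config.exon_length[1] + 1))
                   for _ in range(d)]
        plant = config.planted_junctions_per_gene > 0 and d >= 3
        if plant:
            donor_t = int(rng.integers(0, d - 2))  # translation-order index
            skip_t = donor_t + 1
        else:
            donor_t, skip_t = -1, -1

        # translation-order exon index -> genomic exon index
        t2g = list(range(d)) if strand == "+" else list(range(d - 1, -1, -1))
        if plant:
            gidx = t2g[skip_t]
            lengths[gidx] -= lengths[gidx] % 3  # in-frame skip
        tss_offset = int(rng.integers(0, 7))

        # lay out exons in genomic order
        exons: list[tuple[int, int]] = []
        for li in range(d):
            start = len(chars)
            pad(lengths[li])
            exons.append((start, len(chars)))
            if li < d - 1:
                pad(int(rng.integers(config.intron_length[0],
                                     config.intron_length[1] + 1)))

        # fill the coding part with non-stop codons (sense direction)
        t_exons = [exons[i] for i in t2g]
        cds_len = sum(e - s for s, e in t_exons) - tss_offset
        sense = _sample_codons(rng, cds_len // 3 + 1)[:cds_len]
        # write sense sequence back into the genome
        cursor = 0
        for ti, (s, e) in enumerate(t_exons):
            skip = tss_offset if ti == 0 else 0
            seg_len = (e - s) - skip
            seg = sense[cursor : cursor + seg_len]
            cursor += seg_len
            if strand == "+":
                chars[s + skip : e] = list(seg)
            else:
                chars[s : e - skip] = list(_revcomp(seg))

        # stop-proof the short 5'UTR (poly-C: no stop codon contains C) so
        # that all-frames translation of the first exon never truncates
        # before reaching the annotated alignment
        first = t_exons[0]
        if tss_offset:
            if strand == "+":
                chars[first[0] : first[0] + tss_offset] = ["C"] * tss_offset
            else:
                chars[first[1] - tss_offset : first[1]] = ["G"] * tss_offset

        # guard the planted junction's straddling codon against stops: a 'C'
        # in the acceptor's first sense base can never complete a stop codon
        if plant:
            acc = t_exons[donor_t + 2]
            if strand == "+":
                chars[acc[0]] = "C"
            else:
                chars[acc[1] - 1] = "G"  # complement of sense 'C'

        # CDS regions (forward-sorted), phases per GTF convention
        if strand == "+":
            cds = [(exons[0][0] + tss_offset, exons[0][1])] + exons[1:]
        else:
            cds = exons[:-1] + [(exons[-1][0], exons[-1][1] - tss_offset)]
        phases: dict[tuple[int, int], int] = {}
        cum = 0
        for ti, region in enumerate([cds[i] for i in t2g] if strand == "-"
                                    else cds):
            phases[region] = (3 - cum % 3) % 3
            cum += region[1] - region[0]
        tx = Transcript(
            transcript_id=f"{gene_id}_t0",
            gene_id=gene_id,
            contig=contig,
            strand=strand,
            exons=tuple(exons),
            cds_regions=tuple(cds),
            cds_frames=tuple(phases[c] for c in cds),
        )
        genes[gene_id] = [tx]

        # annotated junction counts (all samples) and segment counts
        for a, b in zip(exons, exons[1:]):
            junction_rows[(contig, a[1], b[0])] = _nb_counts(
                rng, config.mean_depth, config.dispersion, n_all)
        for s, e in exons:
            segment_rows[(contig, s, e)] = _nb_counts(
                rng, config.mean_depth, config.dispersion, n_all)

        # plant the skip junction: boundaries of existing exons, counts only
        # in the foreground (plus plant_in_background leaky normals)
        if plant:
            donor_g, acc_g = t_exons[donor_t], t_exons[donor_t + 2]
            left, right = (donor_g, acc_g) if strand == "+" else (acc_g, donor_g)
            key = (contig, left[1], right[0])
            counts = np.zeros(n_all)
            counts[:n_fg] = _nb_counts(rng, config.mean_depth,
                                       config.dispersion, n_fg) + 1.0
            for bi in range(config.plant_in_background):
                counts[n_fg + bi] = _nb_counts(
                    rng, config.mean_depth, config.dispersion, 1)[0] + 1.0
            junction_rows[key] = counts
            novel.append(key)

            # skip-path translation by independent linear string chunking;
            # truth k-mers are finalized after the loop, once the annotated
            # proteome is known (a junction window whose string the
            # annotation also encodes is not novel)
            path = t_exons[: donor_t + 1] + t_exons[donor_t + 2 :]
            parts = []
            for ti, (s, e) in enumerate(path):
                skip = tss_offset if ti == 0 else 0
                seg = ("".join(chars[s + skip : e]) if strand == "+"
                       else _revcomp("".join(chars[s : e - skip])))
                parts.append(seg)
            boundary = sum(len(p) for p in parts[: donor_t + 1])
            truth_rows.append({
                "gene_id": gene_id,
                "contig": contig,
                "donor_end": key[1],
                "acceptor_start": key[2],
                "_skip_protein": _chunk_translate("".join(parts)),
                "_boundary": boundary,
                "tumor_specific": config.plant_in_background == 0,
            })
        # annotated protein from the final genome (post-guard), independently
        ann_parts = []
        for ti, (s, e) in enumerate(t_exons):
            skip = tss_offset if ti == 0 else 0
            seg = ("".join(chars[s + skip : e]) if strand == "+"
                   else _revcomp("".join(chars[s : e - skip])))
            ann_parts.append(seg)
        annotated_protein_list.append(_chunk_translate("".join(ann_parts)))
        pad(100)

    genome = {contig: GenomeSequence(contig, "".join(chars))}

    # per-foreground-sample germline and somatic SNVs inside coding exons,
    # never creating a stop codon in the annotated frame
    variant_sets: dict[str, VariantSet] = {}
    for sample in fg:
        vs = VariantSet(sample_id=sample)
        for gene_id, (tx,) in ((g, tuple(t)) for g, t in genes.items()):
            vs.germline.extend(_draw_variants(
                rng, genome[contig], tx, config.germline_variants_per_gene,
                exclude={v.position for v in vs.germline + vs.somatic}))
            vs.somatic.extend(_draw_variants(
                rng, genome[contig], tx, config.somatic_variants_per_gene,
                exclude={v.position for v in vs.germline + vs.somatic}))
        variant_sets[sample] = vs

    counts = ExpressionTable(samples, junction_rows, segment_rows)

    # finalize truth: junction-spanning windows of each skip-path protein
    # whose string the annotated proteome does not already encode
    k = config.k
    annotated_windows = {
        protein[w : w + k]
        for protein in annotated_protein_list
        for w in range(max(0, len(protein) - k + 1))
    }
    for row in truth_rows:
        protein = row.pop("_skip_protein")
        boundary = row.pop("_boundary")
        row["kmers"] = ";".join(sorted({
            protein[w : w + k]
            for w in range(max(0, len(protein) - k + 1))
            if 3 * w < boundary < 3 * (w + k)
        } - annotated_windows))
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "contig", "donor_end", "acceptor_start",
                 "kmers", "tumor_specific"],
    )
    truth_kmers = frozenset(
        k for row in truth_rows if row["tumor_specific"]
        for k in row["kmers"].split(";") if k
    )
    return SimulatedData(
        config=config,
        genome=genome,
        genes=genes,
        novel_junctions=novel,
        counts=counts,
        foreground_samples=fg,
        background_samples=bg,
        variant_sets=variant_sets,
        truth=truth,
        truth_kmers=truth_kmers,
    )


def _draw_variants(rng, genome: GenomeSequence, tx: Transcript, n: int,
                   exclude: set[int]) -> list[Variant]:
    """Draw n SNVs inside the transcript's CDS whose alternate base cannot
    form a stop codon in any frame ('C' never occurs in a stop)."""
    out: list[Variant] = []
    positions = [p for s, e in tx.cds_regions for p in range(s, e)
                 if p not in exclude]
    if not positions or n <= 0:
        return out
    chosen = rng.choice(len(positions), size=min(n, len(positions)),
                        replace=False)
    for idx in sorted(int(i) for i in chosen):
        pos = positions[idx]
        ref = genome.sequence[pos]
        for alt in "CGAT":
            if alt != ref and _safe_substitution(genome, tx, pos, alt):
                out.append(Variant(genome.contig_name, pos, ref, alt))
                exclude.add(pos)
                break
    return out


def _safe_substitution(genome: GenomeSequence, tx: Transcript, pos: int,
                       alt: str) -> bool:
    """True when substituting ``alt`` at ``pos`` keeps the transcript's
    annotated translation stop-free at that codon."""
    parts = []
    offset_of_pos = None
    cursor = 0
    regions = tx.cds_regions if tx.strand == "+" else tuple(reversed(tx.cds_regions))
    for s, e in regions:
        seg = genome.sequence[s:e]
        if tx.strand == "-":
            seg = _revcomp(seg)
        if s <= pos < e:
            local = pos - s if tx.strand == "+" else e - 1 - pos
            offset_of_pos = cursor + local
        parts.append(seg)
        cursor += e - s
    if offset_of_pos is None:
        return True
    coding = list("".join(parts))
    coding[offset_of_pos] = alt if tx.strand == "+" else _revcomp(alt)
    ci = offset_of_pos - offset_of_pos % 3
    codon = "".join(coding[ci : ci + 3])
    return len(codon) < 3 or codon not in _STOPS


# ---------------------------------------------------------------------------
# Deterministic hand-built edge-case fixtures
# ---------------------------------------------------------------------------

def _lay_gene(gene_id: str, strand: str, sense_exons: list[str],
              tss_offset: int = 0, intron: str = "GGGGGGGGGGGG",
              utr5: str = "", contig: str = "chrT", lead: str = "AAAA"):
    """Place translation-order sense exon sequences on a genome string.

    Returns (genome map, transcript, forward exon intervals in translation
    order). On the minus strand exons are laid right-to-left and
    reverse-complemented.
    """
    if strand == "-":
        genomic = [_revcomp(s) for s in reversed(sense_exons)]
    else:
        genomic = list(sense_exons)
    seq = lead
    intervals = []
    for i, ex in enumerate(genomic):
        if i:
            seq += intron
        intervals.append((len(seq), len(seq) + len(ex)))
        seq += ex
    seq += "AAAA"
    t_intervals = intervals if strand == "+" else intervals[::-1]
    if strand == "+":
        first = t_intervals[0]
        cds = [(first[0] + tss_offset, first[1])] + t_intervals[1:]
        cds_sorted = sorted(cds)
    else:
        first = t_intervals[0]
        cds = [(first[0], first[1] - tss_offset)] + t_intervals[1:]
        cds_sorted = sorted(cds)
    tx = Transcript(
        transcript_id=f"{gene_id}_t0", gene_id=gene_id, contig=contig,
        strand=strand, exons=tuple(sorted(intervals)),
        cds_regions=tuple(cds_sorted),
        cds_frames=tuple(0 for _ in cds_sorted),
    )
    return {contig: GenomeSequence(contig, seq)}, tx, t_intervals


def make_edge_cases() -> dict[str, SimpleNamespace]:
    """Deterministic mini-fixtures for the tricky corners of the algorithm."""
    cases: dict[str, SimpleNamespace] = {}

    # translation starting mid-exon (5'UTR on the first exon)
    genome, tx, ivs = _lay_gene(
        "mid_tss", "+",
        ["TTTTT" + "ATGGCAGGA",      # 5 UTR bases, then M A G
         "TTTGGGAAA"],               # F G K
        tss_offset=5,
    )
    cases["mid_exon_tss"] = SimpleNamespace(
        genome=genome, transcripts=[tx], exon_intervals=ivs,
        expected_peptide="MAGFGK", tss_offset=5)

    # in-frame stop inside the donor exon: truncation, no propagation
    genome, tx, ivs = _lay_gene(
        "stopgene", "+",
        ["ATGGCATAAGGG",             # M A * ...
         "TTTGGGAAA"],
    )
    cases["stop_at_junction"] = SimpleNamespace(
        genome=genome, transcripts=[tx], exon_intervals=ivs,
        expected_peptide="MA")

    # exon pair shorter than 3k at k=9: triplets must fire
    genome, tx, ivs = _lay_gene(
        "shorty", "+",
        ["ATGGCAGGA", "TTTGGGAAA", "CCCAAAGAGTGGCAC"],
    )
    cases["short_pair_triplet"] = SimpleNamespace(
        genome=genome, transcripts=[tx], exon_intervals=ivs, k=9)

    # minus-strand gene and its mirrored plus-strand twin
    sense = ["ATGGCAGGATTC", "TTTGGGAAACAC", "CCCAAAGAG"]
    genome_m, tx_m, ivs_m = _lay_gene("minus", "-", sense)
    genome_p, tx_p, ivs_p = _lay_gene("plus", "+", sense)
    cases["minus_strand"] = SimpleNamespace(
        minus=SimpleNamespace(genome=genome_m, transcripts=[tx_m],
                              exon_intervals=ivs_m),
        plus=SimpleNamespace(genome=genome_p, transcripts=[tx_p],
                             exon_intervals=ivs_p))

    # overlapping alternative 3'/5' exons triggering the redundancy rule
    seq = "A" * 4 + "ATGGCAGGATTCTTTGGGAAACACGAGGCG"  # exon1 [4,34)
    seq += "G" * 12                                    # intron
    e2_start = len(seq)
    seq += "CCTAAAGAGTGGCACGCA"                        # exon2 [e2,e2+18)
    seq += "AAAA"
    g = {"chrT": GenomeSequence("chrT", seq)}
    long_pair = Transcript("alt_t1", "altgene", "chrT", "+",
                           exons=((4, 34), (e2_start, e2_start + 18)),
                           cds_regions=((4, 34), (e2_start, e2_start + 18)),
                           cds_frames=(0, 0))
    short_pair = Transcript("alt_t2", "altgene", "chrT", "+",
                            exons=((13, 34), (e2_start, e2_start + 12)),
                            cds_regions=((13, 34), (e2_start, e2_start + 12)),
                            cds_frames=(0, 0))
    cases["alt_three_prime"] = SimpleNamespace(
        genome=g, transcripts=[long_pair, short_pair],
        dominating=((4, 34), (e2_start, e2_start + 18)),
        dominated=((13, 34), (e2_start, e2_start + 12)))

    # three somatic mutations inside one exon-pair span
    genome, tx, ivs = _lay_gene(
        "somatic3", "+",
        ["ATGGCAGGATTCAAA", "TTTGGGAAACACGAG"],
    )
    span = (ivs[0][0], ivs[1][1])
    somatic = [
        Variant("chrT", ivs[0][0] + 4, genome["chrT"].sequence[ivs[0][0] + 4], "C"),
        Variant("chrT", ivs[0][0] + 7, genome["chrT"].sequence[ivs[0][0] + 7], "C"),
        Variant("chrT", ivs[1][0] + 2, genome["chrT"].sequence[ivs[1][0] + 2], "C"),
    ]
    somatic = [v for v in somatic if v.ref != "C"] + [
        Variant(v.contig, v.position, v.ref, "G")
        for v in somatic if v.ref == "C"
    ]
    cases["somatic_n3"] = SimpleNamespace(
        genome=genome, transcripts=[tx], exon_intervals=ivs,
        somatic=sorted(somatic), span=span)

    # a disconnected (isolated) retained exon next to a linear gene
    genome, tx, ivs = _lay_gene(
        "isogene", "+",
        ["ATGGCAGGA", "TTTGGGAAA", "CCCAAAGAG"],
    )
    seq = genome["chrT"].sequence + "GGGG" + "ATGCACGAGTGG" + "AAAA"
    iso_start = len(genome["chrT"].sequence) + 4
    iso = Transcript("iso_t1", "isogene", "chrT", "+",
                     exons=((iso_start, iso_start + 12),),
                     cds_regions=((iso_start, iso_start + 12),),
                     cds_frames=(0,))
    cases["isolated_exon"] = SimpleNamespace(
        genome={"chrT": GenomeSequence("chrT", seq)},
        transcripts=[tx, iso],
        isolated_interval=(iso_start, iso_start + 12))

    # strategy-difference gene: junction 2 is annotated but carries zero
    # background reads; novel frames over it survive re-quant, not all-frames
    genome, tx, ivs = _lay_gene(
        "stratgene", "+",
        ["ATGGCAGGATTCTTTGGGAAACACGAGGCGCCT",
         "AAAGAGTGGCACGCAATGGATCTGCGCACC",
         "GGATTCAAACCGTGCGAATATCATGCTAGC"],
    )
    contig = "chrT"
    j1 = (contig, ivs[0][1], ivs[1][0])
    j2 = (contig, ivs[1][1], ivs[2][0])
    novel = (contig, ivs[0][1], ivs[2][0])  # planted skip e1->e3
    samples = ["tumor_0", "normal_0", "normal_1"]
    counts = ExpressionTable(
        samples,
        junction_counts={
            j1: np.array([30.0, 25.0, 40.0]),
            j2: np.array([22.0, 0.0, 0.0]),   # annotated yet silent in normals
            novel: np.array([18.0, 0.0, 0.0]),
        },
        segment_counts={(contig, s, e): np.array([30.0, 30.0, 30.0])
                        for s, e in ivs},
    )
    cases["strategy_difference"] = SimpleNamespace(
        genome=genome, transcripts=[tx], exon_intervals=ivs,
        counts=counts, foreground=["tumor_0"], background=["normal_0", "normal_1"],
        annotated_silent_junction=j2, novel_junction=novel)

    return cases
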