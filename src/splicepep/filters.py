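"""Candidate-selection stack over k-mer records.

All filters are pure functions list[KmerRecord] -> list[KmerRecord], keeping
input order, so they compose freely. Expression is supplied as a DataFrame
indexed by k-mer string with one column per sample.

Background subtraction comes in two strategies:

* **re-quant** — a junction k-mer is removed when its junction position
  carries any reads in the background cohort (frame-blind; retains candidates
  on junctions the background never expresses, including novel-frame ones).
* **all-frames** — a k-mer is removed when its sequence occurs among the
  k-mers of the background graph translated in all three reading frames
  (retains only candidates from junctions absent from the background graph).

Every all-frames survivor also survives re-quant: a sequence absent from the
background all-frames translation implies its junction is absent from the
background graph, hence unread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .genome_io import ExpressionTable
from .kmers import KmerConfig, KmerRecord, kmerize_all, window_count

logger = logging.getLogger(__name__)

#: Foreground inclusion rule: a junction k-mer unexpressed in the target
#: sample is still kept when its maximal normalized cohort expression reaches
#: this many reads.
FOREGROUND_MIN_NORMALIZED = 20.0


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filtering stack.

    u — background recurrence: k-mers present (any read level) in >= u
        background samples are removed; u=1 is the strict complete-exclusion
        setting.
    R — background read threshold: k-mers with expression >= R in at least
        ``r_recurrence`` background samples are removed (None disables).
    T, l — cancer-cohort support: keep k-mers with expression >= T in at
        least l non-target samples.
    t — target-sample read threshold.
    """

    u: int = 1
    R: float | None = None
    r_recurrence: int = 1
    T: float = 0.0
    l: int = 0
    t: float = 1.0
    normalize: bool = False
    sample_whitelist: frozenset[str] | None = None
    mhc_rank_threshold: float = 2.0
    keep_unscored: bool = False

    def __post_init__(self) -> None:
        if self.u < 1 or self.l < 0:
            raise ValueError("u must be >= 1 and l >= 0")
        for name in ("T", "t", "mhc_rank_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.R is not None and self.R < 0:
            raise ValueError("R must be >= 0")


def normalization_factors(library_sizes: pd.Series) -> pd.Series:
    """Per-sample factor: library size divided by the cohort median library
    size (the median sample gets factor 1)."""
    factors = library_sizes / library_sizes.median()
    if (factors <= 0).any():
        raise ValueError("library sizes must be positive")
    return factors


def annotated_kmer_set(proteins, k: int) -> frozenset[str]:
    """All k-windows occurring in the annotated proteome."""
    windows: set[str] = set()
    for protein in proteins:
        for w in range(window_count(len(protein), k)):
            windows.add(protein[w : w + k])
    return frozenset(windows)


def annotation_filter(kmer_records, annotated_peptides, k: int):
    """Remove k-mers whose string occurs in any annotated peptide."""
    annotated = (annotated_peptides
                 if isinstance(annotated_peptides, frozenset)
                 else annotated_kmer_set(annotated_peptides, k))
    return [rec for rec in kmer_records if rec.kmer not in annotated]


def background_filter(kmer_records, background_expression: pd.DataFrame,
                      config: FilterConfig):
    """Remove k-mers recurrent or expressed in the background cohort.

    A k-mer is removed iff it is present (count > 0) in >= u background
    samples, or expressed with >= R reads in >= r_recurrence samples (when R
    is set). u=1 yields complete exclusion of anything background-supported.
    """
    removed: set[str] = set()
    for kmer in background_expression.index:
        row = background_expression.loc[kmer]
        if (row > 0).sum() >= config.u:
            removed.add(kmer)
        elif config.R is not None and (row >= config.R).sum() >= config.r_recurrence:
            removed.add(kmer)
    return [rec for rec in kmer_records if rec.kmer not in removed]


def _normalized(expression: pd.DataFrame, factors: pd.Series | None,
                apply: bool) -> pd.DataFrame:
    if not apply:
        return expression
    if factors is None:
        raise ValueError("normalization requested but no factors given")
    return expression * factors.reindex(expression.columns)


def cancer_support_filter(kmer_records, cohort_expression: pd.DataFrame,
                          target_sample: str, config: FilterConfig,
                          factors: pd.Series | None = None):
    """Keep k-mers supported in the target sample and recurrent in the cohort.

    Kept iff expression >= t in the target sample AND expression >= T in at
    least l non-target samples (l=0 makes the cohort clause vacuous). When
    config.normalize, thresholds compare against factor-scaled expression.
    The whitelist restricts which samples may count toward l.
    """
    if target_sample not in cohort_expression.columns:
        raise ValueError(f"target sample {target_sample!r} not in cohort")
    expr = _normalized(cohort_expression, factors, config.normalize)
    others = [s for s in expr.columns if s != target_sample]
    if config.sample_whitelist is not None:
        others = [s for s in others if s in config.sample_whitelist]
    kept: set[str] = set()
    for kmer in expr.index:
        if expr.at[kmer, target_sample] < config.t:
            continue
        if config.l > 0:
            support = sum(expr.at[kmer, s] >= config.T for s in others)
            if support < config.l:
                continue
        kept.add(kmer)
    return [rec for rec in kmer_records if rec.kmer in kept]


def foreground_default_rule(kmer_records, cohort_expression: pd.DataFrame,
                            target_sample: str,
                            factors: pd.Series | None = None):
    """Default foreground inclusion: keep a k-mer iff it has any read in the
    target sample or its maximal normalized cohort expression is >= 20."""
    if target_sample not in cohort_expression.columns:
        raise ValueError(f"target sample {target_sample!r} not in cohort")
    normalized = _normalized(cohort_expression, factors, factors is not None)
    kept: set[str] = set()
    for kmer in cohort_expression.index:
        if cohort_expression.at[kmer, target_sample] > 0:
            kept.add(kmer)
        elif normalized.loc[kmer].max() >= FOREGROUND_MIN_NORMALIZED:
            kept.add(kmer)
    return [rec for rec in kmer_records if rec.kmer in kept]


def requant_filter(kmer_records, background_counts: ExpressionTable,
                   background_kmer_strings: frozenset[str] | None = None):
    """re-quant background strategy (junction-keyed, frame-blind).

    A junction k-mer is removed iff any of its junction positions carries
    reads (count > 0) in any background sample. Additionally, when a
    background k-mer string set is supplied, germline-personalized k-mers
    whose sequence the background also supports are excluded.
    """
    out = []
    for rec in kmer_records:
        if rec.is_junction:
            expressed = False
            for key in rec.junction_keys:
                counts = background_counts.junction_counts.get(key)
                if counts is not None and (counts > 0).any():
                    expressed = True
                    break
            if expressed:
                continue
        if (background_kmer_strings is not None
                and rec.variant_mode in ("germline", "germline_somatic")
                and rec.kmer in background_kmer_strings):
            continue
        out.append(rec)
    return out


def allframes_background_kmers(graph, genome, k: int) -> frozenset[str]:
    """All k-mer strings from translating a background graph in all three
    reading frames (reference sequence, no personalization)."""
    from .frames import FrameState
    from .translate import traverse
    from .variants import VariantEngine

    engine = VariantEngine(genome, None, "ref")
    records = traverse(graph, FrameState(), engine, mode="all_frames", k=k)
    return frozenset(rec.kmer for rec in kmerize_all(records, KmerConfig(k=k)))


def allframes_filter(kmer_records, background_kmers: frozenset[str]):
    """all-frames background strategy (sequence-keyed).

    A k-mer is removed iff its string occurs in the all-frames translation of
    the background graph. Build the set with :func:`allframes_background_kmers`.
    """
    return [rec for rec in kmer_records if rec.kmer not in background_kmers]


def apply_mhc_threshold(kmer_records, score_table: pd.DataFrame,
                        config: FilterConfig):
    """Keep k-mers whose MHC binding rank is within the threshold for at
    least one allele (<= at the boundary, i.e. top-2% inclusive by default).

    K-mers absent from the score table are kept with a warning when
    config.keep_unscored, dropped otherwise.
    """
    best_rank = score_table.groupby("kmer")["rank_percent"].min()
    out = []
    unscored = 0
    for rec in kmer_records:
        if rec.kmer in best_rank.index:
            if best_rank[rec.kmer] <= config.mhc_rank_threshold:
                out.append(rec)
        elif config.keep_unscored:
            unscored += 1
            out.append(rec)
        else:
            unscored += 1
    if unscored:
        logger.warning("%d k-mers had no MHC score (%s)", unscored,
                       "kept" if config.keep_unscored else "dropped")
    return out


def novel_frame_only(kmer_records):
    """Negative-control selector: k-mers translated exclusively in reading
    frames absent from the annotation (frame_annotated false)."""
    return [rec for rec in kmer_records if not rec.frame_annotated]
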