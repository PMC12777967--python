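"""Pipeline orchestration: wiring graph construction, translation,
k-merization, filtering and digestion into one reproducible run.

The pipeline can run fully in memory (``run_pipeline_data``) or file-to-file
(``run_pipeline``), which also writes a run manifest recording the
configuration snapshot, input digests, per-stage record counts and seed.
Identical manifests imply identical outputs: every stage iterates in a fixed
order and all randomness lives in the synthetic-data seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .filters import (
    FilterConfig,
    allframes_background_kmers,
    allframes_filter,
    annotation_filter,
    apply_mhc_threshold,
    cancer_support_filter,
    foreground_default_rule,
    normalization_factors,
    novel_frame_only,
    requant_filter,
)
from .frames import FrameState, anchor_frames, collect_translation_tuples
from .genome_io import (
    ExpressionTable,
    load_variant_set,
    read_counts,
    read_exclusion_database,
    read_fasta,
    read_gtf,
    read_mhc_scores,
    read_novel_junctions,
    write_kmers,
    write_peptides,
)
from .kmers import KmerConfig, expression_matrix, kmerize_all
from .proteomics import (
    export_tryptic_fasta,
    junction_tryptic_peptides,
    map_kmer_to_context,
)
from .splice_graph import augment_graph, build_graph
from .translate import annotated_proteins, remove_redundant, traverse
from .variants import engines_for_modes

logger = logging.getLogger(__name__)

STAGES = ("graph", "translate", "kmerize", "filter", "mhc", "digest")


@dataclass
class PipelineParams:
    """Non-path parameters of one run."""

    target_sample: str = ""
    foreground_samples: list[str] = field(default_factory=list)
    background_samples: list[str] = field(default_factory=list)
    k: int = 9
    mode: str = "annotated"                 # annotated | all_frames
    variant_mode: str = "ref"               # ref|germline|somatic|germline_somatic|all
    strategy: str | None = "requant"        # requant | allframes | None
    junction_only: bool = True
    apply_redundancy_rule: bool = True
    apply_foreground_rule: bool = True
    filter: FilterConfig = field(default_factory=FilterConfig)
    negative_control: bool = False
    min_fragment_length: int = 7
    missed_cleavages: int = 0
    seed: int = 0


@dataclass
class PipelineResult:
    peptide_records: list
    kmer_records: list          # after k-merization, before filtering
    candidates: list            # after the filtering stack
    expression: pd.DataFrame
    tryptic_entries: list
    stage_counts: dict[str, int]


def _gene_contigs(genes: dict) -> dict[str, str]:
    return {g: txs[0].contig for g, txs in genes.items()}


def run_pipeline_data(
    genome: dict,
    genes: dict,
    counts: ExpressionTable,
    novel_junctions: list,
    variant_set,
    params: PipelineParams,
    mhc_scores: pd.DataFrame | None = None,
    exclusion: frozenset[str] = frozenset(),
    stage: str = "digest",
) -> PipelineResult:
    """Run the pipeline on in-memory inputs up to ``stage``."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    stage_idx = STAGES.index(stage)
    counts_by_stage: dict[str, int] = {}

    fg = params.foreground_samples or counts.sample_ids
    bg = params.background_samples
    target = params.target_sample or fg[0]
    fg_counts = counts.subset(fg)
    bg_counts = counts.subset(bg) if bg else None

    records = []
    bg_graphs = []
    n_vertices = n_edges = 0
    for gene_id in sorted(genes):
        txs = genes[gene_id]
        contig = txs[0].contig
        graph = build_graph(txs)
        fg_graph, _ = augment_graph(graph, novel_junctions)
        n_vertices += len(fg_graph.vertices)
        n_edges += len(fg_graph.edges)
        # background graph: annotation plus novel junctions the background
        # cohort actually reads (SplAdder-style augmentation on normals)
        if bg_counts is not None:
            bg_novel = [
                key for key in novel_junctions
                if key in bg_counts.junction_counts
                and (bg_counts.junction_counts[key] > 0).any()
            ]
            bg_graph, _ = augment_graph(graph, bg_novel)
        else:
            bg_graph = graph
        bg_graphs.append((bg_graph, genome[contig]))

        if stage_idx < STAGES.index("translate"):
            continue
        tuples, _ = collect_translation_tuples(txs)
        anchored = (anchor_frames(fg_graph, tuples) if tuples else FrameState())
        for engine in engines_for_modes(genome[contig], variant_set,
                                        params.variant_mode):
            records.extend(traverse(fg_graph, anchored, engine,
                                    mode=params.mode, k=params.k))
    counts_by_stage["graph_vertices"] = n_vertices
    counts_by_stage["graph_edges"] = n_edges
    if params.apply_redundancy_rule:
        records = remove_redundant(records)
    counts_by_stage["peptides"] = len(records)
    if stage_idx < STAGES.index("kmerize"):
        return PipelineResult(records, [], [], pd.DataFrame(), [],
                              counts_by_stage)

    kconfig = KmerConfig(k=params.k, exclusion_database=exclusion)
    kmers = kmerize_all(records, kconfig)
    counts_by_stage["kmers"] = len(kmers)
    if stage_idx < STAGES.index("filter"):
        expr = expression_matrix(kmers, counts, fg)
        return PipelineResult(records, kmers, [], expr, [], counts_by_stage)

    proteins = annotated_proteins(genes, genome)
    candidates = annotation_filter(kmers, proteins, params.k)
    counts_by_stage["after_annotation_filter"] = len(candidates)
    if params.junction_only:
        candidates = [r for r in candidates if r.is_junction]
        counts_by_stage["junction_kmers"] = len(candidates)

    expr = expression_matrix(candidates, counts, fg)
    factors = normalization_factors(fg_counts.library_sizes)
    if params.apply_foreground_rule and len(expr):
        candidates = foreground_default_rule(candidates, expr, target, factors)
        counts_by_stage["after_foreground_rule"] = len(candidates)

    if params.strategy and bg_counts is not None:
        needs_bg_strings = (
            params.strategy == "allframes"
            or params.variant_mode in ("germline", "germline_somatic", "all")
        )
        bg_strings: frozenset[str] = frozenset()
        if needs_bg_strings:
            acc: set[str] = set()
            for bg_graph, contig_seq in bg_graphs:
                acc |= allframes_background_kmers(bg_graph, contig_seq, params.k)
            bg_strings = frozenset(acc)
        if params.strategy == "requant":
            candidates = requant_filter(
                candidates, bg_counts,
                bg_strings if needs_bg_strings else None)
        elif params.strategy == "allframes":
            candidates = allframes_filter(candidates, bg_strings)
        else:
            raise ValueError(f"unknown strategy {params.strategy!r}")
        counts_by_stage["after_background_strategy"] = len(candidates)

    expr = expression_matrix(candidates, counts, fg)
    if len(expr):
        candidates = cancer_support_filter(candidates, expr, target,
                                           params.filter, factors)
    counts_by_stage["after_cancer_support"] = len(candidates)

    if stage_idx >= STAGES.index("mhc") and mhc_scores is not None:
        candidates = apply_mhc_threshold(candidates, mhc_scores, params.filter)
        counts_by_stage["after_mhc"] = len(candidates)
    if params.negative_control:
        candidates = novel_frame_only(candidates)
        counts_by_stage["negative_control"] = len(candidates)

    tryptic = []
    if stage_idx >= STAGES.index("digest"):
        seen = set()
        for rec in candidates:
            if not rec.is_junction:
                continue
            for context, _ in map_kmer_to_context(rec):
                for frag in junction_tryptic_peptides(
                        context, missed_cleavages=params.missed_cleavages):
                    key = (rec.junction_keys[0] if rec.junction_keys else None,
                           frag.sequence)
                    if key in seen:
                        continue
                    seen.add(key)
                    tryptic.append((target, key[0] or ("", -1, -1),
                                    context, frag))
        counts_by_stage["tryptic_junction_peptides"] = len(tryptic)

    expr = expression_matrix(candidates, counts, fg)
    return PipelineResult(records, kmers, candidates, expr, tryptic,
                          counts_by_stage)


# ---------------------------------------------------------------------------
# File-based run with manifest
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths plus parameters for a file-to-file run."""

    genome: str = ""
    annotation: str = ""
    counts: str = ""
    output_dir: str = "splicepep_out"
    novel_junctions: str | None = None
    germline_vcf: str | None = None
    somatic_vcf: str | None = None
    mhc_scores: str | None = None
    exclusion_database: str | None = None
    whitelist: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known_params = {f.name for f in fields(PipelineParams)}
        known_filter = {f.name for f in fields(FilterConfig)}
        params_kwargs = {}
        filter_kwargs = {}
        cfg_kwargs = {}
        for key, value in raw.items():
            if key in known_filter:
                filter_kwargs[key] = value
            elif key in known_params:
                params_kwargs[key] = value
            else:
                cfg_kwargs[key] = value
        if "sample_whitelist" in filter_kwargs and filter_kwargs["sample_whitelist"]:
            filter_kwargs["sample_whitelist"] = frozenset(
                filter_kwargs["sample_whitelist"])
        params = PipelineParams(filter=FilterConfig(**filter_kwargs),
                                **params_kwargs)
        return cls(params=params, **cfg_kwargs)


def _digest_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, stage: str = "digest") -> dict:
    """Load inputs, run the pipeline, write outputs and the manifest.

    Returns the manifest dict.
    """
    for required in ("genome", "annotation", "counts"):
        if not getattr(config, required):
            raise ValueError(f"missing required input: {required}")
    genome = read_fasta(config.genome)
    genes = read_gtf(config.annotation)
    counts = read_counts(config.counts)
    novel = (read_novel_junctions(config.novel_junctions)
             if config.novel_junctions else [])
    variant_set = None
    if config.germline_vcf or config.somatic_vcf:
        variant_set = load_variant_set(
            config.params.target_sample, config.germline_vcf,
            config.somatic_vcf, genome)
    mhc = read_mhc_scores(config.mhc_scores) if config.mhc_scores else None
    exclusion = (read_exclusion_database(config.exclusion_database)
                 if config.exclusion_database else frozenset())
    if config.whitelist:
        with open(config.whitelist) as handle:
            whitelist = frozenset(l.strip() for l in handle if l.strip())
        config.params.filter = FilterConfig(
            **{**asdict(config.params.filter),
               "sample_whitelist": whitelist})

    result = run_pipeline_data(genome, genes, counts, novel, variant_set,
                               config.params, mhc, exclusion, stage=stage)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if result.peptide_records:
        write_peptides(result.peptide_records, outdir / "peptides.fa",
                       outdir / "peptides.tsv")
    if result.kmer_records:
        write_kmers(result.kmer_records, outdir / "kmers.tsv")
    if result.candidates or stage in ("filter", "mhc", "digest"):
        write_kmers(result.candidates, outdir / "candidates.tsv",
                    expression=result.expression)
    if result.tryptic_entries:
        export_tryptic_fasta(result.tryptic_entries,
                             outdir / "tryptic_junction_peptides.fa",
                             min_length=config.params.min_fragment_length)

    inputs = {}
    for name in ("genome", "annotation", "counts", "novel_junctions",
                 "germline_vcf", "somatic_vcf", "mhc_scores",
                 "exclusion_database", "whitelist"):
        path = getattr(config, name)
        if path:
            inputs[name] = {"path": str(path), "sha256": _digest_file(path)}
    filter_dict = asdict(config.params.filter)
    if filter_dict.get("sample_whitelist") is not None:
        filter_dict["sample_whitelist"] = sorted(filter_dict["sample_whitelist"])
    params_dict = asdict(config.params)
    params_dict["filter"] = filter_dict
    manifest = {
        "tool_version": __version__,
        "stage": stage,
        "seed": config.params.seed,
        "params": params_dict,
        "inputs": inputs,
        "stage_counts": result.stage_counts,
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    for name, count in result.stage_counts.items():
        logger.info("[%s] %s: %d", stage, name, count)
    return manifest
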