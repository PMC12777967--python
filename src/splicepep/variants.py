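"""Sequence personalization: germline application and somatic combinations.

Germline variants are applied jointly (all present or all absent); somatic
mutations are enumerated in all 2^n subset combinations, lazily per exon-pair
span, never genome-wide.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .genome_io import GenomeSequence, ValidationError, Variant, VariantSet

logger = logging.getLogger(__name__)

VARIANT_MODES = ("ref", "germline", "somatic", "germline_somatic")


@dataclass(frozen=True)
class PersonalizedSequence:
    """A genome contig viewed through a set of single-base substitutions.

    Length equals the reference (SNVs only); lookups at substituted positions
    return the alternate base. With an empty substitution map this is the
    identity view of the reference.
    """

    base: GenomeSequence
    substitutions: dict[int, str] = field(default_factory=dict)

    def fetch(self, start: int, end: int) -> str:
        seq = self.base.fetch(start, end)
        if not self.substitutions:
            return seq
        chars = list(seq)
        for pos, alt in self.substitutions.items():
            if start <= pos < end:
                chars[pos - start] = alt
        return "".join(chars)

    def layered(self, variants: list[Variant]) -> "PersonalizedSequence":
        subs = dict(self.substitutions)
        for v in variants:
            if v.position in subs:
                logger.info(
                    "position %d already substituted; somatic overrides", v.position
                )
            subs[v.position] = v.alt
        return PersonalizedSequence(self.base, subs)


@dataclass(frozen=True)
class SomaticSpanSet:
    """Somatic mutations falling inside one exon-pair span [start, end)."""

    span: tuple[int, int]
    mutations: tuple[Variant, ...]

    @property
    def n(self) -> int:
        return len(self.mutations)


def apply_germline(genome: GenomeSequence, germline: list[Variant],
                   mode: str) -> PersonalizedSequence:
    """Return the germline-personalized view of a contig.

    ``mode='germline'`` substitutes every variant jointly; ``mode='reference'``
    returns the identity view. REF bases must match the genome.
    """
    if mode not in ("reference", "germline"):
        raise ValueError(f"mode must be 'reference' or 'germline', got {mode!r}")
    if mode == "reference":
        return PersonalizedSequence(genome, {})
    subs: dict[int, str] = {}
    for v in germline:
        if v.contig != genome.contig_name:
            continue
        actual = genome.fetch(v.position, v.position + 1)
        if actual != v.ref:
            raise ValidationError(
                f"germline REF mismatch at {v.contig}:{v.position}: "
                f"variant says {v.ref}, genome has {actual}"
            )
        subs[v.position] = v.alt
    return PersonalizedSequence(genome, subs)


def somatic_in_span(somatic: list[Variant], span_start: int, span_end: int,
                    contig: str | None = None) -> SomaticSpanSet:
    """Somatic mutations with position in the half-open span [start, end)."""
    hits = tuple(sorted(
        v for v in somatic
        if (contig is None or v.contig == contig)
        and span_start <= v.position < span_end
    ))
    return SomaticSpanSet((span_start, span_end), hits)


def enumerate_combinations(
    span_set: SomaticSpanSet,
    base_sequence: PersonalizedSequence,
    cap: int = 10,
):
    """Yield all 2^n somatic-mutation combinations of one span, lazily.

    Subsets are emitted in binary-counting order over mutations sorted by
    position (the empty subset first), each as
    ``(subset_tuple, personalized_sequence)``.
    """
    if span_set.n > cap:
        raise ValueError(
            f"{span_set.n} somatic mutations in span {span_set.span} exceed "
            f"the combination cap of {cap} (2^n sequences); raise the cap to "
            "proceed"
        )
    muts = span_set.mutations
    for code in range(2 ** span_set.n):
        subset = tuple(m for bit, m in enumerate(muts) if code >> bit & 1)
        yield subset, base_sequence.layered(list(subset))


class VariantEngine:
    """Produces personalized sequence views for one sample and variant mode.

    The germline layer is fixed per mode; somatic subsets are enumerated per
    requested span. Modes: ref, germline, somatic, germline_somatic.
    """

    def __init__(self, genome: GenomeSequence, variant_set: VariantSet | None,
                 mode: str, cap: int = 10):
        if mode not in VARIANT_MODES:
            raise ValueError(f"variant mode {mode!r} not in {VARIANT_MODES}")
        self.mode = mode
        self.cap = cap
        self.variant_set = variant_set or VariantSet(sample_id="")
        germline_mode = ("germline" if mode in ("germline", "germline_somatic")
                         else "reference")
        self.base = apply_germline(genome, self.variant_set.germline, germline_mode)
        self._somatic = (self.variant_set.somatic
                         if mode in ("somatic", "germline_somatic") else [])
        self.contig = genome.contig_name

    def combinations(self, span_start: int, span_end: int):
        span = somatic_in_span(self._somatic, span_start, span_end, self.contig)
        return enumerate_combinations(span, self.base, self.cap)

    def base_view(self) -> PersonalizedSequence:
        """The germline-only view (empty somatic subset)."""
        return self.base


def engines_for_modes(genome: GenomeSequence, variant_set, modes):
    """Build one engine per requested mode ('all' expands to every mode)."""
    if modes == "all":
        modes = list(VARIANT_MODES)
    elif isinstance(modes, str):
        modes = [modes]
    return [VariantEngine(genome, variant_set, m) for m in modes]
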