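"""In-silico tryptic digestion of context peptides for MS validation.

Candidate junction k-mers are mapped back to their longer 2- or 3-exon
context peptides, the context is digested with trypsin (cleavage after K or R
except before P, the Keil rule), and exactly the fragments covering a
junction position are exported. Fragments tile the context peptide, so every
junction reached by translation is covered by at least one fragment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from pyteomics import parser as _pyt_parser

logger = logging.getLogger(__name__)

#: Trypsin cleaves C-terminal of K/R except before proline.
TRYPSIN_RULE = r"[KR](?!P)"

INTERNAL = "internal"
N_TERMINAL = "n_terminal"
C_TERMINAL = "c_terminal"


@dataclass(frozen=True)
class TrypticPeptide:
    sequence: str
    start_offset: int
    end_offset: int
    overlaps_junction: bool = False
    terminal_kind: str = INTERNAL


def tryptic_digest(peptide: str, missed_cleavages: int = 0) -> list[TrypticPeptide]:
    """Digest a peptide with trypsin, keeping fragment offsets.

    With 0 missed cleavages the fragments tile the input. Terminal fragments
    (start-to-first-cleavage, last-cleavage-to-end) are included; a fragment
    spanning the whole peptide (no cleavage site) is labeled n_terminal.
    """
    if not peptide:
        raise ValueError("empty peptide")
    if not 0 <= missed_cleavages <= 2:
        raise ValueError("missed_cleavages must be 0..2")
    out = []
    for start, frag in _pyt_parser.icleave(peptide, TRYPSIN_RULE,
                                           missed_cleavages=missed_cleavages):
        end = start + len(frag)
        if start == 0:
            kind = N_TERMINAL
        elif end == len(peptide):
            kind = C_TERMINAL
        else:
            kind = INTERNAL
        out.append(TrypticPeptide(frag, start, end, terminal_kind=kind))
    return sorted(out, key=lambda f: (f.start_offset, f.end_offset))


def map_kmer_to_context(kmer_record, peptide_records=None):
    """Map a k-mer back to its context peptide record(s) with its offset.

    The primary context is the source record the k-mer was generated from;
    when a list of peptide records is given, every record containing the
    k-mer string is returned (multi-mapping preserved).
    """
    if peptide_records is None:
        if kmer_record.source is None:
            raise ValueError(f"k-mer {kmer_record.kmer} has no source record")
        return [(kmer_record.source, kmer_record.offset)]
    hits = []
    for rec in peptide_records:
        pos = rec.peptide.find(kmer_record.kmer)
        while pos >= 0:
            hits.append((rec, pos))
            pos = rec.peptide.find(kmer_record.kmer, pos + 1)
    if not hits:
        raise ValueError(
            f"k-mer {kmer_record.kmer} maps to no context peptide"
        )
    return hits


def junction_tryptic_peptides(context_record, digest=None,
                              missed_cleavages: int = 0) -> list[TrypticPeptide]:
    """Fragments of a context peptide that overlap a junction position.

    A fragment overlaps junction m when it contains both codons flanking the
    junction (one codon when a single codon straddles it).
    """
    if digest is None:
        digest = tryptic_digest(context_record.peptide, missed_cleavages)
    spans = [context_record.junction_aa_span(m)
             for m in range(len(context_record.junction_coords))]
    spans = [s for s in spans if s is not None]
    out = []
    for frag in digest:
        if any(frag.start_offset <= left and frag.end_offset >= right + 1
               for left, right in spans):
            out.append(TrypticPeptide(frag.sequence, frag.start_offset,
                                      frag.end_offset, overlaps_junction=True,
                                      terminal_kind=frag.terminal_kind))
    return out


def export_tryptic_fasta(entries, path: str | Path,
                         min_length: int = 7) -> int:
    """Write tryptic junction-peptides as FASTA for external MS search.

    ``entries`` are (sample_id, junction_key, context_record, fragment)
    tuples. The minimum fragment length (default 7 aa, a common search-engine
    floor) applies only here, at export. Returns the number written.
    """
    n = 0
    with open(path, "w") as out:
        for sample_id, key, record, frag in entries:
            if len(frag.sequence) < min_length:
                continue
            contig, donor, acceptor = key
            header = (
                f">tjp_{n:06d} sample={sample_id} "
                f"junction={contig}:{donor}:{acceptor} gene={record.gene_id} "
                f"frame_annotated={record.frame_annotated} "
                f"terminal={frag.terminal_kind}"
            )
            out.write(f"{header}\n{frag.sequence}\n")
            n += 1
    return n
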