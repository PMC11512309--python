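"""Integration-site calling from aligned genomic flanks.

An integration site is the single LTR-proximal genomic base where the flank
begins: alignment start on the plus strand, alignment end - 1 on the minus
strand.  Only alignments that consume the read from its first base (no 5'
clipping) and hit the genome uniquely are used.  Sites need at least
``min_support`` reads, and among retained sites within the collapse window
on one strand only the best-supported one survives.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pysam

from .errors import InvalidParameterError


@dataclass(frozen=True)
class FlankAlignment:
    read_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    aligned_from_read_start: bool
    unique_hit: bool


@dataclass(frozen=True)
class IntegrationSite:
    chrom: str
    position: int  # 0-based single base
    strand: str
    read_support: int


def _occurrences(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def naive_align(flank: str, genome, read_id: str = "") -> FlankAlignment | None:
    """Exact-match search of a flank (and its reverse complement) in a toy
    genome: the hermetic stand-in for a short-read aligner.

    Returns the first occurrence in genome order, flagged unique iff exactly
    one occurrence exists over both strands; None when the flank is absent.
    """
    from .synthetic import revcomp

    if len(flank) < 15:
        raise InvalidParameterError("flank must be >= 15 bases")
    hits: list[tuple[str, int, str]] = []
    rc = revcomp(flank)
    for name, seq in genome.chromosomes:
        hits.extend((name, i, "+") for i in _occurrences(seq, flank))
        hits.extend((name, i, "-") for i in _occurrences(seq, rc))
    if not hits:
        return None
    hits.sort()
    chrom, start, strand = hits[0]
    return FlankAlignment(
        read_id, chrom, start, start + len(flank), strand,
        aligned_from_read_start=True, unique_hit=len(hits) == 1,
    )


def alignments_from_sam(path: str, unique_by_xs: bool = True):
    """Yield FlankAlignments from a SAM/BAM file.

    Start anchoring requires no clip at the read's 5' end (cigar order is
    reference order, so for reverse-strand alignments the read start is the
    final cigar operation).  Uniqueness is XS-tag absence (no secondary
    alignment score), the aligner's single-hit signal.  Unmapped, secondary
    and supplementary records are skipped.
    """
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            cig = aln.cigartuples
            if not cig:
                continue
            lead = cig[-1] if aln.is_reverse else cig[0]
            from_start = lead[0] not in (4, 5)  # no soft/hard clip at read start
            unique = not aln.has_tag("XS") if unique_by_xs else True
            yield FlankAlignment(
                aln.query_name,
                aln.reference_name,
                aln.reference_start,
                aln.reference_end,
                "-" if aln.is_reverse else "+",
                aligned_from_read_start=from_start,
                unique_hit=unique,
            )


def filter_alignments(alignments) -> list[FlankAlignment]:
    """Retain alignments that are start-anchored and genome-unique."""
    return [a for a in alignments if a.aligned_from_read_start and a.unique_hit]


def alignment_to_position(aln: FlankAlignment) -> tuple[str, int, str]:
    """LTR-proximal base of an alignment: start on +, end - 1 on -."""
    pos = aln.start if aln.strand == "+" else aln.end - 1
    return aln.chrom, pos, aln.strand


def call_sites(positions, min_support: int = 5, window: int = 5) -> list[IntegrationSite]:
    """Collapse per-read positions into supported integration sites.

    Reads are counted per exact (chrom, position, strand); positions below
    ``min_support`` are dropped; then, per chromosome and strand, retained
    positions within ``window`` bases of one another (|p1 - p2| <= window)
    are resolved greedily by descending support, ties to the smaller
    coordinate.  The survivor keeps its own support count — read counts are
    never merged.  Output is sorted and independent of input order.
    """
    if min_support < 1 or window < 0:
        raise InvalidParameterError("min_support >= 1 and window >= 0 required")
    counts = Counter((c, s, p) for c, p, s in positions)
    by_group: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for (chrom, strand, pos), n in counts.items():
        if n >= min_support:
            by_group.setdefault((chrom, strand), []).append((pos, n))
    out: list[IntegrationSite] = []
    for (chrom, strand), cands in by_group.items():
        cands.sort(key=lambda t: (-t[1], t[0]))
        chosen: list[tuple[int, int]] = []
        for pos, n in cands:
            if all(abs(pos - p) > window for p, _ in chosen):
                chosen.append((pos, n))
        out.extend(IntegrationSite(chrom, p, strand, n) for p, n in chosen)
    out.sort(key=lambda s: (s.chrom, s.position, s.strand))
    return out


def align_and_call(
    trimmed_reads, genome, min_support: int = 5, window: int = 5
) -> list[IntegrationSite]:
    """Hermetic flank -> site pipeline: exact alignment, start/uniqueness
    filtering, position extraction, site calling."""
    _MISS = object()
    cache: dict[str, object] = {}
    positions = []
    for tr in trimmed_reads:
        aln = cache.get(tr.flank, _MISS)
        if aln is _MISS:
            aln = naive_align(tr.flank, genome, tr.id)
            cache[tr.flank] = aln
        if aln is None:
            continue
        if aln.aligned_from_read_start and aln.unique_hit:
            positions.append(alignment_to_position(aln))
    return call_sites(positions, min_support, window)
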