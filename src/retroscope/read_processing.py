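"""Demultiplexing and the four-stage LTR-junction trimming cascade.

Raw junction reads have the layout

    barcode + LTR-primer region + terminal LTR 9-mer + genomic flank + adapter

and are reduced to their genomic flank by, in order: an anchored trim of the
LTR-primer region (untrimmed reads discarded), an anchored trim of the
terminal LTR 9-mer (untrimmed discarded, survivors shorter than 15 bases
discarded), removal of the 3' sequencing adapter, and a scan for an internal
proviral decoy sequence whose presence discards the read.

Matching is substitution-only (no indels) with a per-match error budget of
``floor(max_error_rate * matched_length)``, mirroring cutadapt's -e
semantics; partial patterns are honoured at read boundaries down to each
stage's minimum overlap.  N bases always count as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidParameterError

DEFAULT_LTR_PRIMER = "GCTTGCCAAACCTACAGGTG"
DEFAULT_LTR_TERMINAL = "GGTCTTTCA"
DEFAULT_ADAPTER = "ACCACTAGTGTCGAC"
DEFAULT_INTERNAL_DECOY = "TTCCCCCCTT"


@dataclass(frozen=True)
class RawRead:
    """A FASTQ read: id, sequence and (optional) per-base quality string."""

    id: str
    sequence: str
    quality: str = ""

    def __post_init__(self) -> None:
        if self.quality and len(self.quality) != len(self.sequence):
            raise InvalidParameterError(
                f"read {self.id!r}: sequence and quality lengths differ"
            )

    def slice(self, start: int, end: int | None = None) -> "RawRead":
        end = len(self.sequence) if end is None else end
        q = self.quality[start:end] if self.quality else ""
        return RawRead(self.id, self.sequence[start:end], q)


@dataclass(frozen=True)
class TrimSpec:
    """Landmarks and thresholds of the trimming cascade."""

    barcode_set: dict[str, str] = field(default_factory=dict)
    ltr_primer: str = DEFAULT_LTR_PRIMER
    ltr_terminal: str = DEFAULT_LTR_TERMINAL
    adapter: str = DEFAULT_ADAPTER
    internal_decoy: str = DEFAULT_INTERNAL_DECOY
    barcode_min_overlap: int = 8
    primer_min_overlap: int = 20
    terminal_min_overlap: int = 8
    adapter_min_overlap: int = 10
    decoy_min_overlap: int = 10
    min_flank_length: int = 15
    max_error_rate: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.max_error_rate < 0.5):
            raise InvalidParameterError("max_error_rate must lie in [0, 0.5)")
        for name, pattern, overlap in [
            ("ltr_primer", self.ltr_primer, self.primer_min_overlap),
            ("ltr_terminal", self.ltr_terminal, self.terminal_min_overlap),
            ("adapter", self.adapter, self.adapter_min_overlap),
            ("internal_decoy", self.internal_decoy, self.decoy_min_overlap),
        ]:
            if not pattern:
                raise InvalidParameterError(f"{name} must be non-empty")
            if overlap > len(pattern):
                raise InvalidParameterError(
                    f"{name}: min_overlap {overlap} exceeds pattern length"
                )


@dataclass(frozen=True)
class TrimmedRead:
    id: str
    barcode_group: str | None
    flank: str
    trim_log: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class Rejection:
    """Normal (non-exceptional) outcome for a read removed by the cascade."""

    read_id: str
    reason: str  # untrimmed | trimmed | no_primer | no_terminal | too_short | internal


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def match_anchored_prefix(
    sequence: str, pattern: str, min_overlap: int, max_error_rate: float
) -> int | None:
    """Length consumed by a 5'-anchored match of ``pattern``, or None.

    The full pattern is required when the read is long enough; a shorter read
    may be matched by a pattern prefix of at least ``min_overlap`` bases.
    """
    matched = min(len(sequence), len(pattern))
    if matched < min_overlap:
        return None
    allowed = int(max_error_rate * matched)
    if _mismatches(sequence[:matched], pattern[:matched]) <= allowed:
        return matched
    return None


def find_internal(
    sequence: str, pattern: str, min_overlap: int, max_error_rate: float
) -> tuple[int, int] | None:
    """Best (fewest-mismatch, leftmost) full occurrence of ``pattern``."""
    if len(pattern) < min_overlap:
        return None
    allowed = int(max_error_rate * len(pattern))
    best: tuple[int, int] | None = None  # (mismatches, start)
    for i in range(len(sequence) - len(pattern) + 1):
        m = _mismatches(sequence[i : i + len(pattern)], pattern)
        if m <= allowed and (best is None or m < best[0]):
            best = (m, i)
            if m == 0:
                break
    if best is None:
        return None
    return best[1], best[1] + len(pattern)


def find_adapter_3prime(
    sequence: str, adapter: str, min_overlap: int, max_error_rate: float
) -> int | None:
    """Start of the 3' adapter match, or None.

    A full internal occurrence is preferred; otherwise the longest adapter
    prefix of at least ``min_overlap`` bases ending exactly at the read's 3'
    end counts as a match.
    """
    hit = find_internal(sequence, adapter, min_overlap, max_error_rate)
    if hit is not None:
        return hit[0]
    for k in range(min(len(adapter) - 1, len(sequence)), min_overlap - 1, -1):
        if _mismatches(sequence[-k:], adapter[:k]) <= int(max_error_rate * k):
            return len(sequence) - k
    return None


def anchored_prefix_trim(
    read: RawRead,
    pattern: str,
    min_overlap: int,
    max_error_rate: float = 0.1,
    action: str = "keep",
    anchored: bool = True,
) -> RawRead | Rejection:
    """One cutadapt-style 5' trimming stage.

    ``anchored`` selects -g^PATTERN semantics (match must start at the read's
    first base); otherwise the best internal occurrence is used and all bases
    through the match end are removed.  ``action`` is ``discard_untrimmed``,
    ``discard_trimmed`` or ``keep``; rejection is a normal outcome carrying a
    reason code, never an exception.
    """
    if not pattern:
        raise InvalidParameterError("pattern must be non-empty")
    if anchored:
        consumed = match_anchored_prefix(read.sequence, pattern, min_overlap, max_error_rate)
        span = None if consumed is None else (0, consumed)
    else:
        span = find_internal(read.sequence, pattern, min_overlap, max_error_rate)
    if span is None:
        if action == "discard_untrimmed":
            return Rejection(read.id, "untrimmed")
        return read
    if action == "discard_trimmed":
        return Rejection(read.id, "trimmed")
    return read.slice(span[1])


def three_prime_adapter_trim(
    read: RawRead, adapter: str, min_overlap: int = 10, max_error_rate: float = 0.1
) -> RawRead:
    """Remove a 3' adapter and everything downstream; pass through unchanged
    when no match of at least ``min_overlap`` bases is found."""
    start = find_adapter_3prime(read.sequence, adapter, min_overlap, max_error_rate)
    if start is None:
        return read
    return read.slice(0, start)


def demultiplex(
    reads,
    barcode_set: dict[str, str],
    min_overlap: int = 8,
    max_error_rate: float = 0.1,
) -> tuple[dict[str, list[RawRead]], list[RawRead]]:
    """Assign reads to barcode groups by best-scoring anchored prefix match.

    The barcode is removed and the group name is prepended to the read id.
    Reads matching no barcode, or tying between two barcodes, are returned
    unassigned.  Output is independent of input read order.
    """
    if not barcode_set:
        raise InvalidParameterError("barcode_set must be non-empty")
    groups: dict[str, list[RawRead]] = {name: [] for name in barcode_set}
    unassigned: list[RawRead] = []
    for read in reads:
        scored: list[tuple[int, int, str]] = []  # (mismatches, consumed, name)
        for name, bc in barcode_set.items():
            matched = min(len(read.sequence), len(bc))
            if matched < min_overlap:
                continue
            m = _mismatches(read.sequence[:matched], bc[:matched])
            if m <= int(max_error_rate * matched):
                scored.append((m, matched, name))
        if not scored:
            unassigned.append(read)
            continue
        scored.sort(key=lambda t: t[0])
        if len(scored) > 1 and scored[0][0] == scored[1][0]:
            unassigned.append(read)  # ambiguous tie
            continue
        m, consumed, name = scored[0]
        trimmed = read.slice(consumed)
        groups[name].append(RawRead(f"{name}:{read.id}", trimmed.sequence, trimmed.quality))
    return groups, unassigned


def process_read(
    read: RawRead, spec: TrimSpec, barcode_group: str | None = None
) -> TrimmedRead | Rejection:
    """Run one demultiplexed read through the full trimming cascade.

    Rejection reasons: ``no_primer`` (LTR-primer region absent),
    ``no_terminal`` (terminal LTR 9-mer absent), ``too_short`` (flank below
    the minimum length), ``internal`` (inner proviral decoy present).
    """
    log: list[tuple[str, str]] = []
    r = anchored_prefix_trim(
        read, spec.ltr_primer, spec.primer_min_overlap, spec.max_error_rate,
        action="discard_untrimmed",
    )
    if isinstance(r, Rejection):
        return Rejection(read.id, "no_primer")
    log.append(("ltr_primer", "trimmed"))

    r = anchored_prefix_trim(
        r, spec.ltr_terminal, spec.terminal_min_overlap, spec.max_error_rate,
        action="discard_untrimmed",
    )
    if isinstance(r, Rejection):
        return Rejection(read.id, "no_terminal")
    log.append(("ltr_terminal", "trimmed"))
    if len(r.sequence) < spec.min_flank_length:
        return Rejection(read.id, "too_short")

    r2 = three_prime_adapter_trim(r, spec.adapter, spec.adapter_min_overlap, spec.max_error_rate)
    log.append(("adapter", "trimmed" if len(r2.sequence) < len(r.sequence) else "untrimmed"))
    if len(r2.sequence) < spec.min_flank_length:
        return Rejection(read.id, "too_short")

    decoy = find_internal(
        r2.sequence, spec.internal_decoy, spec.decoy_min_overlap, spec.max_error_rate
    )
    if decoy is not None:
        return Rejection(read.id, "internal")
    log.append(("internal_decoy", "absent"))
    return TrimmedRead(read.id, barcode_group, r2.sequence, tuple(log))


def trim_pipeline(
    reads, spec: TrimSpec
) -> tuple[list[TrimmedRead], list[Rejection]]:
    """Apply :func:`process_read` to an iterable of reads."""
    kept: list[TrimmedRead] = []
    rejected: list[Rejection] = []
    for read in reads:
        out = process_read(read, spec)
        (kept if isinstance(out, TrimmedRead) else rejected).append(out)
    return kept, rejected


def rejection_report(
    kept: list[TrimmedRead], rejected: list[Rejection]
) -> pd.DataFrame:
    """Per-reason read counts, as written to the trimming report TSV."""
    counts = pd.Series([r.reason for r in rejected], dtype=object).value_counts()
    rows = [("passed", len(kept))] + list(counts.items())
    return pd.DataFrame(rows, columns=["outcome", "reads"])
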