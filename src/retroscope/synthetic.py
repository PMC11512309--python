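"""Synthetic study data: toy genomes, chromatin annotations, planted
integration sites, LTR-junction reads, ddPCR droplets and flow events.

Every generator takes an explicit integer seed and is bit-reproducible, so
each downstream pipeline stage can be tested against planted ground truth
without any external download.  The generators model the *statistical*
structure the analysis assumes — read layout, Poisson droplet occupancy, a
bimodal silent/active reporter mixture — not sequencing chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, MissingFeatureError
from .feature_annotation import FeatureSet
from .read_processing import (
    DEFAULT_ADAPTER,
    DEFAULT_INTERNAL_DECOY,
    DEFAULT_LTR_PRIMER,
    DEFAULT_LTR_TERMINAL,
    RawRead,
)

BASES = "ACGT"
SUBCOMPARTMENT_LABELS = ("A1", "A2", "B1", "B2", "B3")
LAD_LABEL = "LAD"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# genome


@dataclass(frozen=True)
class ToyGenome:
    """A small random genome: named chromosomes over the A/C/G/T alphabet."""

    chromosomes: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise InvalidParameterError("chromosome names must be unique")
        for name, seq in self.chromosomes:
            if not seq:
                raise InvalidParameterError(f"chromosome {name!r} is empty")
            if set(seq) - set(BASES):
                raise InvalidParameterError(
                    f"chromosome {name!r} contains non-ACGT characters"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.chromosomes)

    def sequence(self, name: str) -> str:
        for n, s in self.chromosomes:
            if n == name:
                return s
        raise KeyError(name)


def build_toy_genome(n_chrom: int, lengths: list[int], seed: int) -> ToyGenome:
    """Uniform-composition random genome with ``n_chrom`` chromosomes."""
    if n_chrom != len(lengths):
        raise InvalidParameterError("n_chrom must equal len(lengths)")
    if any(length <= 0 for length in lengths):
        raise InvalidParameterError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    chroms = []
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    for i, length in enumerate(lengths):
        codes = rng.integers(0, 4, size=length)
        chroms.append((f"chr{i + 1}", base_arr[codes].tobytes().decode()))
    return ToyGenome(tuple(chroms))


# ---------------------------------------------------------------------------
# annotations


@dataclass(frozen=True)
class AnnotationBundle:
    """Chromatin annotations of a toy genome, grouped by family.

    ``segments`` mimics a chromHMM-style segmentation (labels like Tss, Enh,
    Gen5; one FeatureSet per label, disjoint within a label), the five
    ``subcompartments`` are mutually disjoint, and ``lads`` is a single
    interval set.  ``coverage_fractions`` records the realized genome
    fraction covered per label.
    """

    segments: dict[str, FeatureSet]
    subcompartments: dict[str, FeatureSet]
    lads: FeatureSet
    coverage_fractions: dict[str, float]

    def feature_set(self, label: str) -> FeatureSet:
        if label in self.segments:
            return self.segments[label]
        if label in self.subcompartments:
            return self.subcompartments[label]
        if label == self.lads.label:
            return self.lads
        raise MissingFeatureError(label)


def _place_disjoint(
    items: list[tuple[str, int]],
    genome: ToyGenome,
    rng: np.random.Generator,
) -> dict[str, list[tuple[str, int, int]]]:
    """Place (label, length) intervals uniformly and without mutual overlap.

    Each interval is assigned a chromosome with probability proportional to
    chromosome length; within a chromosome, k intervals of total length S
    are placed by drawing k sorted offsets from [0, L - S] and stacking —
    the classic construction for uniform non-overlapping placement.
    """
    out: dict[str, list[tuple[str, int, int]]] = {}
    if not items:
        return out
    names = [n for n, _ in genome.chromosomes]
    lens = np.array([genome.lengths[n] for n in names], dtype=np.int64)
    probs = lens / lens.sum()
    need = sum(L for _, L in items)
    if need > genome.total_length:
        raise InvalidParameterError("requested annotation coverage exceeds genome size")
    for _ in range(200):
        assignment = rng.choice(len(names), size=len(items), p=probs)
        per_chrom_need = np.bincount(
            assignment, weights=[L for _, L in items], minlength=len(names)
        )
        if np.all(per_chrom_need <= lens):
            break
    else:
        raise InvalidParameterError(
            "could not place annotation intervals without overlap; "
            "coverage too high for this genome"
        )
    for ci, name in enumerate(names):
        idx = [i for i in range(len(items)) if assignment[i] == ci]
        if not idx:
            continue
        order = rng.permutation(len(idx))
        idx = [idx[i] for i in order]
        lengths = np.array([items[i][1] for i in idx], dtype=np.int64)
        slack = int(lens[ci] - lengths.sum())
        draws = np.sort(rng.integers(0, slack + 1, size=len(idx)))
        starts = draws + np.concatenate([[0], np.cumsum(lengths[:-1])])
        for j, i in enumerate(idx):
            label, L = items[i]
            out.setdefault(label, []).append((name, int(starts[j]), int(starts[j] + L)))
    return out


def generate_annotations(
    genome: ToyGenome,
    spec: dict[str, tuple[int, int, float | None]],
    seed: int,
) -> AnnotationBundle:
    """Generate an annotation bundle from ``label -> (n_intervals,
    interval_length, target_coverage)`` requests.

    ``target_coverage`` may be None; when given, ``n_intervals *
    interval_length`` must realize it within 1% of the genome, otherwise the
    request is rejected as infeasible.  Labels A1..B3 form the disjoint
    subcompartment family (placed jointly), the label ``LAD`` fills the LAD
    set, and every other label is an independent segment class.
    """
    rng = np.random.default_rng(seed)
    total = genome.total_length
    for label, (n, L, target) in spec.items():
        if n < 0 or (n > 0 and L <= 0):
            raise InvalidParameterError(f"{label}: invalid interval request")
        if target is not None:
            if not 0 <= target <= 1:
                raise InvalidParameterError(f"{label}: coverage must lie in [0, 1]")
            if abs(n * L / total - target) > 0.01:
                raise InvalidParameterError(
                    f"{label}: {n} x {L} bp realizes coverage {n * L / total:.4f}, "
                    f"not within 1% of target {target}"
                )

    sub_items = [
        (label, spec[label][1])
        for label in SUBCOMPARTMENT_LABELS
        if label in spec
        for _ in range(spec[label][0])
    ]
    placed_sub = _place_disjoint(sub_items, genome, rng)
    subcompartments = {
        label: FeatureSet(label, placed_sub.get(label, []))
        for label in SUBCOMPARTMENT_LABELS
        if label in spec
    }

    segments: dict[str, FeatureSet] = {}
    lads = FeatureSet(LAD_LABEL, [])
    for label, (n, L, _) in spec.items():
        if label in SUBCOMPARTMENT_LABELS:
            continue
        placed = _place_disjoint([(label, L)] * n, genome, rng)
        fs = FeatureSet(label, placed.get(label, []))
        if label == LAD_LABEL:
            lads = fs
        else:
            segments[label] = fs

    coverage = {
        label: fs.total_bases() / total
        for label, fs in {**segments, **subcompartments, LAD_LABEL: lads}.items()
        if label in spec
    }
    return AnnotationBundle(segments, subcompartments, lads, coverage)


# ---------------------------------------------------------------------------
# integration sites


@dataclass(frozen=True)
class UniformBias:
    """Sites placed i.i.d. uniformly over the genome."""


@dataclass(frozen=True)
class FeatureProximityBias:
    """With probability ``weight`` a site lands an Exp(decay_bp)-distributed
    distance from a uniformly chosen interval of ``label``; otherwise uniform.

    Emulates the promoter/enhancer-proximal targeting preference of
    gammaretroviral integration."""

    label: str
    weight: float = 1.0
    decay_bp: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.weight <= 1:
            raise InvalidParameterError("weight must lie in [0, 1]")
        if self.decay_bp <= 0:
            raise InvalidParameterError("decay_bp must be positive")


@dataclass(frozen=True)
class PlantedSite:
    chrom: str
    position: int
    strand: str
    read_count: int


@dataclass(frozen=True)
class PlantedISSet:
    """Ground-truth integration sites for recovery tests."""

    sites: tuple[PlantedSite, ...]
    bias_model: object
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.chrom, s.position, s.strand, s.read_count) for s in self.sites],
            columns=["chrom", "position", "strand", "read_count"],
        )


def _uniform_position(
    rng: np.random.Generator, names: list[str], offsets: np.ndarray
) -> tuple[str, int]:
    flat = int(rng.integers(0, offsets[-1]))
    ci = int(np.searchsorted(offsets, flat, side="right") - 1)
    return names[ci], flat - int(offsets[ci])


def plant_integration_sites(
    genome: ToyGenome,
    annotations: AnnotationBundle | None,
    n_sites: int,
    bias_model,
    seed: int,
    support_range: tuple[int, int] = (5, 30),
    min_separation: int = 0,
) -> PlantedISSet:
    """Plant ``n_sites`` ground-truth integration sites.

    ``support_range`` bounds the per-site planted read count (uniform
    integer, inclusive).  ``min_separation`` > 0 redraws candidates landing
    within that distance of an accepted site on the same chromosome and
    strand, which makes downstream exact-recovery assertions well posed.
    """
    if n_sites < 1:
        raise InvalidParameterError("n_sites must be >= 1")
    if support_range[0] < 1 or support_range[0] > support_range[1]:
        raise InvalidParameterError("invalid support_range")
    rng = np.random.default_rng(seed)
    names = [n for n, _ in genome.chromosomes]
    lens = np.array([genome.lengths[n] for n in names], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)])

    proximal = isinstance(bias_model, FeatureProximityBias)
    if proximal:
        if annotations is None:
            raise MissingFeatureError(bias_model.label)
        intervals = annotations.feature_set(bias_model.label).intervals
        if not intervals:
            raise MissingFeatureError(bias_model.label)

    sites: list[PlantedSite] = []
    attempts = 0
    while len(sites) < n_sites:
        attempts += 1
        if attempts > 100 * n_sites + 1000:
            raise InvalidParameterError(
                "could not satisfy min_separation; too many sites for this genome"
            )
        if proximal and rng.random() < bias_model.weight:
            chrom, s, e = intervals[int(rng.integers(0, len(intervals)))]
            d = int(rng.exponential(bias_model.decay_bp))
            if rng.random() < 0.5:
                pos = e + d
            else:
                pos = s - 1 - d
            pos = int(np.clip(pos, 0, genome.lengths[chrom] - 1))
        else:
            chrom, pos = _uniform_position(rng, names, offsets)
        strand = "+" if rng.random() < 0.5 else "-"
        if min_separation > 0 and any(
            s.chrom == chrom and s.strand == strand and abs(s.position - pos) < min_separation
            for s in sites
        ):
            continue
        count = int(rng.integers(support_range[0], support_range[1] + 1))
        sites.append(PlantedSite(chrom, pos, strand, count))
    return PlantedISSet(tuple(sites), bias_model, seed)


# ---------------------------------------------------------------------------
# junction reads


@dataclass(frozen=True)
class ReadSimConfig:
    """Layout and error model of simulated LTR-junction reads."""

    barcode: str = "ACGTACGT"
    ltr_primer_region: str = DEFAULT_LTR_PRIMER
    ltr_terminal: str = DEFAULT_LTR_TERMINAL
    adapter: str = DEFAULT_ADAPTER
    internal_decoy: str = DEFAULT_INTERNAL_DECOY
    flank_length: int = 30
    substitution_rate: float = 0.0
    internal_read_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("barcode", "ltr_primer_region", "ltr_terminal", "adapter",
                     "internal_decoy"):
            if not getattr(self, name):
                raise InvalidParameterError(f"{name} must be non-empty")
        for name in ("substitution_rate", "internal_read_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if self.flank_length < 15:
            raise InvalidParameterError("flank_length must be >= 15")


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        current = chr(arr[i])
        choices = [b for b in BASES if b != current]
        arr[i] = ord(choices[int(rng.integers(0, 3))])
    return arr.tobytes().decode()


def simulate_junction_reads(
    genome: ToyGenome, sites: PlantedISSet, cfg: ReadSimConfig
) -> tuple[list[RawRead], pd.DataFrame]:
    """Emit junction reads for every planted site, plus a truth table.

    Each read is barcode + LTR-primer region + terminal LTR 9-mer + genomic
    flank + adapter.  The flank starts at the site position and runs 3'-ward
    on the site's strand: plus-strand genome[pos, pos+L), minus-strand the
    reverse complement of genome[pos-L+1, pos+1), so that mapping the flank
    recovers the LTR-proximal base.  Decoy reads carry the internal proviral
    sequence immediately after the terminal 9-mer.  Flanks running off a
    chromosome end are truncated and recorded, not errors.
    """
    rng = np.random.default_rng(cfg.seed)
    reads: list[RawRead] = []
    rows = []
    L = cfg.flank_length
    for si, site in enumerate(sites.sites):
        seq = genome.sequence(site.chrom)
        if site.strand == "+":
            end = min(site.position + L, len(seq))
            flank = seq[site.position : end]
        else:
            start = max(site.position - L + 1, 0)
            flank = revcomp(seq[start : site.position + 1])
        truncated = len(flank) < L
        for j in range(site.read_count):
            is_decoy = bool(rng.random() < cfg.internal_read_fraction)
            insert = cfg.internal_decoy if is_decoy else ""
            raw = (
                cfg.barcode + cfg.ltr_primer_region + cfg.ltr_terminal
                + insert + flank + cfg.adapter
            )
            raw = _substitute(raw, cfg.substitution_rate, rng)
            rid = f"site{si:04d}_r{j:03d}"
            reads.append(RawRead(rid, raw, "I" * len(raw)))
            rows.append(
                (rid, site.chrom, site.position, site.strand, flank, is_decoy, truncated)
            )
    truth = pd.DataFrame(
        rows,
        columns=["read_id", "chrom", "position", "strand", "flank", "is_decoy", "truncated"],
    )
    return reads, truth


# ---------------------------------------------------------------------------
# ddPCR droplets


@dataclass(frozen=True)
class DropletSimConfig:
    """A ddPCR well: droplet partitioning of a template at known concentration."""

    n_droplets: int = 15000
    droplet_volume: float = 0.00085  # microlitres, QX200 convention
    well_volume: float = 20.0  # microlitres
    true_concentration: float = 1.0  # copies per microlitre
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise InvalidParameterError("n_droplets must be positive")
        if self.droplet_volume <= 0 or self.well_volume <= 0:
            raise InvalidParameterError("volumes must be positive")
        if self.true_concentration < 0:
            raise InvalidParameterError("concentration must be >= 0")


def simulate_droplets(cfg: DropletSimConfig) -> tuple[int, int]:
    """(positive_droplets, total_droplets) under Poisson occupancy.

    A droplet is positive iff it received >= 1 template molecule, i.e. with
    probability 1 - exp(-concentration * droplet_volume)."""
    rng = np.random.default_rng(cfg.seed)
    p = 1.0 - np.exp(-cfg.true_concentration * cfg.droplet_volume)
    return int(rng.binomial(cfg.n_droplets, p)), cfg.n_droplets


# ---------------------------------------------------------------------------
# flow cytometry events


@dataclass(frozen=True)
class FlowSimConfig:
    """A flow sample: two-component log-intensity mixture plus viability dye.

    ``active_fraction`` is the weight of the bright (expressing) component;
    Hoechst-positive events model dead cells removed by viability gating.
    Log-means/sds are log10 of arbitrary fluorescence units; the defaults
    separate the components by several standard deviations, as in a
    well-resolved GFP reporter measurement.
    """

    n_events: int = 10000
    active_fraction: float = 0.5
    active_log_mean: float = 4.0
    active_log_sd: float = 0.3
    background_log_mean: float = 1.5
    background_log_sd: float = 0.3
    hoechst_positive_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("active_fraction", "hoechst_positive_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if self.active_log_sd <= 0 or self.background_log_sd <= 0:
            raise InvalidParameterError("log-sds must be positive")
        if self.n_events <= 0:
            raise InvalidParameterError("n_events must be positive")


def simulate_flow_events(cfg: FlowSimConfig) -> pd.DataFrame:
    """Event table with ``gfp_intensity`` (linear units) and
    ``hoechst_positive`` columns."""
    rng = np.random.default_rng(cfg.seed)
    active = rng.random(cfg.n_events) < cfg.active_fraction
    logs = np.where(
        active,
        rng.normal(cfg.active_log_mean, cfg.active_log_sd, cfg.n_events),
        rng.normal(cfg.background_log_mean, cfg.background_log_sd, cfg.n_events),
    )
    hoechst = rng.random(cfg.n_events) < cfg.hoechst_positive_fraction
    return pd.DataFrame(
        {"gfp_intensity": 10.0 ** logs, "hoechst_positive": hoechst, "active": active}
    )
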