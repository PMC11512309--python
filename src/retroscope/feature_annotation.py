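"""Annotation of integration sites against chromatin features.

Feature classes (chromHMM-style segments, Hi-C A/B subcompartments,
lamina-associated domains) are held as sorted half-open interval sets.
Sites are single-base, strand-aware positions in a pandas DataFrame with
columns ``chrom``, ``position``, ``strand``.

Distances are unsigned base-pair gaps: a site overlapping a feature is at
distance 0, and a site immediately adjacent to a feature boundary
(book-ended) is also at distance 0.  Some ``bedtools closest -d`` dialects
report book-ended pairs as 1; at the kilobase-scale medians this pipeline
summarises, the difference is immaterial, but the convention here is fixed
and tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ChromosomeMismatchError, MalformedAnnotationError

SITE_COLUMNS = ["chrom", "position", "strand"]


def sites_frame(records) -> pd.DataFrame:
    """Build a canonical site table from (chrom, position, strand[, ...]) tuples
    or objects with those attributes."""
    rows = []
    for r in records:
        if isinstance(r, tuple):
            rows.append(r[:3])
        else:
            rows.append((r.chrom, r.position, r.strand))
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


@dataclass
class FeatureSet:
    """Named genomic intervals of one class, 0-based half-open, sorted."""

    label: str
    intervals: list[tuple[str, int, int]]
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        ivs = sorted((str(c), int(s), int(e)) for c, s, e in self.intervals)
        for c, s, e in ivs:
            if not s < e:
                raise MalformedAnnotationError(
                    f"empty or inverted interval {c}:{s}-{e} in {self.label!r}"
                )
            if s < 0:
                raise MalformedAnnotationError(f"negative start in {self.label!r}")
        self.intervals = ivs
        self._index = {}

    def __len__(self) -> int:
        return len(self.intervals)

    def chroms(self) -> set[str]:
        return {c for c, _, _ in self.intervals}

    def per_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Merged (starts, ends) arrays per chromosome; overlapping or
        book-ended intervals are merged, which preserves nearest-distance
        and membership semantics."""
        if not self._index:
            by: dict[str, list[tuple[int, int]]] = {}
            for c, s, e in self.intervals:
                by.setdefault(c, []).append((s, e))
            for c, ivs in by.items():
                merged: list[list[int]] = []
                for s, e in ivs:  # already sorted
                    if merged and s <= merged[-1][1]:
                        merged[-1][1] = max(merged[-1][1], e)
                    else:
                        merged.append([s, e])
                arr = np.array(merged, dtype=np.int64)
                self._index[c] = (arr[:, 0], arr[:, 1])
        return self._index

    def total_bases(self) -> int:
        return sum(
            int((ends - starts).sum()) for starts, ends in self.per_chrom().values()
        )

    def coverage(self, chrom_lengths: dict[str, int]) -> float:
        total = sum(chrom_lengths.values())
        return self.total_bases() / total if total else 0.0

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str) -> "FeatureSet":
        return cls(label, list(zip(df["chrom"], df["start"], df["end"])))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intervals, columns=["chrom", "start", "end"])
        df["label"] = self.label
        return df


def _nearest_distance(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Unsigned gap between 1-base sites at ``pos`` and the nearest of the
    merged intervals [starts, ends)."""
    idx = np.searchsorted(starts, pos, side="right") - 1
    n = len(starts)
    dist = np.full(pos.shape, np.iinfo(np.int64).max, dtype=np.int64)
    has_left = idx >= 0
    inside = has_left & (pos < ends[np.clip(idx, 0, n - 1)])
    # gap to the interval on the left (ends[idx] <= pos)
    left_gap = np.where(has_left, pos - ends[np.clip(idx, 0, n - 1)], dist)
    # gap to the interval on the right (starts[idx+1] >= pos + 1)
    has_right = idx + 1 < n
    right_gap = np.where(
        has_right, starts[np.clip(idx + 1, 0, n - 1)] - (pos + 1), dist
    )
    out = np.minimum(left_gap, right_gap)
    out[inside] = 0
    return out


def _check_namespace(sites: pd.DataFrame, features: FeatureSet) -> None:
    if len(sites) and len(features):
        site_chroms = set(sites["chrom"].unique())
        if not site_chroms & features.chroms():
            offending = sorted(site_chroms)[0]
            raise ChromosomeMismatchError(
                f"no chromosome shared between sites and {features.label!r} "
                f"annotation (e.g. site chromosome {offending!r})"
            )


def distance_to_nearest(sites: pd.DataFrame, features: FeatureSet) -> pd.DataFrame:
    """Distance from each site to the nearest feature of one class.

    Returns the site table with ``label`` and ``distance`` columns appended;
    ``distance`` is NaN for sites on chromosomes carrying no feature of the
    class (these are the "absent" records, excluded and counted downstream).
    """
    _check_namespace(sites, features)
    out = sites.copy().reset_index(drop=True)
    out["label"] = features.label
    dist = np.full(len(out), np.nan)
    index = features.per_chrom()
    for chrom, sub in out.groupby("chrom"):
        if chrom not in index:
            continue
        starts, ends = index[chrom]
        dist[sub.index.to_numpy()] = _nearest_distance(
            sub["position"].to_numpy(np.int64), starts, ends
        )
    out["distance"] = dist
    return out


def _family_disjoint(family: list[FeatureSet]) -> None:
    ivs: list[tuple[str, int, int, str]] = []
    for fs in family:
        ivs.extend((c, s, e, fs.label) for c, s, e in fs.intervals)
    ivs.sort()
    for (c1, s1, e1, l1), (c2, s2, e2, l2) in zip(ivs, ivs[1:]):
        if c1 == c2 and s2 < e1:
            raise MalformedAnnotationError(
                f"overlapping intervals within one class family: "
                f"{l1} {c1}:{s1}-{e1} vs {l2} {c2}:{s2}-{e2}"
            )


def assign_membership(sites: pd.DataFrame, family: list[FeatureSet]) -> pd.Series:
    """Label of the containing interval per site, or None.

    ``family`` is one class family (e.g. the five subcompartment sets) whose
    intervals must be mutually disjoint; overlap is a hard error.
    """
    _family_disjoint(family)
    labels = pd.Series([None] * len(sites), index=sites.reset_index(drop=True).index,
                       dtype=object)
    s = sites.reset_index(drop=True)
    for fs in family:
        index = fs.per_chrom()
        for chrom, sub in s.groupby("chrom"):
            if chrom not in index:
                continue
            starts, ends = index[chrom]
            pos = sub["position"].to_numpy(np.int64)
            idx = np.searchsorted(starts, pos, side="right") - 1
            inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(starts) - 1)])
            labels.loc[sub.index[inside]] = fs.label
    return labels


def annotate_memberships(
    sites: pd.DataFrame,
    subcompartments: list[FeatureSet] | None = None,
    lads: FeatureSet | None = None,
) -> pd.DataFrame:
    """Site table with ``subcompartment`` (label or None) and ``in_lad`` columns.

    The LAD flag is assigned independently of the subcompartment label."""
    out = sites.copy().reset_index(drop=True)
    if subcompartments is not None:
        out["subcompartment"] = assign_membership(out, subcompartments)
    if lads is not None:
        out["in_lad"] = assign_membership(out, [lads]).notna()
    return out


def shuffle_sites(sites: pd.DataFrame, chrom_lengths: dict[str, int], seed: int) -> pd.DataFrame:
    """Relocate every site to a uniformly random genomic position.

    The chromosome is chosen proportionally to its length and the strand of
    each input site is preserved, mirroring a ``bedtools shuffle`` random
    control.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    names = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in names], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])
    flat = rng.integers(0, total, size=len(sites))
    which = np.searchsorted(offsets, flat, side="right") - 1
    out = sites.copy().reset_index(drop=True)
    out["chrom"] = [names[i] for i in which]
    out["position"] = flat - offsets[which]
    return out
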