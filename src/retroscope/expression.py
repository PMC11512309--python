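"""Proviral expression-stability quantification.

Covers GFP+ gating of flow-cytometry event tables against a mock
(untransduced) control, time-course fold changes of the GFP+ fraction,
clonal variegation summaries, Poisson inversion of ddPCR droplet counts
into absolute copy numbers, per-cell proviral copy number against the
two-copy RPP30 reference gene, and the active-genome ratio (% GFP+ cells
per proviral copy per 100 genome equivalents; 1 means every provirus is
expected to be active).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    InvalidParameterError,
    MissingControlError,
    MissingReferenceError,
    SaturationError,
    UndefinedFoldError,
    UndefinedRatioError,
)


@dataclass(frozen=True)
class FlowSample:
    """Viability-gated flow events of one sample.

    ``events`` has columns ``gfp_intensity`` and ``hoechst_positive``;
    Hoechst-positive (dead) events are removed before any gating."""

    sample_id: str
    dpi: int
    events: pd.DataFrame

    def viable(self) -> pd.Series:
        ev = self.events
        if "hoechst_positive" in ev.columns:
            ev = ev[~ev["hoechst_positive"].astype(bool)]
        return ev["gfp_intensity"]


@dataclass(frozen=True)
class ExpressionRecord:
    sample_id: str
    gfp_fraction: float
    mfi: float | None
    cn_per_100_cells: float | None = None
    active_ratio: float | None = None
    fold_change_vs_baseline: float | None = None


def gate_gfp(
    sample: FlowSample, mock: FlowSample, quantile: float = 0.999
) -> tuple[float, float | None]:
    """GFP+ fraction and MFI of a sample gated against a mock control.

    The GFP+ threshold is the given quantile (default 99.9%) of the mock's
    viable-event intensities — a reproducible stand-in for a hand-drawn
    cytometry gate.  MFI is the median intensity of the GFP+ subpopulation,
    absent (None) when no event passes the gate.
    """
    if not 0 < quantile < 1:
        raise InvalidParameterError("quantile must lie in (0, 1)")
    mock_int = mock.viable().to_numpy(dtype=float)
    if mock_int.size == 0:
        raise MissingControlError("mock sample has no viable events")
    intensities = sample.viable().to_numpy(dtype=float)
    if intensities.size == 0:
        raise MissingControlError(f"sample {sample.sample_id!r} has no viable events")
    # "higher" interpolation keeps the mock's own above-gate fraction at or
    # below 1 - quantile, the property a negative-control gate must have
    threshold = float(np.quantile(mock_int, quantile, method="higher"))
    positive = intensities > threshold
    fraction = float(positive.mean())
    mfi = float(np.median(intensities[positive])) if positive.any() else None
    return fraction, mfi


def fold_change_timecourse(
    fractions_by_dpi: dict[int, float], baseline_dpi: int = 3
) -> dict[int, float]:
    """GFP+ fraction at each timepoint relative to the baseline timepoint.

    The baseline maps to exactly 1.0 by construction."""
    if baseline_dpi not in fractions_by_dpi:
        raise UndefinedFoldError(f"baseline timepoint {baseline_dpi} dpi missing")
    base = fractions_by_dpi[baseline_dpi]
    if base <= 0:
        raise UndefinedFoldError("baseline GFP+ fraction is zero")
    out = {dpi: f / base for dpi, f in fractions_by_dpi.items()}
    out[baseline_dpi] = 1.0
    return out


def classify_clones(
    gfp_fractions, thresholds: tuple[float, float] = (0.9, 0.5)
) -> pd.DataFrame:
    """Partition single-cell clones by their GFP+ fraction.

    Classes: stable (>= upper threshold), variegated (in [lower, upper)) and
    mostly-silent (< lower).  Counts always sum to the clone count.
    """
    hi, lo = thresholds
    if not 0 <= lo < hi <= 1:
        raise InvalidParameterError("thresholds must satisfy 0 <= lower < upper <= 1")
    f = np.asarray(list(gfp_fractions), dtype=float)
    counts = {
        f">={hi:g}": int((f >= hi).sum()),
        f"[{lo:g},{hi:g})": int(((f >= lo) & (f < hi)).sum()),
        f"<{lo:g}": int((f < lo).sum()),
    }
    total = len(f)
    return pd.DataFrame(
        {
            "clone_class": list(counts),
            "count": list(counts.values()),
            "percentage": [100 * c / total if total else 0.0 for c in counts.values()],
        }
    )


def ddpcr_copies(
    positive: int,
    total: int,
    droplet_volume: float = 0.00085,
    well_volume: float = 20.0,
) -> float:
    """Absolute copies per well from droplet counts by Poisson inversion.

    lambda = -ln(1 - positive/total) copies per droplet; concentration =
    lambda / droplet_volume; copies_per_well = concentration * well_volume.
    Saturated wells (all droplets positive) are rejected — the inversion is
    undefined there.
    """
    if total <= 0 or positive < 0 or positive > total:
        raise InvalidParameterError("need 0 <= positive <= total with total > 0")
    if positive == total:
        raise SaturationError("all droplets positive; concentration unquantifiable")
    if droplet_volume <= 0 or well_volume <= 0:
        raise InvalidParameterError("volumes must be positive")
    lam = -math.log1p(-positive / total)
    return lam / droplet_volume * well_volume


def per_cell_cn(provirus_copies: float, rpp30_copies: float) -> float:
    """Proviral copies per 100 genome equivalents.

    RPP30 is present at two copies per diploid genome, so genome
    equivalents = RPP30 / 2 (100 genome equivalents = 200 RPP30 copies).
    """
    if rpp30_copies <= 0:
        raise MissingReferenceError("RPP30 copy number must be positive")
    if provirus_copies < 0:
        raise InvalidParameterError("provirus copies must be >= 0")
    return 100.0 * provirus_copies / (rpp30_copies / 2.0)


def active_ratio(gfp_fraction: float, cn_per_100_cells: float) -> float:
    """Active-genome ratio: % GFP+ cells per proviral copy per 100 cells.

    A ratio of 1 marks the point where every detected provirus is expected
    to drive expression; values below 1 indicate a silent proviral
    population (multi-copy cells bias the ratio slightly below 1 even when
    all proviruses are active)."""
    if cn_per_100_cells <= 0:
        raise UndefinedRatioError("copy number must be positive")
    if not 0 <= gfp_fraction <= 1:
        raise InvalidParameterError("gfp_fraction must lie in [0, 1]")
    return 100.0 * gfp_fraction / cn_per_100_cells


def mean_copies_per_well(wells: pd.DataFrame, target: str) -> float:
    """Average CopiesPer20uLWell over technical replicate wells of a target.

    ``wells`` columns: target, positive_droplets, total_droplets and
    optionally droplet_volume / well_volume."""
    sub = wells[wells["target"] == target]
    if sub.empty:
        raise InvalidParameterError(f"no wells for target {target!r}")
    copies = [
        ddpcr_copies(
            int(row["positive_droplets"]),
            int(row["total_droplets"]),
            float(row.get("droplet_volume", 0.00085)),
            float(row.get("well_volume", 20.0)),
        )
        for _, row in sub.iterrows()
    ]
    return float(np.mean(copies))
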