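"""Statistical comparison of integration-site sets.

Centre piece is the Impact effect size, a robust two-part comparison of two
distance distributions: a central-tendency difference (difference of
medians scaled by pooled robust spread) and a distribution-shape difference
(half the L1 distance between the kernel density estimates of the two
samples after each is centred at its own median and scaled by its own
spread).  The reported Impact is whichever component dominates in
magnitude, signed by the direction of the central-tendency shift.  |Impact|
above 0.5 is conventionally read as a medium-to-high effect and below 0.3
as low.

Also here: median distances, domain-targeting frequency tables with log2
fold changes against a reference group, and exact binomial enrichment tests
calibrated against shuffled random-site controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, gaussian_kde
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, InvalidParameterError

IMPACT_LOW = 0.3
IMPACT_MEDIUM_HIGH = 0.5

NONE_CLASS = "none"


@dataclass(frozen=True)
class ImpactResult:
    impact: float
    ct_diff: float  # central-tendency difference, signed
    morph_diff: float  # distribution-shape difference, in [0, 1]


def _madn(x: np.ndarray) -> float:
    """Normal-consistent median absolute deviation (1.4826 x MAD)."""
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _standardize(x: np.ndarray) -> np.ndarray:
    scale = _madn(x)
    if scale == 0:
        scale = float(np.std(x, ddof=1))
    if scale == 0:
        return np.zeros_like(x)
    return (x - np.median(x)) / scale


def _shape_difference(a: np.ndarray, b: np.ndarray) -> float:
    za, zb = _standardize(a), _standardize(b)
    ca, cb = np.ptp(za) == 0, np.ptp(zb) == 0
    if ca and cb:
        return 0.0  # both degenerate: identical point-mass shapes
    if ca or cb:
        return 1.0  # point mass vs continuous spread
    ka = gaussian_kde(za, bw_method="silverman")
    kb = gaussian_kde(zb, bw_method="silverman")
    h = max(math.sqrt(float(ka.covariance[0, 0])), math.sqrt(float(kb.covariance[0, 0])))
    lo = min(za.min(), zb.min()) - 3 * h
    hi = max(za.max(), zb.max()) + 3 * h
    grid = np.linspace(lo, hi, 512)
    return 0.5 * float(np.trapezoid(np.abs(ka(grid) - kb(grid)), grid))


def impact_effect_size(a, b) -> ImpactResult:
    """Impact effect size of sample ``b`` relative to sample ``a``.

    ct_diff = (median(b) - median(a)) / s_pool with s_pool the root mean
    square of the two normal-consistent MADs (pooled SD when both MADs
    vanish).  morph_diff compares the standardized density shapes.  Impact
    is ct_diff when |ct_diff| >= morph_diff, otherwise morph_diff carrying
    the sign of the central shift (falling back to the mean difference, then
    to zero, when medians tie).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("impact_effect_size needs >= 2 finite values per sample")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    sa, sb = _madn(a), _madn(b)
    if sa == 0 and sb == 0:
        s_pool = math.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2)
    else:
        s_pool = math.sqrt((sa * sa + sb * sb) / 2)
    if s_pool == 0:
        ct = 0.0 if med_a == med_b else math.copysign(math.inf, med_b - med_a)
    else:
        ct = (med_b - med_a) / s_pool
    morph = _shape_difference(a, b)
    if abs(ct) >= morph:
        impact = ct
    else:
        sign = np.sign(ct)
        if sign == 0:
            sign = np.sign(np.mean(b) - np.mean(a))
        impact = float(sign) * morph  # sign 0 -> impact 0
    return ImpactResult(float(impact), float(ct), float(morph))


def impact_band(impact: float) -> str:
    """Effect-size band: 'low' (<0.3), 'medium-to-high' (>=0.5), else
    'intermediate'."""
    mag = abs(impact)
    if mag < IMPACT_LOW:
        return "low"
    if mag >= IMPACT_MEDIUM_HIGH:
        return "medium-to-high"
    return "intermediate"


def median_distance(values) -> float:
    """Median of a distance distribution; absent (NaN) records are excluded."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise InsufficientDataError("all distance records absent")
    return float(np.median(v))


def targeting_frequencies(
    memberships: pd.DataFrame,
    reference: str,
    group_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group domain-targeting table with log2 fold changes vs a reference.

    ``memberships`` has one row per site with columns ``group`` and
    ``domain_class`` (None/NaN mapped to the absorbing 'none' class).
    Frequencies are count / total sites of the group, so each group's
    frequencies sum to 1 across classes including 'none'.  Fold changes
    against a zero reference frequency are reported as NaN (undefined), not
    infinite.
    """
    df = memberships.copy()
    observed_groups = set(df["group"].unique())
    allowed = set(group_labels) if group_labels is not None else observed_groups | {reference}
    unknown = observed_groups - allowed
    if unknown or reference not in allowed:
        raise InvalidParameterError(f"unknown group label(s): {sorted(unknown) or reference}")
    if reference not in observed_groups:
        raise InvalidParameterError(f"reference group {reference!r} has no sites")
    df["domain_class"] = df["domain_class"].where(df["domain_class"].notna(), NONE_CLASS)
    counts = df.groupby(["group", "domain_class"], sort=True).size()
    totals = df.groupby("group").size()
    rows = []
    classes = sorted(df["domain_class"].unique())
    for group in sorted(observed_groups):
        for cls in classes:
            k = int(counts.get((group, cls), 0))
            rows.append((group, cls, k, k / totals[group]))
    table = pd.DataFrame(rows, columns=["group", "domain_class", "count", "frequency"])
    ref = table[table["group"] == reference].set_index("domain_class")["frequency"]
    fold = []
    for _, row in table.iterrows():
        rf = ref.get(row["domain_class"], 0.0)
        if rf == 0 or row["frequency"] == 0:
            fold.append(np.nan)
        else:
            fold.append(math.log2(row["frequency"] / rf))
    table["log2_fold_change"] = fold
    return table


@dataclass(frozen=True)
class EnrichmentResult:
    expected_frequency: float  # pooled shuffle frequency p0
    observed_frequency: float
    direction: str  # enriched | depleted | none
    p_value: float  # two-sided exact binomial vs p0
    p_empirical: float | None  # permutation p when >= 20 shuffle replicates


def enrichment_vs_random(
    observed: tuple[int, int], shuffled_sets: list[tuple[int, int]]
) -> EnrichmentResult:
    """Exact binomial test of an observed in-class count against the pooled
    frequency of shuffled random-site controls.

    With at least 20 shuffle replicates, an empirical two-sided permutation
    p-value (rank of the observed deviation among shuffle deviations) is
    reported alongside the binomial one.
    """
    k, n = observed
    if n == 0:
        raise InsufficientDataError("observed total is zero")
    if not shuffled_sets or any(t == 0 for _, t in shuffled_sets):
        raise InsufficientDataError("need >= 1 non-empty shuffled set")
    p0 = sum(c for c, _ in shuffled_sets) / sum(t for _, t in shuffled_sets)
    f_obs = k / n
    if p0 in (0.0, 1.0):
        p_value = 1.0 if f_obs == p0 else 0.0
    else:
        p_value = binomtest(k, n, p0, alternative="two-sided").pvalue
    if f_obs > p0:
        direction = "enriched"
    elif f_obs < p0:
        direction = "depleted"
    else:
        direction = "none"
    p_emp = None
    if len(shuffled_sets) >= 20:
        devs = [abs(c / t - p0) for c, t in shuffled_sets]
        p_emp = (1 + sum(d >= abs(f_obs - p0) for d in devs)) / (len(shuffled_sets) + 1)
    return EnrichmentResult(p0, f_obs, direction, float(p_value), p_emp)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values across one class family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
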