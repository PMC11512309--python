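"""Self-contained desk-scale validation scenarios.

Each function builds a synthetic study condition with the package's own
generators, runs the relevant pipeline stages end to end, and returns the
measured quantities as plain numbers.  The scenarios double as the
package's reproducibility suite: the same functions back the test suite and
``scripts/acceptance.py``.

Problem sizes (2 Mb round-trip genome, 1,000-read trimming cohort, 100
shuffle replicates of 3,000 sites, 10^4-draw Impact samples, 100 ddPCR
wells, 1,000 calibration trials) are chosen so the whole suite runs in well
under a coffee break while leaving binomial sampling error far below the
assertion margins.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binomtest

from .enrichment import enrichment_vs_random, impact_effect_size
from .expression import active_ratio, ddpcr_copies, per_cell_cn
from .feature_annotation import assign_membership, distance_to_nearest, shuffle_sites
from .is_calling import align_and_call
from .read_processing import TrimSpec, demultiplex, trim_pipeline
from .synthetic import (
    DropletSimConfig,
    FeatureProximityBias,
    PlantedISSet,
    PlantedSite,
    ReadSimConfig,
    UniformBias,
    build_toy_genome,
    generate_annotations,
    plant_integration_sites,
    simulate_droplets,
    simulate_junction_reads,
)

_BARCODES = {"B1": "ACGTACGT"}


def _run_pipeline(genome, planted: PlantedISSet, read_seed: int):
    reads, _ = simulate_junction_reads(genome, planted, ReadSimConfig(seed=read_seed))
    groups, _ = demultiplex(reads, _BARCODES)
    kept, _ = trim_pipeline(groups["B1"], TrimSpec())
    return align_and_call(kept, genome)


def _as_tuples(sites) -> set[tuple]:
    return {
        (s.chrom, s.position, s.strand, getattr(s, "read_support", None) or s.read_count)
        for s in sites
    }


def roundtrip_scenario(seed: int, n_sites: int = 50) -> dict:
    """Simulate -> trim -> align -> call on a 2 Mb genome; compare with truth.

    Planted supports are uniform in [5, 30].  A second pass lowers 10% of
    the sites to 4 supporting reads, one below the calling threshold, and
    checks that exactly those sites disappear.
    """
    genome = build_toy_genome(2, [1_000_000, 1_000_000], seed)
    planted = plant_integration_sites(
        genome, None, n_sites, UniformBias(), seed + 1,
        support_range=(5, 30), min_separation=200,
    )
    called = _run_pipeline(genome, planted, seed + 2)
    exact = _as_tuples(called) == _as_tuples(planted.sites)

    rng = np.random.default_rng(seed + 3)
    n_low = max(1, round(0.1 * n_sites))
    low_idx = set(rng.choice(n_sites, size=n_low, replace=False).tolist())
    lowered = tuple(
        PlantedSite(s.chrom, s.position, s.strand, 4) if i in low_idx else s
        for i, s in enumerate(planted.sites)
    )
    low_planted = PlantedISSet(lowered, planted.bias_model, seed + 1)
    called_low = _run_pipeline(genome, low_planted, seed + 4)
    surviving = {(s.chrom, s.position, s.strand) for i, s in enumerate(lowered) if i not in low_idx}
    dropped = {(s.chrom, s.position, s.strand) for i, s in enumerate(lowered) if i in low_idx}
    got = {(s.chrom, s.position, s.strand) for s in called_low}
    return {
        "n_sites": n_sites,
        "recovered_exact": exact,
        "recovery_pct": 100.0 * len(_as_tuples(called) & _as_tuples(planted.sites)) / n_sites,
        "n_low_support": n_low,
        "low_support_excluded_pct": 100.0 * len(dropped - got) / n_low,
        "high_support_retained": got == surviving,
    }


def trimming_scenario(seed: int, n_reads: int = 1000) -> dict:
    """1,000 junction reads (5% internal-decoy, 5% short-flank) through the
    cascade; per-read outcomes compared against simulator truth."""
    genome = build_toy_genome(2, [1_000_000, 1_000_000], seed)
    n_decoy = n_short = round(0.05 * n_reads)
    n_normal = n_reads - n_decoy - n_short

    normal = plant_integration_sites(
        genome, None, n_normal // 20, UniformBias(), seed + 1,
        support_range=(20, 20), min_separation=100,
    )
    reads_n, truth_n = simulate_junction_reads(genome, normal, ReadSimConfig(seed=seed + 2))

    decoy_sites = plant_integration_sites(
        genome, None, n_decoy // 10, UniformBias(), seed + 3,
        support_range=(10, 10), min_separation=100,
    )
    reads_d, _ = simulate_junction_reads(
        genome, decoy_sites, ReadSimConfig(seed=seed + 4, internal_read_fraction=1.0)
    )

    # short-flank reads: plus-strand sites close enough to a chromosome end
    # that the flank truncates below the 15-base minimum
    rng = np.random.default_rng(seed + 5)
    short_sites = tuple(
        PlantedSite("chr1" if i % 2 else "chr2",
                    genome.lengths["chr1"] - int(rng.integers(5, 15)), "+", 1)
        for i in range(n_short)
    )
    reads_s, _ = simulate_junction_reads(
        genome, PlantedISSet(short_sites, UniformBias(), seed + 5),
        ReadSimConfig(seed=seed + 6),
    )

    expected: dict[str, tuple[str, str | None]] = {}
    flank_truth = dict(zip(truth_n["read_id"], truth_n["flank"]))
    all_reads = []
    for r in reads_n:
        expected[r.id] = ("kept", flank_truth[r.id])
        all_reads.append(r)
    for r in reads_d:
        expected[f"d_{r.id}"] = ("internal", None)
        all_reads.append(type(r)(f"d_{r.id}", r.sequence, r.quality))
    for r in reads_s:
        expected[f"s_{r.id}"] = ("too_short", None)
        all_reads.append(type(r)(f"s_{r.id}", r.sequence, r.quality))

    groups, unassigned = demultiplex(all_reads, _BARCODES)
    spec = TrimSpec()
    concordant = 0
    kept, rejected = trim_pipeline(groups["B1"], spec)
    outcomes: dict[str, tuple[str, str | None]] = {}
    for t in kept:
        outcomes[t.id.split(":", 1)[1]] = ("kept", t.flank)
    for rj in rejected:
        outcomes[rj.read_id.split(":", 1)[1]] = (rj.reason, None)
    for rid, want in expected.items():
        if outcomes.get(rid) == want:
            concordant += 1
    return {
        "n_reads": len(all_reads),
        "n_unassigned": len(unassigned),
        "concordance_pct": 100.0 * concordant / len(all_reads),
    }


def _lad_genome(seed: int):
    genome = build_toy_genome(2, [500_000, 500_000], seed)
    ann = generate_annotations(genome, {"LAD": (25, 20_000, 0.50)}, seed + 1)
    return genome, ann


def shuffle_calibration(
    seed: int, n_replicates: int = 100, n_sites: int = 3000, alpha: float = 0.01
) -> dict:
    """Shuffled random controls on a 50%-LAD genome: the exact binomial test
    of LAD frequency against 0.5 should rarely reject."""
    genome, ann = _lad_genome(seed)
    base = plant_integration_sites(genome, None, n_sites, UniformBias(), seed + 2).to_frame()
    non_reject = 0
    freqs = []
    for i in range(n_replicates):
        sh = shuffle_sites(base, genome.lengths, seed + 10 + i)
        k = int(assign_membership(sh, [ann.lads]).notna().sum())
        freqs.append(k / n_sites)
        if binomtest(k, n_sites, 0.5).pvalue > alpha:
            non_reject += 1
    return {
        "n_replicates": n_replicates,
        "n_sites": n_sites,
        "mean_lad_frequency_pct": 100.0 * float(np.mean(freqs)),
        "non_reject_pct": 100.0 * non_reject / n_replicates,
    }


def impact_suite(seed: int, n_draws: int = 10_000, n_sites: int = 500) -> dict:
    """Impact effect-size reference behaviours: identity, a +2-pooled-SD
    location shift, and planted promoter-proximity bias vs uniform."""
    rng = np.random.default_rng(seed)
    x = rng.exponential(1000, size=1000)
    identity = impact_effect_size(x, x)

    a = rng.normal(0.0, 1.0, n_draws)
    shift = impact_effect_size(a, a + 2.0)

    genome = build_toy_genome(2, [500_000, 500_000], seed + 1)
    ann = generate_annotations(genome, {"Tss": (100, 200, 0.02)}, seed + 2)
    tss = ann.segments["Tss"]
    uniform = plant_integration_sites(genome, None, n_sites, UniformBias(), seed + 3).to_frame()
    biased = plant_integration_sites(
        genome, ann, n_sites, FeatureProximityBias("Tss", 1.0, 100.0), seed + 4
    ).to_frame()
    null = plant_integration_sites(
        genome, ann, n_sites, FeatureProximityBias("Tss", 0.0, 100.0), seed + 5
    ).to_frame()
    d_uniform = distance_to_nearest(uniform, tss)["distance"]
    strong = impact_effect_size(distance_to_nearest(biased, tss)["distance"], d_uniform)
    weak = impact_effect_size(distance_to_nearest(null, tss)["distance"], d_uniform)
    return {
        "identity_impact": identity.impact,
        "shift_ct_diff": shift.ct_diff,
        "shift_morph_diff": shift.morph_diff,
        "shift_impact": shift.impact,
        "strong_bias_impact": strong.impact,
        "null_bias_impact": weak.impact,
        "n_draws": n_draws,
        "n_sites": n_sites,
    }


def ddpcr_recovery(seed: int, n_wells: int = 100, lam: float = 0.1) -> dict:
    """Poisson inversion vs droplet simulation at 0.1 copies/droplet, plus
    the fixed copy-number and active-ratio conventions."""
    droplet_volume = 0.00085
    conc = lam / droplet_volume
    recovered = []
    for i in range(n_wells):
        pos, total = simulate_droplets(
            DropletSimConfig(n_droplets=20_000, true_concentration=conc, seed=seed + i)
        )
        recovered.append(ddpcr_copies(pos, total) / 20.0)
    mean_rel_err = abs(float(np.mean(recovered)) - conc) / conc
    return {
        "n_wells": n_wells,
        "mean_concentration_error_pct": 100.0 * mean_rel_err,
        "cn_per_100_cells": per_cell_cn(100.0, 2000.0),
        "active_genome_ratio": active_ratio(0.04, 8.0),
    }


def enrichment_calibration(seed: int, n_trials: int = 1000, alpha: float = 0.05) -> dict:
    """Type-I error of the binomial enrichment test under the null.

    The shuffle reference pools 20 shuffled 3,000-site sets on the 50%-LAD
    genome; each trial shuffles a fresh 1,000-site set (a draw from the same
    null) and tests its LAD count against the pooled reference frequency.
    """
    genome, ann = _lad_genome(seed)
    base = plant_integration_sites(genome, None, 3000, UniformBias(), seed + 2).to_frame()
    shuffled_sets = []
    for i in range(20):
        sh = shuffle_sites(base, genome.lengths, seed + 100 + i)
        k = int(assign_membership(sh, [ann.lads]).notna().sum())
        shuffled_sets.append((k, len(sh)))

    trial_base = base.iloc[:1000]
    rejections = 0
    for t in range(n_trials):
        sh = shuffle_sites(trial_base, genome.lengths, seed + 1000 + t)
        k = int(assign_membership(sh, [ann.lads]).notna().sum())
        res = enrichment_vs_random((k, len(sh)), shuffled_sets)
        if res.p_value <= alpha:
            rejections += 1
    return {
        "n_trials": n_trials,
        "alpha": alpha,
        "rejection_rate_pct": 100.0 * rejections / n_trials,
    }
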