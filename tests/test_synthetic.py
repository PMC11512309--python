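"""Generators: determinism, calibration against closed-form expectations,
and the exact read layout the trimming cascade assumes."""

import numpy as np
import pytest
from scipy.stats import binom

from retroscope import (
    DropletSimConfig,
    FeatureProximityBias,
    FlowSimConfig,
    ReadSimConfig,
    UniformBias,
    build_toy_genome,
    distance_to_nearest,
    generate_annotations,
    plant_integration_sites,
    revcomp,
    simulate_droplets,
    simulate_flow_events,
    simulate_junction_reads,
)
from retroscope.errors import InvalidParameterError, MissingFeatureError
from retroscope.feature_annotation import assign_membership


def binomial_ci(n, p, alpha=0.01):
    lo, hi = binom.ppf([alpha / 2, 1 - alpha / 2], n, p)
    return lo / n, hi / n


class TestToyGenome:
    def test_shape_and_determinism(self):
        g = build_toy_genome(2, [5000, 5000], seed=7)
        g2 = build_toy_genome(2, [5000, 5000], seed=7)
        assert g.lengths == {"chr1": 5000, "chr2": 5000}
        assert g.chromosomes == g2.chromosomes

    def test_gc_fraction_uniform(self):
        g = build_toy_genome(1, [10000], seed=1)
        seq = g.sequence("chr1")
        gc = (seq.count("G") + seq.count("C")) / 10000
        lo, hi = binomial_ci(10000, 0.5)
        assert lo <= gc <= hi

    def test_invalid_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_toy_genome(1, [0], seed=1)


class TestAnnotations:
    def test_realized_coverage_matches_target(self, genome, annotations):
        for label, frac in annotations.coverage_fractions.items():
            fs = annotations.feature_set(label)
            assert fs.coverage(genome.lengths) == pytest.approx(frac)
        assert abs(annotations.coverage_fractions["LAD"] - 0.5) <= 0.01
        assert annotations.coverage_fractions["Tss"] == pytest.approx(0.02)

    def test_subcompartments_disjoint(self, annotations):
        # assign_membership hard-errors on family overlap; success is the check
        import pandas as pd

        sites = pd.DataFrame({"chrom": ["chr1"], "position": [10], "strand": ["+"]})
        assign_membership(sites, list(annotations.subcompartments.values()))

    def test_zero_intervals_gives_empty_set(self, genome):
        ann = generate_annotations(genome, {"Tss": (0, 200, None)}, seed=1)
        assert len(ann.segments["Tss"]) == 0

    def test_infeasible_coverage_rejected(self, genome):
        with pytest.raises(InvalidParameterError):
            generate_annotations(genome, {"LAD": (25, 20_000, 0.10)}, seed=1)
        with pytest.raises(InvalidParameterError):
            generate_annotations(genome, {"LAD": (2, 900_000, None)}, seed=1)


class TestPlanting:
    def test_uniform_lad_fraction_matches_coverage(self, genome, annotations, uniform_sites):
        in_lad = assign_membership(uniform_sites, [annotations.lads]).notna()
        lo, hi = binomial_ci(len(uniform_sites), 0.5)
        assert lo <= in_lad.mean() <= hi

    def test_proximity_bias_shrinks_tss_distance(self, genome, annotations, uniform_sites):
        biased = plant_integration_sites(
            genome, annotations, 500, FeatureProximityBias("Tss", 1.0, 100.0), seed=9
        ).to_frame()
        tss = annotations.segments["Tss"]
        med_b = distance_to_nearest(biased, tss)["distance"].median()
        med_u = distance_to_nearest(uniform_sites, tss)["distance"].median()
        assert med_b < med_u

    def test_seed_determinism(self, genome):
        a = plant_integration_sites(genome, None, 100, UniformBias(), seed=5)
        b = plant_integration_sites(genome, None, 100, UniformBias(), seed=5)
        assert a.sites == b.sites

    def test_missing_bias_label_errors(self, genome, annotations):
        with pytest.raises(MissingFeatureError):
            plant_integration_sites(
                genome, annotations, 10, FeatureProximityBias("NoSuch"), seed=1
            )


class TestJunctionReads:
    def test_plus_strand_layout(self, genome):
        from retroscope.synthetic import PlantedISSet, PlantedSite

        site = PlantedSite("chr1", 5000, "+", 1)
        cfg = ReadSimConfig(seed=1)
        reads, truth = simulate_junction_reads(
            genome, PlantedISSet((site,), UniformBias(), 1), cfg
        )
        seq = reads[0].sequence
        after = seq.split(cfg.ltr_terminal, 1)[1]
        assert after == genome.sequence("chr1")[5000:5030] + cfg.adapter

    def test_minus_strand_flank_is_revcomp_upstream(self, genome):
        from retroscope.synthetic import PlantedISSet, PlantedSite

        site = PlantedSite("chr1", 5000, "-", 1)
        _, truth = simulate_junction_reads(
            genome, PlantedISSet((site,), UniformBias(), 1), ReadSimConfig(seed=1)
        )
        expected = revcomp(genome.sequence("chr1")[5000 - 29 : 5001])
        assert truth["flank"].iloc[0] == expected

    def test_decoy_reads_carry_decoy_after_terminal(self, genome):
        from retroscope.synthetic import PlantedISSet, PlantedSite

        site = PlantedSite("chr1", 5000, "+", 7)
        cfg = ReadSimConfig(seed=1, internal_read_fraction=1.0)
        reads, truth = simulate_junction_reads(
            genome, PlantedISSet((site,), UniformBias(), 1), cfg
        )
        assert len(reads) == 7  # read count per site honoured
        for r in reads:
            assert cfg.ltr_terminal + cfg.internal_decoy in r.sequence
        assert truth["is_decoy"].all()

    def test_chromosome_end_truncation_recorded(self, genome):
        from retroscope.synthetic import PlantedISSet, PlantedSite

        end = genome.lengths["chr1"] - 1
        site = PlantedSite("chr1", end - 9, "+", 1)
        _, truth = simulate_junction_reads(
            genome, PlantedISSet((site,), UniformBias(), 1), ReadSimConfig(seed=1)
        )
        assert truth["truncated"].iloc[0]
        assert len(truth["flank"].iloc[0]) == 10


class TestDroplets:
    def test_zero_concentration(self):
        pos, total = simulate_droplets(DropletSimConfig(true_concentration=0.0, seed=1))
        assert pos == 0 and total == 15000

    def test_poisson_occupancy_calibration(self):
        lam = 0.1
        cfg = DropletSimConfig(
            n_droplets=20000, true_concentration=lam / 0.00085, seed=2
        )
        pos, total = simulate_droplets(cfg)
        p = 1 - np.exp(-lam)
        lo, hi = binomial_ci(total, p)
        assert lo <= pos / total <= hi

    def test_seed_determinism(self):
        cfg = DropletSimConfig(true_concentration=50.0, seed=3)
        assert simulate_droplets(cfg) == simulate_droplets(cfg)


class TestFlowEvents:
    def test_active_fraction_zero_is_all_background(self):
        ev = simulate_flow_events(FlowSimConfig(active_fraction=0.0, seed=1))
        assert not ev["active"].any()

    def test_mixture_weight_recovered(self):
        ev = simulate_flow_events(FlowSimConfig(n_events=10000, active_fraction=0.8, seed=2))
        lo, hi = binomial_ci(10000, 0.8)
        # components are separated by >8 sd: a fixed mid cut recovers the weight
        frac = (ev["gfp_intensity"] > 10 ** 2.75).mean()
        assert lo <= frac <= hi

    def test_all_hoechst_positive_leaves_nothing(self):
        ev = simulate_flow_events(FlowSimConfig(hoechst_positive_fraction=1.0, seed=3))
        assert (~ev["hoechst_positive"]).sum() == 0
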