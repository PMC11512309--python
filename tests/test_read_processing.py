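"""Trimming cascade: cutadapt-equivalent stage semantics, sharp thresholds,
round-trip recovery on simulated reads, and order/error-rate properties."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retroscope import (
    RawRead,
    Rejection,
    ReadSimConfig,
    TrimSpec,
    TrimmedRead,
    UniformBias,
    anchored_prefix_trim,
    build_toy_genome,
    demultiplex,
    plant_integration_sites,
    process_read,
    simulate_junction_reads,
    three_prime_adapter_trim,
    trim_pipeline,
)
from retroscope.read_processing import (
    DEFAULT_ADAPTER,
    DEFAULT_INTERNAL_DECOY,
    DEFAULT_LTR_PRIMER,
    DEFAULT_LTR_TERMINAL,
)

PRIMER = DEFAULT_LTR_PRIMER
TERMINAL = DEFAULT_LTR_TERMINAL
ADAPTER = DEFAULT_ADAPTER
DECOY = DEFAULT_INTERNAL_DECOY
TAIL = "ACGTTGCAGGATCCAATGCA"  # 20 bp neutral payload


def brute_force_anchored(seq, pattern, rate):
    """Independent oracle: anchored substitution alignment at offset 0."""
    L = min(len(seq), len(pattern))
    errs = sum(1 for a, b in zip(seq[:L], pattern[:L]) if a != b)
    return errs <= int(rate * L)


class TestAnchoredPrefixTrim:
    def test_exact_primer_is_removed(self):
        out = anchored_prefix_trim(
            RawRead("r", PRIMER + TAIL), PRIMER, 20, 0.1, "discard_untrimmed"
        )
        assert out.sequence == TAIL

    def test_untrimmed_discarded(self):
        out = anchored_prefix_trim(
            RawRead("r", TAIL * 3), PRIMER, 20, 0.1, "discard_untrimmed"
        )
        assert isinstance(out, Rejection) and out.reason == "untrimmed"

    @pytest.mark.parametrize("n_subs,survives", [(0, True), (1, True), (2, True), (3, False)])
    def test_error_budget_matches_brute_force(self, n_subs, survives):
        # floor(0.1 * 20) = 2 substitutions allowed in the 20-mer
        mutated = list(PRIMER)
        for i in random.Random(n_subs).sample(range(20), n_subs):
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        seq = "".join(mutated) + TAIL
        assert brute_force_anchored(seq, PRIMER, 0.1) is survives
        out = anchored_prefix_trim(RawRead("r", seq), PRIMER, 20, 0.1, "discard_untrimmed")
        assert isinstance(out, RawRead) is survives

    def test_non_anchored_internal_match_discard_trimmed(self):
        out = anchored_prefix_trim(
            RawRead("r", TAIL + DECOY + TAIL), DECOY, 10, 0.1,
            "discard_trimmed", anchored=False,
        )
        assert isinstance(out, Rejection) and out.reason == "trimmed"


class TestAdapterTrim:
    def test_full_internal_occurrence(self):
        out = three_prime_adapter_trim(RawRead("r", TAIL + ADAPTER + "GGGG"), ADAPTER)
        assert out.sequence == TAIL

    def test_nine_base_suffix_below_overlap_unchanged(self):
        seq = TAIL + ADAPTER[:9]
        assert three_prime_adapter_trim(RawRead("r", seq), ADAPTER).sequence == seq

    def test_ten_base_suffix_prefix_trimmed(self):
        # oracle: scan every suffix of the read against adapter prefixes
        seq = TAIL + ADAPTER[:10]
        hits = [
            k
            for k in range(10, len(ADAPTER) + 1)
            if seq.endswith(ADAPTER[:k][: min(k, len(seq))]) and k <= len(seq)
        ]
        assert hits == [10]
        assert three_prime_adapter_trim(RawRead("r", seq), ADAPTER).sequence == TAIL


class TestDemultiplex:
    BARCODES = {"B1": "ACGTACGT", "B2": "TTGGCCAA", "B3": "GATCGATC"}

    def test_assignment_and_name_annotation(self):
        groups, unassigned = demultiplex(
            [RawRead("r1", "ACGTACGT" + TAIL)], self.BARCODES
        )
        assert not unassigned
        (read,) = groups["B1"]
        assert read.id == "B1:r1" and read.sequence == TAIL

    def test_no_match_unassigned(self):
        groups, unassigned = demultiplex([RawRead("r1", "GGGGGGGG" + TAIL)], self.BARCODES)
        assert len(unassigned) == 1 and all(not v for v in groups.values())

    def test_group_sizes_match_planted_counts(self, genome):
        planted = plant_integration_sites(genome, None, 10, UniformBias(), seed=11)
        all_reads, truth = [], {}
        for name, bc in self.BARCODES.items():
            reads, _ = simulate_junction_reads(
                genome, planted, ReadSimConfig(barcode=bc, seed=ord(name[1]))
            )
            reads = [RawRead(f"{name}_{r.id}", r.sequence, r.quality) for r in reads]
            truth[name] = len(reads)
            all_reads.extend(reads)
        groups, unassigned = demultiplex(all_reads, self.BARCODES)
        assert not unassigned
        assert {k: len(v) for k, v in groups.items()} == truth

    def test_order_invariance(self):
        reads = [
            RawRead(f"r{i}", bc + TAIL)
            for i, bc in enumerate(["ACGTACGT", "TTGGCCAA", "GATCGATC"] * 5)
        ]
        fwd, _ = demultiplex(reads, self.BARCODES)
        rev, _ = demultiplex(list(reversed(reads)), self.BARCODES)
        assert {k: sorted(r.id for r in v) for k, v in fwd.items()} == {
            k: sorted(r.id for r in v) for k, v in rev.items()
        }


class TestCascade:
    def read(self, flank, decoy=False):
        insert = DECOY if decoy else ""
        return RawRead("r", PRIMER + TERMINAL + insert + flank + ADAPTER)

    def test_error_free_read_recovers_flank(self):
        flank = "ATCGATCGATCGATCGATCG"
        out = process_read(self.read(flank), TrimSpec())
        assert isinstance(out, TrimmedRead) and out.flank == flank

    @pytest.mark.parametrize("n,reason", [(14, "too_short"), (15, None)])
    def test_minimum_flank_length_is_sharp(self, n, reason):
        out = process_read(self.read("A" * n), TrimSpec())
        if reason:
            assert isinstance(out, Rejection) and out.reason == reason
        else:
            assert isinstance(out, TrimmedRead)

    def test_decoy_rejected_internal(self):
        out = process_read(self.read("ATCGATCGATCGATCGATCG", decoy=True), TrimSpec())
        assert isinstance(out, Rejection) and out.reason == "internal"

    def test_missing_landmarks(self):
        assert process_read(RawRead("r", TAIL * 4), TrimSpec()).reason == "no_primer"
        out = process_read(RawRead("r", PRIMER + TAIL * 3), TrimSpec())
        assert out.reason == "no_terminal"

    def test_roundtrip_recovery_rate_is_one(self, genome):
        planted = plant_integration_sites(
            genome, None, 30, UniformBias(), seed=21, min_separation=100
        )
        reads, truth = simulate_junction_reads(genome, planted, ReadSimConfig(seed=22))
        groups, _ = demultiplex(reads, {"B1": "ACGTACGT"})
        kept, rejected = trim_pipeline(groups["B1"], TrimSpec())
        assert not rejected
        flanks = {t.id.split(":", 1)[1]: t.flank for t in kept}
        for row in truth.itertuples():
            assert flanks[row.read_id] == row.flank

    @given(st.floats(min_value=0.0, max_value=0.45))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_survivors_monotone_in_error_rate(self, rate):
        rng = random.Random(99)
        reads = []
        for i in range(30):
            mutated = list(PRIMER + TERMINAL + "ACGT" * 5 + ADAPTER)
            for j in rng.sample(range(len(mutated)), rng.randint(0, 6)):
                mutated[j] = rng.choice("ACGT")
            reads.append(RawRead(f"r{i}", "".join(mutated)))
        strict, _ = trim_pipeline(reads, TrimSpec(max_error_rate=0.0))
        loose, _ = trim_pipeline(reads, TrimSpec(max_error_rate=rate))
        assert len(loose) >= len(strict)
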