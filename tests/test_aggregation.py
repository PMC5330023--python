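"""Tallies, frequencies, calls, genotype expectations and the per-sample summary."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from basepile.aggregation import (
    CATEGORIES,
    FrequencyTable,
    PositionCounts,
    compute_frequencies,
    derive_calls,
    expected_at_target,
    expected_counts,
    summarize_sample,
    tally_position,
)
from basepile.config_io import RunConfig, TargetPosition, parse_target_spec
from basepile.fixtures import (
    CompositionSpec,
    random_reference,
    simulate_position_reads,
    write_alignment_fixture,
)
from basepile.genome_io import CalledVariant
from basepile.pileup_engine import Observation


def base_obs(base, q, name="r", ins=None, ins_q=None):
    return Observation(kind="base", read_name=name, base=base, base_quality=q,
                       inserted_seq=ins, inserted_quals=ins_q)


def counts_of(**kw):
    excluded = kw.pop("excluded", 0)
    alleles = kw.pop("insertion_alleles", {})
    return PositionCounts(counts=kw, excluded=excluded, insertion_alleles=alleles)


class TestTallyPosition:
    def test_low_quality_base_moves_to_excluded(self):
        obs = [base_obs("C", 30, f"c{i}") for i in range(6)] + [base_obs("C", 10, "c6")]
        obs += [base_obs("T", 30, f"t{i}") for i in range(3)]
        pc = tally_position(obs, bq_threshold=50)  # Phred floor 17
        assert pc.counts == {"C": 6, "T": 3}
        assert pc.excluded == 1
        assert pc.depth == 9

    def test_empty_observations_all_zero(self):
        pc = tally_position([], bq_threshold=50)
        assert pc.depth == 0 and pc.excluded == 0 and pc.counts == {}

    def test_insertions_tallied_independently_of_bases(self):
        obs = [base_obs("C", 35, f"r{i}", ins="G", ins_q=(35,)) for i in range(4)]
        pc = tally_position(obs, bq_threshold=50)
        assert pc.counts["C"] == 4
        assert pc.counts["insertion"] == 4
        assert pc.insertion_alleles == {"G": 4}

    def test_low_mean_quality_insertion_excluded(self):
        obs = [base_obs("C", 35, "r0", ins="GG", ins_q=(10, 12))]
        pc = tally_position(obs, bq_threshold=50)
        assert pc.counts.get("insertion", 0) == 0
        assert pc.excluded == 1
        assert pc.counts["C"] == 1  # flanking base retained on its own quality

    def test_deletions_never_quality_excluded(self):
        obs = [Observation(kind="deletion", read_name="d0")]
        pc = tally_position(obs, bq_threshold=100)
        assert pc.counts == {"deletion": 1} and pc.excluded == 0

    def test_mean_quality_over_retained_only(self):
        obs = [base_obs("A", 40, "a0"), base_obs("A", 20, "a1"), base_obs("A", 5, "a2")]
        pc = tally_position(obs, bq_threshold=50)
        assert pc.mean_quality["A"] == pytest.approx(30.0)

    def test_raising_threshold_is_monotone(self, rng):
        obs = [base_obs(rng.choice("ACGT"), rng.randint(0, 45), f"r{i}")
               for i in range(300)]
        prev = tally_position(obs, 33)
        for t in range(35, 80, 4):
            cur = tally_position(obs, t)
            assert cur.excluded >= prev.excluded
            for b in "ACGT":
                assert cur.counts.get(b, 0) <= prev.counts.get(b, 0)
            prev = cur


class TestComputeFrequencies:
    def test_insertion_frequency_homopolymer_worked_example(self):
        pc = counts_of(G=12355, A=21, C=2, T=1, deletion=370,
                       insertion_alleles={"G": 4051}, insertion=4051, excluded=183)
        ft = compute_frequencies(pc)
        assert ft.denominator == 12749
        assert round(ft.freq["insertion"], 2) == 0.32

    def test_low_frequency_snv_worked_example(self):
        pc = counts_of(C=10048, A=247, T=12, deletion=14)
        ft = compute_frequencies(pc)
        assert ft.denominator == 10321
        assert round(ft.freq["A"], 2) == 0.02

    def test_single_category_gives_unity(self):
        ft = compute_frequencies(counts_of(G=100))
        assert ft.freq["G"] == 1.0

    def test_zero_depth_reports_zeros(self):
        ft = compute_frequencies(counts_of())
        assert ft.denominator == 0
        assert all(v == 0.0 for v in ft.freq.values())

    @settings(derandomize=True, max_examples=100)
    @given(st.dictionaries(st.sampled_from(["A", "C", "G", "T", "N", "deletion"]),
                           st.integers(0, 10**6), min_size=1))
    def test_base_and_deletion_frequencies_normalize(self, counts):
        ft = compute_frequencies(counts_of(**counts))
        if ft.denominator > 0:
            total = sum(ft.freq[c] for c in ("A", "C", "G", "T", "N", "deletion"))
            assert math.isclose(total, 1.0, abs_tol=1e-9)


class TestDeriveCalls:
    def test_sorted_descending_with_threshold(self):
        ft = FrequencyTable({"G": 0.97, "deletion": 0.03, "insertion": 0.30}, 1000)
        assert derive_calls(ft, 0.01) == [("G", 0.97), ("insertion", 0.30), ("deletion", 0.03)]

    def test_all_below_threshold_empty(self):
        ft = FrequencyTable({"A": 0.004, "deletion": 0.002}, 1000)
        assert derive_calls(ft, 0.01) == []

    def test_six_categories_cap(self):
        ft = FrequencyTable({c: 0.2 for c in CATEGORIES}, 100)
        assert len(derive_calls(ft, 0.01)) == 6

    def test_ties_broken_by_fixed_category_order(self):
        ft = FrequencyTable({"T": 0.5, "A": 0.5}, 10)
        assert derive_calls(ft, 0.0) == [("A", 0.5), ("T", 0.5)]

    def test_invariant_under_mapping_iteration_order(self):
        items = [("G", 0.6), ("A", 0.2), ("deletion", 0.1), ("insertion", 0.1)]
        expected = derive_calls(FrequencyTable(dict(items), 100), 0.0)
        for perm in ([3, 1, 0, 2], [2, 0, 3, 1], [1, 3, 2, 0]):
            shuffled = dict(items[i] for i in perm)
            assert derive_calls(FrequencyTable(shuffled, 100), 0.0) == expected


class TestExpectedCounts:
    def test_heterozygous_snv_halves_depth(self):
        call = CalledVariant("c", 10, "C", ("T",), (0, 1))
        assert expected_counts(call, 100).expected == {"C": 50.0, "T": 50.0}

    def test_homozygous_alternate(self):
        call = CalledVariant("c", 10, "G", ("C",), (1, 1))
        assert expected_counts(call, 80).expected == {"C": 80.0}

    def test_insertion_allele_adds_insertion_beyond_anchor_base(self):
        call = CalledVariant("c", 10, "A", ("AG",), (0, 1))
        exp = expected_counts(call, 200).expected
        assert exp == {"A": 200.0, "insertion": 100.0}

    def test_genotype_index_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="genotype index"):
            CalledVariant("c", 10, "A", ("T",), (0, 2))

    def test_base_and_deletion_expectation_sums_to_depth(self):
        call = CalledVariant("c", 10, "AG", ("A",), (0, 1))
        exp = expected_counts(call, 60).expected
        assert sum(v for c, v in exp.items() if c != "insertion") == 60


class TestExpectedAtTarget:
    def test_insertion_call_overlays_following_position(self):
        calls = {("c", 9): CalledVariant("c", 9, "A", ("AG",), (0, 1))}
        exp, rec = expected_at_target(calls, "c", 10, depth=200, ref_base="G")
        assert exp["insertion"] == 100.0
        assert exp["G"] == 200.0  # base weight falls back to the reference
        assert rec is not None

    def test_deletion_call_overlays_deleted_position(self):
        calls = {("c", 9): CalledVariant("c", 9, "AG", ("A",), (0, 1))}
        exp, _ = expected_at_target(calls, "c", 10, depth=100, ref_base="G")
        assert exp == {"deletion": 50.0, "G": 50.0}

    def test_snv_at_its_own_position(self):
        calls = {("c", 10): CalledVariant("c", 10, "C", ("T",), (0, 1))}
        exp, _ = expected_at_target(calls, "c", 10, depth=100, ref_base="C")
        assert exp == {"C": 50.0, "T": 50.0}

    def test_no_overlapping_record_expects_pure_reference(self):
        exp, rec = expected_at_target({}, "c", 10, depth=40, ref_base="T")
        assert exp == {"T": 40.0} and rec is None


@pytest.fixture(scope="module")
def pipeline(tmp_path_factory):
    ref = random_reference(400, 5)
    spec = CompositionSpec(
        chrom="t", pos=200, coverage=300,
        base_fractions={"C": 0.7, "T": 0.3}, insertion_fraction=0.2,
        inserted_seq="GA", seed=13,
    )
    reads = simulate_position_reads(spec, ref)
    d = tmp_path_factory.mktemp("pipe")
    bam, _, fasta = write_alignment_fixture(reads, ref, d)
    return bam, fasta, ref


class TestSummarizeSample:
    def test_records_follow_target_order(self, pipeline):
        bam, fasta, _ = pipeline
        targets = parse_target_spec("t 198 200\nt 300\nmissing 5\nt 200\nt 200\nt 200")
        records = summarize_sample("S", bam, targets, RunConfig(), fasta)
        assert len(records) == len(targets)
        assert [r.target for r in records] == targets

    def test_absent_contig_yields_zero_depth_record(self, pipeline):
        bam, fasta, _ = pipeline
        records = summarize_sample(
            "S", bam, [TargetPosition("missing", 5)], RunConfig(), fasta)
        assert records[0].counts.depth == 0
        assert records[0].frequencies.denominator == 0

    def test_reference_base_matches_fasta(self, pipeline):
        bam, fasta, ref = pipeline
        records = summarize_sample(
            "S", bam, [TargetPosition("t", 123)], RunConfig(), fasta)
        assert records[0].ref_base == ref[122]

    def test_occurrence_index_selects_kth_inserted_base(self, pipeline):
        bam, fasta, _ = pipeline
        targets = parse_target_spec("t 200\nt 200\nt 200")
        records = summarize_sample("S", bam, targets, RunConfig(), fasta)
        n_ins = records[0].counts.counts["insertion"]
        assert records[0].insertion_display == {"G": n_ins}
        assert records[1].insertion_display == {"A": n_ins}
        assert records[2].insertion_display == {}  # no third inserted base

    def test_expected_absent_without_calls_vcf(self, pipeline):
        bam, fasta, _ = pipeline
        records = summarize_sample(
            "S", bam, [TargetPosition("t", 200)], RunConfig(), fasta)
        assert records[0].expected is None


class TestRecoveryBand:
    def test_alternate_fraction_recovered_within_binomial_band(self):
        """freq[alt] lands within 4·sqrt(p(1−p)/n) of p in >= 19 of 20 seeds."""
        from basepile.pileup_engine import observe_read_at

        p, n = 0.1, 800
        band = 4 * math.sqrt(p * (1 - p) / n)
        hits = 0
        for seed in range(20):
            spec = CompositionSpec(
                chrom="t", pos=100, coverage=n,
                base_fractions={"G": 1 - p, "A": p}, seed=seed,
            )
            reads = simulate_position_reads(spec)
            obs = [o for r in reads if (o := observe_read_at(r, 100))]
            ft = compute_frequencies(tally_position(obs, 50))
            if abs(ft.freq["A"] - p) <= band:
                hits += 1
        assert hits >= 19
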