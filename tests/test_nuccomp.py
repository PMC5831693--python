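"""Seeded nucleotide alignment, pair summaries, SNPs, dotplots, clustering."""

from __future__ import annotations

import math

import numpy as np
import pytest

from propiphage import nuccomp
from propiphage.core_io import GenomeRecord, revcomp
from propiphage.nuccomp import (
    assign_clusters,
    count_snps,
    dotplot,
    seed_extend_align,
    summarize_pair,
)
from conftest import random_dna


def genome(seq: str, gid: str = "g") -> GenomeRecord:
    return GenomeRecord(id=gid, sequence=seq, source="synthetic")


def mutate(rng: np.random.Generator, seq: str, positions) -> str:
    arr = list(seq)
    for p in positions:
        arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
    return "".join(arr)


class TestSeedExtend:
    def test_self_alignment_full_length_identity(self, cohort_genomes):
        g = cohort_genomes[0]
        hsps = seed_extend_align(g, g)
        full = [h for h in hsps if h.a_start == 1 and h.a_end == g.length_bp]
        assert len(full) == 1
        assert full[0].identity_percent == 100.0
        assert full[0].strand == "+"

    def test_reverse_complement_flagged_minus(self, rng):
        s = random_dna(rng, 5000)
        hsps = seed_extend_align(genome(s, "a"), genome(revcomp(s), "b"))
        full = [h for h in hsps if h.strand == "-" and h.a_start == 1 and h.a_end == 5000]
        assert len(full) == 1
        assert full[0].b_start == 1 and full[0].b_end == 5000

    def test_planted_segment_recovered(self, rng):
        """A 500 bp segment at 95% identity planted in otherwise unrelated
        30 kb sequences is recovered as exactly one retained HSP covering
        >=90% of the plant."""
        a = random_dna(rng, 30_000)
        b = random_dna(rng, 30_000)
        segment = a[10_000:10_500]
        n_subs = 25  # 5% of 500
        positions = rng.choice(500, size=n_subs, replace=False)
        planted = mutate(rng, segment, positions)
        b = b[:20_000] + planted + b[20_500:]
        hsps = seed_extend_align(genome(a, "a"), genome(b, "b"))
        assert len(hsps) == 1
        h = hsps[0]
        overlap = min(h.a_end, 10_500) - max(h.a_start, 10_001) + 1
        assert overlap >= 0.9 * 500
        assert h.e_value <= 1e-5

    def test_sequence_shorter_than_word_is_empty(self):
        assert seed_extend_align(genome("ACGTACGT", "a"), genome("ACGTACGT" * 10, "b")) == []

    def test_no_spurious_hits_between_random_genomes(self):
        """Karlin-Altschul filtering at E<=1e-5 leaves no HSP between
        independent random 10 kb sequences (20 seeds)."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            a, b = random_dna(r, 10_000), random_dna(r, 10_000)
            assert seed_extend_align(genome(a, "a"), genome(b, "b")) == []


class TestSummarizePair:
    def test_self_pair_is_100_100_with_zero_snps(self, cohort_genomes):
        g = cohort_genomes[0]
        s = summarize_pair(g, g)
        assert s.identity_percent == 100.0
        assert s.coverage_percent == 100.0
        assert s.snp_count == 0

    def test_summary_symmetric_under_argument_swap(self, cohort_genomes):
        a, b = cohort_genomes[0], cohort_genomes[4]
        ab, ba = summarize_pair(a, b), summarize_pair(b, a)
        assert ab.identity_percent == pytest.approx(ba.identity_percent, abs=0.05)
        assert ab.coverage_percent == pytest.approx(ba.coverage_percent, abs=0.05)

    def test_within_cluster_coverage_exceeds_between(self, cohort_summaries, cohort_truth):
        labels = cohort_truth.cluster_labels
        within = [s.coverage_percent for s in cohort_summaries
                  if labels[s.genome_a] == labels[s.genome_b]]
        between = [s.coverage_percent for s in cohort_summaries
                   if labels[s.genome_a] != labels[s.genome_b]]
        assert min(within) > max(between)

    def test_expected_coverage_matches_module_truth(self, cohort_summaries, cohort_truth):
        for s in cohort_summaries:
            expected = cohort_truth.expected_pairs[f"{s.genome_a}|{s.genome_b}"]
            assert s.coverage_percent == pytest.approx(
                expected["expected_coverage_percent"], abs=3.0)


class TestCountSnps:
    def test_identical_sequences_zero(self, rng):
        s = random_dna(rng, 2000)
        assert count_snps(genome(s, "a"), genome(s, "b")) == 0

    def test_planted_substitutions_counted_exactly(self, cohort_genomes, rng):
        g = cohort_genomes[0]
        positions = rng.choice(g.length_bp, size=5, replace=False)
        mutant = genome(mutate(rng, g.sequence, positions), "mut")
        assert count_snps(g, mutant) == 5

    def test_twin_pair_matches_planted_truth(self, cohort_genomes, cohort_truth):
        by_id = {g.id: g for g in cohort_genomes}
        a, b = cohort_truth.twin_pair
        assert count_snps(by_id[a], by_id[b]) == cohort_truth.twin_snps

    def test_low_coverage_pair_is_rejected(self, cohort_genomes):
        a = cohort_genomes[0]       # cluster A
        b = cohort_genomes[4]       # cluster B: ~35% coverage
        with pytest.raises(ValueError, match="summarize_pair"):
            count_snps(a, b)

    def test_indels_reported_separately(self, rng):
        s = random_dna(rng, 3000)
        edited = s[:1000] + s[1003:2000] + "A" + s[2000:]   # one deletion + one insertion
        diffs = nuccomp.collinear_differences(s, edited)
        assert diffs["indel_events"] == 2
        assert diffs["snp_count"] <= 2   # spurious substitutions only at junctions, if any


class TestDotplot:
    def test_self_plot_main_diagonal(self, rng):
        # draw until the sequence has no repeated 10-mer (deterministic rng chain)
        while True:
            s = random_dna(rng, 600)
            words = [s[i : i + 10] for i in range(len(s) - 9)]
            if len(set(words)) == len(words):
                break
        match = dotplot(genome(s, "a"), genome(s, "b"), word=10)
        diag = [(a, b) for a, b, st in match.matches if st == "+" and a == b]
        assert len(diag) == len(s) - 10 + 1

    def test_planted_module_appears_at_offset(self, rng):
        a = random_dna(rng, 4000)
        b = random_dna(rng, 4000)
        b = b[:3000] + a[500:1000] + b[3500:]
        match = dotplot(genome(a, "a"), genome(b, "b"), word=10)
        offdiag = [(x, y) for x, y, st in match.matches if st == "+"]
        run = [(x, y) for x, y in offdiag if y - x == 2500 and 501 <= x <= 991]
        assert len(run) == 491  # full collinear run at the planted offset

    def test_chance_match_count_within_3_sigma(self):
        """Forward word matches between independent random 10 kb sequences
        follow the binomial expectation (L-9)^2 / 4^10."""
        rng = np.random.default_rng(42)
        a, b = random_dna(rng, 10_000), random_dna(rng, 10_000)
        match = dotplot(genome(a, "a"), genome(b, "b"), word=10)
        observed = sum(1 for *_ , st in match.matches if st == "+")
        n_pairs = (10_000 - 9) ** 2
        p = 0.25 ** 10
        expected = n_pairs * p
        sigma = math.sqrt(n_pairs * p * (1 - p))
        assert abs(observed - expected) <= 3 * sigma

    def test_downsampling_keeps_main_diagonal(self, rng):
        s = random_dna(rng, 2000)
        match = dotplot(genome(s, "a"), genome(s, "b"), word=10, max_points=100)
        diag = [(a, b) for a, b, st in match.matches if st == "+" and a == b]
        assert len(diag) == len(s) - 9

    def test_short_word_rejected(self):
        with pytest.raises(ValueError):
            dotplot("ACGTACGTACGT", "ACGTACGTACGT", word=3)


class TestAssignClusters:
    def test_recovers_planted_partition(self, cohort_summaries, cohort_truth):
        assignment = assign_clusters(cohort_summaries)
        assert assignment.labels == cohort_truth.cluster_labels

    def test_invariant_to_input_order(self, cohort_summaries, rng):
        shuffled = list(cohort_summaries)
        rng.shuffle(shuffled)
        assert assign_clusters(shuffled).labels == assign_clusters(cohort_summaries).labels

    def test_single_genome_is_singleton(self):
        s = nuccomp.PairwiseNucSummary("only", "only", 100.0, 100.0, [], 0)
        assert assign_clusters([s]).clusters() == {"A": ["only"]}

    def test_missing_pair_reported(self, cohort_summaries):
        with pytest.raises(ValueError, match="phiA1"):
            assign_clusters(cohort_summaries[2:])
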