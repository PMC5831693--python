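"""att-core discovery (suffix automaton vs brute force) and prophage
reconstruction with per-gene provenance."""

from __future__ import annotations

import numpy as np
import pytest

from propiphage import attscan, forge
from propiphage.attscan import (
    AttSite,
    find_att_core,
    gene_provenance,
    longest_common_substring,
    scan_prophages,
    trna_overlap,
)
from propiphage.core_io import GeneFeature, GenomeRecord
from propiphage.phams import ProteinEntry
from conftest import random_dna


def brute_force_lcs_length(a: str, b: str) -> int:
    """O(n*m) dynamic-programming oracle (row-vectorised)."""
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    best = 0
    for ch in a.encode():
        cur = np.zeros(len(b) + 1, dtype=np.int32)
        hit = bb == ch
        cur[1:][hit] = prev[:-1][hit] + 1
        m = cur.max()
        if m > best:
            best = int(m)
        prev = cur
    return best


class TestLongestCommonSubstring:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGTACGT", "TTTACGTT", 5),  # "TACGT"
        ("AAAA", "TTTT", 0),  # disjoint alphabets share nothing
        ("ACGT", "ACGT", 4),
    ])
    def test_small_cases(self, a, b, expected):
        length, a_end, b_end = longest_common_substring(a, b)
        assert length == expected
        if length:
            sub = b[b_end - length + 1 : b_end + 1]
            assert sub in a and sub in b

    def test_equals_brute_force_oracle_on_random_instances(self, rng):
        """Suffix-automaton result equals the DP oracle on instances up to
        5 kb, with and without planted shared substrings."""
        sizes = [(60, 150), (200, 800), (500, 2500), (1500, 5000)]
        for la, lb in sizes:
            for rep in range(4):
                a, b = random_dna(rng, la), random_dna(rng, lb)
                if rep % 2:  # plant a shared substring
                    k = int(rng.integers(10, min(40, la // 2)))
                    start_a = int(rng.integers(0, la - k))
                    start_b = int(rng.integers(0, lb - k))
                    b = b[:start_b] + a[start_a : start_a + k] + b[start_b + k :]
                length, a_end, b_end = longest_common_substring(a, b)
                assert length == brute_force_lcs_length(a, b)
                sub = b[b_end - length + 1 : b_end + 1]
                assert sub in a


class TestFindAttCore:
    def test_planted_core_recovered_at_exact_coordinates(self, cohort_genomes,
                                                         cohort_truth, plain_host):
        host, host_truth = plain_host
        phage = cohort_genomes[0]
        integrase = next(g for g in phage.genes if "integrase" in g.product)
        site = find_att_core(phage, integrase, host)
        truth = cohort_truth.att[phage.id]
        assert site is not None
        assert site.core_length == len(truth["core_sequence"])
        assert (site.attP_start, site.attP_end) == (truth["attP_start"], truth["attP_end"])
        assert (site.attB_start, site.attB_end) == (host_truth.host["attB_start"],
                                                    host_truth.host["attB_end"])
        assert site.core_sequence == truth["core_sequence"]

    def test_core_string_identical_on_phage_and_host(self, cohort_genomes, plain_host):
        host, _ = plain_host
        phage = cohort_genomes[0]
        integrase = next(g for g in phage.genes if "integrase" in g.product)
        site = find_att_core(phage, integrase, host)
        assert phage.subseq(site.attP_start, site.attP_end) == \
               host.subseq(site.attB_start, site.attB_end)

    def test_minus_strand_host_occurrence_found(self, cohort_genomes, plain_host, rng):
        from propiphage.core_io import revcomp
        host, _ = plain_host
        flipped = GenomeRecord(id="flip", sequence=revcomp(host.sequence), source="synthetic")
        phage = cohort_genomes[0]
        integrase = next(g for g in phage.genes if "integrase" in g.product)
        site = find_att_core(phage, integrase, flipped)
        assert site is not None and site.host_strand == "-"
        assert site.core_sequence == find_att_core(phage, integrase, host).core_sequence

    def test_unrelated_host_yields_none(self, cohort_genomes, rng):
        host = GenomeRecord(id="h", sequence=random_dna(rng, 50_000), source="synthetic")
        phage = cohort_genomes[0]
        integrase = next(g for g in phage.genes if "integrase" in g.product)
        assert find_att_core(phage, integrase, host) is None

    def test_window_truncated_with_warning(self, cohort_genomes, plain_host):
        host, _ = plain_host
        phage = cohort_genomes[0]
        near_start = GeneFeature("x", 40, 400, "+", product="tyrosine integrase")
        with pytest.warns(UserWarning, match="truncated"):
            attscan._upstream_window(phage, near_start, 500)


class TestTrnaOverlap:
    def make_site(self, b_start: int, b_end: int) -> AttSite:
        n = b_end - b_start + 1
        return AttSite(core_length=n, core_sequence="A" * n, attP_start=1, attP_end=n,
                       attB_start=b_start, attB_end=b_end)

    def test_contained_and_disjoint(self):
        trna = GeneFeature("t1", 100, 175, "+", product="tRNA-Pro", kind="tRNA")
        assert trna_overlap(self.make_site(120, 160), [trna]) == "t1"
        assert trna_overlap(self.make_site(200, 240), [trna]) is None

    def test_single_terminal_base_counts_as_overlap(self):
        trna = GeneFeature("t1", 100, 175, "+", product="tRNA-Gly", kind="tRNA")
        assert trna_overlap(self.make_site(175, 219), [trna]) == "t1"
        assert trna_overlap(self.make_site(176, 220), [trna]) is None

    def test_non_trna_features_ignored(self):
        cds = GeneFeature("g1", 100, 175, "+", product="integrase", kind="CDS")
        assert trna_overlap(self.make_site(120, 160), [cds]) is None

    def test_planted_trna_found(self, cohort_genomes, plain_host):
        host, _ = plain_host
        phage = cohort_genomes[0]
        integrase = next(g for g in phage.genes if "integrase" in g.product)
        site = find_att_core(phage, integrase, host)
        assert trna_overlap(site, host.genes) == "trna1"


class TestScanProphages:
    def test_split_contig_prophage_reconstructed(self, cohort_genomes, prophage_host):
        contigs, host_truth = prophage_host
        calls = scan_prophages(contigs, cohort_genomes[:4])
        assert len(calls) == 1
        call = calls[0]
        assert {s.contig_id for s in call.segments} == {"host_c1", "host_c17"}
        t = host_truth.host
        assert call.attL["contig"] == t["attL"]["contig"]
        assert abs(call.attL["start"] - t["attL"]["start"]) <= 5
        assert abs(call.attL["end"] - t["attL"]["end"]) <= 5
        assert call.attR["contig"] == t["attR"]["contig"]
        assert abs(call.attR["start"] - t["attR"]["start"]) <= 5
        assert abs(call.attR["end"] - t["attR"]["end"]) <= 5
        assert call.attL["core_sequence"] == t["core_sequence"]

    def test_provenance_switches_donor_at_breakpoint(self, cohort_genomes, prophage_host):
        contigs, host_truth = prophage_host
        calls = scan_prophages(contigs, cohort_genomes[:4])
        truth_by_gene = {g["gene_number"]: g["donor"]
                         for g in host_truth.host["prophage"]["genes"]}
        assert calls[0].genes
        for g in calls[0].genes:
            assert g["source_phage"] == truth_by_gene[g["gene_number"]]
        donors = [truth_by_gene[g["gene_number"]] for g in calls[0].genes]
        assert len(set(donors)) == 2  # both donors represented across the breakpoint

    def test_prophage_free_host_yields_empty(self, cohort_genomes, rng):
        host = GenomeRecord(id="clean", sequence=random_dna(rng, 60_000), source="synthetic")
        assert scan_prophages([host], cohort_genomes[:2]) == []

    def test_high_min_hit_suppresses_call(self, cohort_genomes, prophage_host):
        contigs, _ = prophage_host
        assert scan_prophages(contigs, cohort_genomes[:4], min_hit=100_000) == []


class TestGeneProvenance:
    def test_identical_protein_scores_100(self):
        panel = [ProteinEntry("pA_1", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", "pA"),
                 ProteinEntry("pB_1", "MWWHHCCEEKARNDCEQGHILKMFPSTWYVMKT", "pB")]
        gene = GeneFeature("g", 1, 99, "+", product="x",
                           translation="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        table = gene_provenance([("c1", gene)], panel)
        assert table[0]["best_match"] == "pA_1"
        assert table[0]["identity_percent"] == 100.0
        assert table[0]["ties"] == []

    def test_exact_tie_is_reported(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        panel = [ProteinEntry("pA_1", seq, "pA"), ProteinEntry("pB_1", seq, "pB")]
        gene = GeneFeature("g", 1, 99, "+", translation=seq)
        table = gene_provenance([("c1", gene)], panel)
        assert table[0]["ties"] == ["pB_1"]
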