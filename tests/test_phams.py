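"""Protein alignment, pham clustering and shared-gene-content matrices."""

from __future__ import annotations

import numpy as np
import pytest

from propiphage import phams
from propiphage.phams import (
    Pham,
    ProteinEntry,
    align_protein_pair,
    build_phams,
    pair_is_related,
    shared_gene_fraction,
    shared_gene_matrix,
)
from conftest import random_dna

AAS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AAS), size=n))


def brute_force_phams(proteins, identity=32.5, coverage=50.0):
    """Independent oracle: naive all-vs-all alignment and fixed-point
    transitive closure (no prefilter, no union-find)."""
    ids = [p.protein_id for p in proteins]
    related = {i: {i} for i in range(len(proteins))}
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            if pair_is_related(proteins[i], proteins[j], identity, coverage):
                related[i].add(j)
                related[j].add(i)
    # fixed-point closure
    changed = True
    while changed:
        changed = False
        for i in range(len(proteins)):
            expanded = set(related[i])
            for j in related[i]:
                expanded |= related[j]
            if expanded != related[i]:
                related[i] = expanded
                changed = True
    groups = {frozenset(ids[j] for j in related[i]) for i in range(len(proteins))}
    return groups


class TestAlignProteinPair:
    def test_identical_sequences(self):
        res = align_protein_pair("MKTAYIAKQR", "MKTAYIAKQR")
        assert res["identity_percent"] == pytest.approx(100.0)

    def test_single_substitution_identity(self):
        # one mismatch over six aligned columns
        res = align_protein_pair("ACDEFG", "ACDKFG")
        assert res["identity_percent"] == pytest.approx(100 * 5 / 6, abs=0.01)
        assert res["aligned_columns"] == 6

    def test_symmetry(self, rng):
        for _ in range(5):
            a, b = random_protein(rng, 80), random_protein(rng, 90)
            ab, ba = align_protein_pair(a, b), align_protein_pair(b, a)
            assert ab["identity_percent"] == pytest.approx(ba["identity_percent"])
            assert ab["score"] == pytest.approx(ba["score"])

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_protein_pair("", "MKT")


class TestBuildPhams:
    def test_identical_proteins_form_one_pham(self):
        prots = [ProteinEntry(f"p{i}", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", "g")
                 for i in range(5)]
        result = build_phams(prots)
        assert len(result) == 1 and result[0].size == 5

    def test_transitive_chain_links_unrelated_ends(self, rng):
        """A~B and B~C via shared halves, A and C unrelated: single linkage
        must still produce one pham {A,B,C} (checked against the naive
        fixed-point closure oracle)."""
        u, v, w, z = (random_protein(rng, 80) for _ in range(4))
        prots = [ProteinEntry("A", u + v), ProteinEntry("B", v + w), ProteinEntry("C", w + z)]
        assert pair_is_related(prots[0], prots[1])
        assert pair_is_related(prots[1], prots[2])
        assert not pair_is_related(prots[0], prots[2])
        got = {frozenset(p.members) for p in build_phams(prots, prefilter=False)}
        assert got == {frozenset({"A", "B", "C"})}
        assert got == brute_force_phams(prots)

    def test_random_proteins_are_singletons(self, rng):
        prots = [ProteinEntry(f"r{i}", random_protein(rng, 100)) for i in range(20)]
        result = build_phams(prots)
        assert len(result) == 20
        assert all(p.size == 1 for p in result)

    def test_matches_oracle_and_prefilter_is_lossless_on_cohort_subset(self, cohort_genomes):
        proteins, _ = phams.proteins_from_genomes(cohort_genomes[:2])
        with_filter = {frozenset(p.members) for p in build_phams(proteins)}
        without = {frozenset(p.members) for p in build_phams(proteins, prefilter=False)}
        oracle = brute_force_phams(proteins)
        assert with_filter == without == oracle

    def test_partition_invariant_under_input_order(self, cohort_genomes, rng):
        proteins, _ = phams.proteins_from_genomes(cohort_genomes[:2])
        shuffled = list(proteins)
        rng.shuffle(shuffled)
        a = [(p.pham_id, p.members) for p in build_phams(proteins)]
        b = [(p.pham_id, p.members) for p in build_phams(shuffled)]
        assert a == b

    def test_partition_covers_all_proteins_disjointly(self, cohort_phams):
        pham_list, proteins, _ = cohort_phams
        seen: set[str] = set()
        for p in pham_list:
            assert p.size >= 1
            assert not (p.members & seen)
            seen |= p.members
        assert seen == {p.protein_id for p in proteins}

    def test_recovers_planted_module_families(self, cohort_phams, cohort_truth):
        pham_list, _, _ = cohort_phams
        planted: dict[str, set[str]] = {}
        for pid, module in cohort_truth.pham_truth.items():
            planted.setdefault(module, set()).add(pid)
        assert {frozenset(p.members) for p in pham_list} == \
               {frozenset(v) for v in planted.values()}


class TestSharedGeneContent:
    def test_self_fraction_is_one(self, cohort_phams):
        pham_list, _, genome_of = cohort_phams
        frac = shared_gene_fraction("phiA1", "phiA1", pham_list, genome_of)
        assert frac == {"a_to_b": 1.0, "b_to_a": 1.0, "mean": 1.0}

    def test_disjoint_pools_share_nothing(self):
        prots = ([ProteinEntry(f"g1_{i}", "MKTAYIAKQR" + AAS[i] * 30, "g1") for i in range(4)]
                 + [ProteinEntry(f"g2_{i}", "MWWHHCCEEK" + AAS[i + 5] * 30, "g2")
                    for i in range(4)])
        genome_of = {p.protein_id: p.genome_id for p in prots}
        pl = build_phams(prots)
        frac = shared_gene_fraction("g1", "g2", pl, genome_of)
        assert frac["mean"] == 0.0

    def test_directional_fractions_match_truth_counts(self, cohort_phams, cohort_truth):
        pham_list, _, genome_of = cohort_phams
        ga, gb = "phiA1", "phiB1"
        modules = {}
        for pid, module in cohort_truth.pham_truth.items():
            modules.setdefault(pid.rsplit("_", 1)[0], set()).add(module)
        both = len(modules[ga] & modules[gb])
        frac = shared_gene_fraction(ga, gb, pham_list, genome_of)
        assert frac["a_to_b"] == pytest.approx(both / len(modules[ga]))
        assert frac["b_to_a"] == pytest.approx(both / len(modules[gb]))

    def test_unknown_genome_rejected(self, cohort_phams):
        pham_list, _, genome_of = cohort_phams
        with pytest.raises(ValueError, match="nosuch"):
            shared_gene_fraction("nosuch", "phiA1", pham_list, genome_of)

    def test_matrix_block_structure(self, cohort_phams, cohort_truth, cohort_genomes):
        """Within-cluster shared-gene proportions strictly exceed every
        between-cluster proportion (the heat-map block structure)."""
        pham_list, _, genome_of = cohort_phams
        ids = [g.id for g in cohort_genomes]
        m = shared_gene_matrix(ids, pham_list, genome_of)
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.allclose(m.values, m.values.T)
        labels = cohort_truth.cluster_labels
        within, between = [], []
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    (within if labels[a] == labels[b] else between).append(m.values[i, j])
        assert min(within) > max(between)
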