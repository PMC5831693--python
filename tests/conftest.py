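"""Shared fixtures: one default synthetic cohort (and derived artifacts) per
test session, so the expensive generation and pairwise comparison run once."""

from __future__ import annotations

import numpy as np
import pytest

from propiphage import forge, nuccomp, phams


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition cohort: 7 genomes in clusters of 4 + 3, twin pair
    differing by 2 substitutions."""
    return forge.forge_cohort(forge.ForgeConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_genomes(default_cohort):
    return default_cohort[0]


@pytest.fixture(scope="session")
def cohort_truth(default_cohort):
    return default_cohort[1]


@pytest.fixture(scope="session")
def cohort_summaries(cohort_genomes):
    return [nuccomp.summarize_pair(a, b)
            for i, a in enumerate(cohort_genomes) for b in cohort_genomes[i + 1 :]]


@pytest.fixture(scope="session")
def cohort_phams(cohort_genomes):
    proteins, genome_of = phams.proteins_from_genomes(cohort_genomes)
    return phams.build_phams(proteins), proteins, genome_of


@pytest.fixture(scope="session")
def plain_host(default_cohort):
    """Host with a vacant attB (no prophage) for att-core discovery."""
    genomes, truth = default_cohort
    cfg = forge.ForgeConfig(seed=1)
    contigs, host_truth = forge.forge_host(cfg, [genomes[0], genomes[1]], truth,
                                           with_prophage=False)
    return contigs[0], host_truth


@pytest.fixture(scope="session")
def prophage_host(default_cohort):
    """Host carrying a chimeric split-contig prophage from two cluster-A donors."""
    genomes, truth = default_cohort
    cfg = forge.ForgeConfig(seed=1)
    contigs, host_truth = forge.forge_host(cfg, [genomes[0], genomes[1]], truth,
                                           with_prophage=True)
    return contigs, host_truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
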