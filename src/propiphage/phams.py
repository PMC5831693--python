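"""All-vs-all protein comparison and transitive clustering into phamilies.

A *pham* (phamily) is an equivalence class of phage proteins grouped by
pairwise sequence similarity; phams are the unit of gene-content comparison
between genomes.  Two proteins are directly related when a global alignment
shows at least ``identity_threshold`` percent identity over at least
``coverage_threshold`` of the shorter protein; phams are the single-linkage
transitive closure of this relation.  The default operating point
(>= 32.5 % identity over >= 50 % of the shorter protein, BLOSUM62 with
affine gap costs 11/1) is the classical gene-family clustering point used
for actinobacteriophage comparative genomics and is exposed as
configuration.

For cohorts where related proteins are near-identical and unrelated ones
are effectively random (the regime of a phage cluster cohort), an exact
k-mer prefilter skips alignments that cannot reach the identity threshold;
it can be disabled to force the full all-vs-all alignment.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices


@dataclass(frozen=True)
class ProteinEntry:
    """One predicted protein: ``protein_id`` is ``genome_id`` + gene number."""

    protein_id: str
    translation: str
    genome_id: str = ""

    def __post_init__(self) -> None:
        if not self.translation:
            raise ValueError(f"protein {self.protein_id}: empty translation")

    @property
    def length_aa(self) -> int:
        return len(self.translation)


@dataclass
class Pham:
    pham_id: int
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SharedGeneMatrix:
    """Symmetric matrix of (symmetrised) shared-gene proportions in [0, 1]."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("shared-gene matrix must be symmetric")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("shared-gene proportions must lie in [0, 1]")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("diagonal must be 1 (every genome shares all phams with itself)")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("genome\t" + "\t".join(self.ids) + "\n")
            for i, gid in enumerate(self.ids):
                fh.write(gid + "\t" + "\t".join(f"{v:.4f}" for v in self.values[i]) + "\n")


def _make_aligner(open_gap: float = 11.0, extend_gap: float = 1.0,
                  matrix: str = "BLOSUM62") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(open_gap)
    aligner.extend_gap_score = -abs(extend_gap)
    aligner.mode = "global"
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


def align_protein_pair(a: ProteinEntry | str, b: ProteinEntry | str,
                       aligner: PairwiseAligner | None = None) -> dict[str, float]:
    """Globally align two proteins (BLOSUM62, affine gaps open 11 / extend 1).

    Returns ``identity_percent`` (identical columns over aligned columns,
    where terminal-gap columns are excluded but internal gap columns count),
    ``aligned_columns``, ``aligned_span`` (number of residue-residue
    columns) and the alignment ``score``.  Symmetric in its arguments.
    """
    sa = a.translation if isinstance(a, ProteinEntry) else a
    sb = b.translation if isinstance(b, ProteinEntry) else b
    if not sa or not sb:
        raise ValueError("cannot align an empty protein sequence")
    if sb < sa:
        # canonical argument order: co-optimal alignments can differ between
        # align(a,b) and align(b,a); fixing the order makes identity symmetric
        sa, sb = sb, sa
    aligner = aligner or _DEFAULT_ALIGNER
    alignment = aligner.align(sa, sb)[0]
    counts = alignment.counts()
    aligned_span = counts.identities + counts.mismatches
    aligned_columns = aligned_span + counts.internal_gaps
    identity = 100.0 * counts.identities / aligned_columns if aligned_columns else 0.0
    return {
        "identity_percent": identity,
        "aligned_columns": aligned_columns,
        "aligned_span": aligned_span,
        "score": float(alignment.score),
    }


def pair_is_related(a: ProteinEntry, b: ProteinEntry,
                    identity_threshold: float = 32.5,
                    coverage_threshold: float = 50.0,
                    aligner: PairwiseAligner | None = None) -> bool:
    """The direct pham relation: identity and shorter-protein coverage both
    above threshold."""
    res = align_protein_pair(a, b, aligner=aligner)
    shorter = min(a.length_aa, b.length_aa)
    coverage = 100.0 * res["aligned_span"] / shorter
    return res["identity_percent"] >= identity_threshold and coverage >= coverage_threshold


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx

    def groups(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for x in self.parent:
            out[self.find(x)].add(x)
        return out


def _kmer_candidates(proteins: Sequence[ProteinEntry], k: int = 6,
                     min_shared: int = 2) -> set[tuple[int, int]]:
    """Index k-mers to propose candidate pairs sharing >= ``min_shared`` words."""
    index: dict[str, list[int]] = defaultdict(list)
    for i, p in enumerate(proteins):
        seq = p.translation
        for w in {seq[j : j + k] for j in range(len(seq) - k + 1)}:
            index[w].append(i)
    shared: dict[tuple[int, int], int] = defaultdict(int)
    for ids in index.values():
        if len(ids) < 2:
            continue
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                shared[(ids[x], ids[y])] += 1
    return {pair for pair, n in shared.items() if n >= min_shared}


def build_phams(proteins: Sequence[ProteinEntry],
                identity_threshold: float = 32.5,
                coverage_threshold: float = 50.0,
                prefilter: bool = True,
                aligner: PairwiseAligner | None = None) -> list[Pham]:
    """Cluster proteins into phams by single-linkage transitive closure.

    Pham ids are assigned deterministically: phams are sorted by their
    lexicographically smallest member id and numbered from 1, so the output
    is invariant under input order.

    With ``prefilter=True`` (default) only pairs sharing at least two exact
    amino-acid 6-mers are aligned.  A pair at the 32.5 % identity threshold
    with fewer shared 6-mers is possible in principle for highly diverged
    real proteins; disable the prefilter to force the exact all-vs-all build.
    """
    if not proteins:
        raise ValueError("build_phams requires at least one protein")
    ids = [p.protein_id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("protein ids must be unique within a cohort")
    # Deterministic processing order regardless of caller order.
    order = sorted(range(len(proteins)), key=lambda i: ids[i])
    proteins = [proteins[i] for i in order]
    ids = [p.protein_id for p in proteins]

    uf = _UnionFind(ids)
    if prefilter:
        candidates = _kmer_candidates(proteins)
    else:
        candidates = {(i, j) for i in range(len(proteins)) for j in range(i + 1, len(proteins))}
    for i, j in sorted(candidates):
        if uf.find(ids[i]) == uf.find(ids[j]):
            # Already linked transitively; alignment cannot change the closure.
            continue
        if pair_is_related(proteins[i], proteins[j], identity_threshold,
                           coverage_threshold, aligner=aligner):
            uf.union(ids[i], ids[j])
    groups = sorted(uf.groups().values(), key=lambda g: min(g))
    return [Pham(pham_id=k + 1, members=frozenset(g)) for k, g in enumerate(groups)]


def pham_table(phams: Sequence[Pham]) -> dict[str, int]:
    """Mapping protein_id -> pham_id."""
    out: dict[str, int] = {}
    for pham in phams:
        for member in pham.members:
            out[member] = pham.pham_id
    return out


def write_pham_table(phams: Sequence[Pham], path: str | Path) -> None:
    table = pham_table(phams)
    with open(path, "w") as fh:
        fh.write("protein_id\tpham_id\n")
        for pid in sorted(table):
            fh.write(f"{pid}\t{table[pid]}\n")


def _genome_pham_sets(phams: Sequence[Pham],
                      genome_of: Mapping[str, str]) -> dict[str, set[int]]:
    sets: dict[str, set[int]] = defaultdict(set)
    for pham in phams:
        for member in pham.members:
            sets[genome_of[member]].add(pham.pham_id)
    return sets


def shared_gene_fraction(genome_a: str, genome_b: str, phams: Sequence[Pham],
                         genome_of: Mapping[str, str]) -> dict[str, float]:
    """Directional and symmetrised shared-pham proportions for a genome pair.

    ``genome_of`` maps protein_id -> genome_id for every pham member.
    Returns ``a_to_b`` (= |phams in both| / |phams in a|), ``b_to_a`` and
    their ``mean``.
    """
    sets = _genome_pham_sets(phams, genome_of)
    for g in (genome_a, genome_b):
        if g not in sets:
            raise ValueError(f"genome {g} contributed no proteins to the pham build")
    both = len(sets[genome_a] & sets[genome_b])
    a_to_b = both / len(sets[genome_a])
    b_to_a = both / len(sets[genome_b])
    return {"a_to_b": a_to_b, "b_to_a": b_to_a, "mean": (a_to_b + b_to_a) / 2.0}


def shared_gene_matrix(genome_ids: Sequence[str], phams: Sequence[Pham],
                       genome_of: Mapping[str, str]) -> SharedGeneMatrix:
    """Symmetrised shared-gene-content matrix over a cohort (heat-map input)."""
    n = len(genome_ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            frac = shared_gene_fraction(genome_ids[i], genome_ids[j], phams, genome_of)
            values[i, j] = values[j, i] = frac["mean"]
    return SharedGeneMatrix(ids=list(genome_ids), values=values)


def proteins_from_genomes(genomes: Sequence) -> tuple[list[ProteinEntry], dict[str, str]]:
    """Extract :class:`ProteinEntry` objects (and protein->genome map) from
    annotated :class:`~propiphage.core_io.GenomeRecord` objects."""
    proteins: list[ProteinEntry] = []
    genome_of: dict[str, str] = {}
    for genome in genomes:
        for gene in genome.genes:
            if gene.kind != "CDS" or not gene.translation:
                continue
            pid = f"{genome.id}_{gene.gene_number}"
            proteins.append(ProteinEntry(protein_id=pid, translation=gene.translation,
                                         genome_id=genome.id))
            genome_of[pid] = genome.id
    return proteins, genome_of
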