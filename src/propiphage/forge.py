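"""Synthetic phage-cohort generator with planted ground truth.

The forge emulates the statistical structure of a cohort of temperate
*P. freudenreichii*-like siphophages so that every pipeline stage can be
exercised offline against known truth:

* ~35-39 kb, ~65 % GC genomes built from coding "modules" (synthetic ORFs,
  translation table 11) drawn from a shared pool;
* two clusters with extensive within-cluster module sharing and a smaller
  shared backbone between clusters, mirroring the span-coverage structure
  that separates phage clusters (within-cluster span coverage ~75 %,
  between-cluster ~35 %);
* a near-identical "twin" genome pair inside one cluster differing by a
  known handful of single-nucleotide substitutions;
* 12-base 3' cohesive ends (the stored sequence is the full virion top
  strand, so the overhang is the terminal 12 bases);
* per cluster, a tyrosine-integrase module with an attP common core planted
  in the spacer directly upstream;
* a host genome with an attB core overlapping a planted tRNA and,
  optionally, an integrated chimeric prophage (modules from two donor
  phages) split across two overlapping contigs in the middle of the
  tape-measure gene.

Mutations are substitutions only by default, keeping SNP-count truth exact;
substitutions inside ORFs never create internal stop codons, so every
emitted CDS re-translates cleanly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from propiphage.core_io import (
    GeneFeature,
    GenomeRecord,
    ReadStartProfile,
    revcomp,
    translate_cds,
)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass
class ForgeConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the observable structure of a seven-phage cohort in
    two clusters (4 + 3 genomes), ~36 kb genomes at ~65 % GC with 12-base
    3' cohesive ends, a 45 bp attP/attB common core, and a twin pair
    differing by exactly two substitutions.
    """

    seed: int = 1
    n_clusters: int = 2
    genomes_per_cluster: tuple[int, ...] = (4, 3)
    genome_length_bp: int = 36_000
    gc_target: float = 0.65
    # genome composition budgets (fractions of genome_length_bp in coding modules)
    backbone_fraction: float = 0.35   # modules shared across clusters
    cluster_core_fraction: float = 0.40  # additional modules shared within a cluster
    private_fraction: float = 0.17    # genome-private modules
    gene_length_range: tuple[int, int] = (450, 1500)
    spacer_length_range: tuple[int, int] = (40, 120)
    tape_measure_length: int = 3399   # ~1132 aa tail tape measure, the longest gene
    minus_strand_fraction: float = 0.15
    # divergence
    substitution_rate_within_cluster: float = 0.010
    substitution_rate_between_cluster: float = 0.040
    twin_pair: bool = True
    twin_snps: int = 2
    # cohesive ends
    cos_overhang: str | None = None   # None -> seeded random 12-mer
    cos_overhang_length: int = 12
    # integration
    att_core_lengths: tuple[int, ...] = (45, 49)
    # host
    host_length: int = 100_000
    host_gc: float = 0.67
    trna_length: int = 76
    attb_trna_overlap: int = 20
    prophage_split_at: int | None = None   # phage coordinate; None -> middle of tape measure
    contig_overlap: int = 150

    def __post_init__(self) -> None:
        for frac in (self.backbone_fraction, self.cluster_core_fraction,
                     self.private_fraction, self.gc_target, self.minus_strand_fraction):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        if self.backbone_fraction + self.cluster_core_fraction + self.private_fraction > 0.95:
            raise ValueError("module budgets exceed genome length (spacers need ~5%)")
        if self.genome_length_bp <= 0 or self.host_length <= 0:
            raise ValueError("lengths must be positive")
        if len(self.genomes_per_cluster) != self.n_clusters:
            raise ValueError("genomes_per_cluster must have n_clusters entries")


@dataclass
class _Module:
    """One coding module of the shared pool: a synthetic ORF."""

    module_id: str
    sequence: str          # coding-strand ancestral sequence (ATG ... stop)
    strand: str
    product: str


@dataclass
class ForgeTruth:
    """Planted ground truth, verified against the emitted records."""

    cluster_labels: dict[str, str] = field(default_factory=dict)
    pham_truth: dict[str, str] = field(default_factory=dict)  # protein_id -> module_id
    layouts: dict[str, list[dict]] = field(default_factory=dict)
    expected_pairs: dict[str, dict] = field(default_factory=dict)  # "a|b" -> stats
    twin_pair: tuple[str, str] | None = None
    twin_snps: int = 0
    cos: dict[str, dict] = field(default_factory=dict)
    att: dict[str, dict] = field(default_factory=dict)  # genome_id -> attP info
    host: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ---------------------------------------------------------------------------
# sequence primitives
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    return "".join(rng.choice(_BASES, size=length, p=_base_probs(gc)))


def _codon_table(gc: float) -> tuple[list[str], np.ndarray]:
    codons, weights = [], []
    p = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                if codon in _STOPS:
                    continue
                codons.append(codon)
                weights.append(p[b1] * p[b2] * p[b3])
    w = np.array(weights)
    return codons, w / w.sum()


def _random_orf(rng: np.random.Generator, length_nt: int, gc: float) -> str:
    """ATG + random non-stop codons + TAA, of total length ``length_nt``."""
    n_codons = max(length_nt // 3, 4)
    codons, weights = _codon_table(gc)
    idx = rng.choice(len(codons), size=n_codons - 2, p=weights)
    return "ATG" + "".join(codons[i] for i in idx) + "TAA"


def _mutate_orf(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute bases at ``rate`` without touching the start/stop codon or
    creating internal stop codons."""
    if rate <= 0:
        return seq
    arr = list(seq)
    n = len(arr)
    k = rng.binomial(n, rate)
    positions = rng.choice(n, size=min(k, n), replace=False)
    for pos in sorted(int(p) for p in positions):
        codon_idx = pos // 3
        if codon_idx == 0 or codon_idx == n // 3 - 1:
            continue  # keep start and stop codons intact
        old = arr[pos]
        choices = [b for b in "ACGT" if b != old]
        rng.shuffle(choices)
        for new in choices:
            arr[pos] = new
            codon = "".join(arr[3 * codon_idx : 3 * codon_idx + 3])
            if codon not in _STOPS:
                break
            arr[pos] = old
    return "".join(arr)


def _mutate_spacer(rng: np.random.Generator, seq: str, n_subs: int) -> tuple[str, int]:
    arr = list(seq)
    positions = rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False)
    done = 0
    for pos in positions:
        old = arr[int(pos)]
        arr[int(pos)] = rng.choice([b for b in "ACGT" if b != old])
        done += 1
    return "".join(arr), done


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _draw_modules(rng: np.random.Generator, budget_bp: int, cfg: ForgeConfig,
                  prefix: str, products: Sequence[str] = ()) -> list[_Module]:
    modules: list[_Module] = []
    total = 0
    i = 0
    while total < budget_bp:
        lo, hi = cfg.gene_length_range
        length = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
        product = products[i] if i < len(products) else "hypothetical protein"
        modules.append(_Module(module_id=f"{prefix}{i + 1:02d}",
                               sequence=_random_orf(rng, length, cfg.gc_target),
                               strand=strand, product=product))
        total += length
        i += 1
    return modules


def forge_cohort(config: ForgeConfig | None = None) -> tuple[list[GenomeRecord], ForgeTruth]:
    """Generate a phage cohort with planted cluster, pham, SNP, cos and att truth.

    Deterministic under ``config.seed``: the same configuration yields
    byte-identical genomes and truth.
    """
    cfg = config or ForgeConfig()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.genome_length_bp

    # --- module pools -----------------------------------------------------
    if cfg.backbone_fraction > 0:
        backbone = _draw_modules(
            rng, max(int(cfg.backbone_fraction * L) - cfg.tape_measure_length, 0), cfg, "bb",
            products=["terminase large subunit", "portal protein", "major capsid protein",
                      "major tail subunit", "endolysin", "holin"])
        # the tape-measure module opens the second backbone block, so it sits
        # near the middle of every genome layout (and of the prophage chimera)
        backbone.insert(len(backbone) // 2,
                        _Module("bb_tmp",
                                _random_orf(rng, cfg.tape_measure_length, cfg.gc_target),
                                "+", "tape measure protein"))
    else:
        backbone = []
    cluster_cores: list[list[_Module]] = []
    att_cores: list[str] = []
    for c in range(cfg.n_clusters):
        core = _draw_modules(rng, int(cfg.cluster_core_fraction * L), cfg, f"c{c}_",
                             products=["tyrosine integrase", "immunity repressor",
                                       "Cro-like protein", "antirepressor"])
        core[0] = _Module(core[0].module_id, core[0].sequence, "+", "tyrosine integrase")
        if not backbone:
            # no shared backbone: each cluster carries its own tape measure
            core.insert(len(core) // 2,
                        _Module(f"c{c}_tmp",
                                _random_orf(rng, cfg.tape_measure_length, cfg.gc_target),
                                "+", "tape measure protein"))
        cluster_cores.append(core)
        core_len = cfg.att_core_lengths[c % len(cfg.att_core_lengths)]
        att_cores.append(_random_dna(rng, core_len, cfg.gc_target))
    overhang = cfg.cos_overhang or _random_dna(rng, cfg.cos_overhang_length, cfg.gc_target)
    if cfg.cos_overhang is not None and len(overhang) != cfg.cos_overhang_length:
        cfg.cos_overhang_length = len(overhang)

    # cluster-level divergence of the shared backbone
    backbone_by_cluster: list[dict[str, str]] = []
    for c in range(cfg.n_clusters):
        backbone_by_cluster.append({
            m.module_id: _mutate_orf(rng, m.sequence, cfg.substitution_rate_between_cluster)
            for m in backbone
        })

    truth = ForgeTruth(twin_snps=cfg.twin_snps if cfg.twin_pair else 0)
    genomes: list[GenomeRecord] = []
    genome_modules: dict[str, dict[str, int]] = {}   # genome -> {module_id: bp}

    cluster_letters = "ABCDEFGH"
    twin_source: tuple[str, int] | None = None  # (genome_id, cluster)

    for c, n_genomes in enumerate(cfg.genomes_per_cluster):
        for g in range(n_genomes):
            gid = f"phi{cluster_letters[c]}{g + 1}"
            truth.cluster_labels[gid] = cluster_letters[c]

            is_twin_copy = (cfg.twin_pair and c == cfg.n_clusters - 1 and g == 1
                            and twin_source is not None)
            if is_twin_copy:
                _make_twin(gid, twin_source[0], genomes, truth, genome_modules, rng, cfg)
                continue

            # genome-specific copies of shared modules
            module_list: list[_Module] = []
            half = next((i for i, m in enumerate(backbone) if m.module_id == "bb_tmp"),
                        len(backbone))
            for m in backbone[:half]:
                module_list.append(_Module(m.module_id,
                                           _mutate_orf(rng, backbone_by_cluster[c][m.module_id],
                                                       cfg.substitution_rate_within_cluster),
                                           m.strand, m.product))
            for m in cluster_cores[c]:
                module_list.append(_Module(m.module_id,
                                           _mutate_orf(rng, m.sequence,
                                                       cfg.substitution_rate_within_cluster),
                                           m.strand, m.product))
            private = _draw_modules(rng, int(cfg.private_fraction * L), cfg, f"{gid}_pv")
            module_list.extend(private)
            for m in backbone[half:]:
                module_list.append(_Module(m.module_id,
                                           _mutate_orf(rng, backbone_by_cluster[c][m.module_id],
                                                       cfg.substitution_rate_within_cluster),
                                           m.strand, m.product))

            record, layout, att_info = _assemble_genome(
                gid, module_list, att_cores[c], overhang, rng, cfg)
            genomes.append(record)
            truth.layouts[gid] = layout
            truth.att[gid] = att_info
            truth.cos[gid] = {
                "left_end": 1,
                "right_end": record.length_bp,
                "minus_peak": record.length_bp - len(overhang),
                "overhang_sequence": overhang,
                "overhang_length": len(overhang),
                "polarity": "3prime",
            }
            genome_modules[gid] = {e["module_id"]: e["stop"] - e["start"] + 1 for e in layout}
            for e in layout:
                truth.pham_truth[f"{gid}_{e['gene_number']}"] = e["module_id"]
            if cfg.twin_pair and c == cfg.n_clusters - 1 and g == 0:
                twin_source = (gid, c)

    # expected pairwise coverage from the module truth table
    ids = [g.id for g in genomes]
    by_id = {g.id: g for g in genomes}
    for i, ga in enumerate(ids):
        for gb in ids[i + 1 :]:
            shared = set(genome_modules[ga]) & set(genome_modules[gb])
            shared_bp = sum(genome_modules[ga][m] for m in shared)
            shorter = min(by_id[ga].length_bp, by_id[gb].length_bp)
            if truth.twin_pair and {ga, gb} == set(truth.twin_pair):
                # twins are identical end to end (spacers included), not just
                # over coding modules
                shared_bp, coverage = shorter, 100.0
            else:
                coverage = 100.0 * shared_bp / shorter
            truth.expected_pairs[f"{ga}|{gb}"] = {
                "shared_modules": sorted(shared),
                "shared_bp": shared_bp,
                "expected_coverage_percent": coverage,
                "same_cluster": truth.cluster_labels[ga] == truth.cluster_labels[gb],
            }

    _verify_cohort_truth(genomes, truth)
    return genomes, truth


def _make_twin(gid: str, source_id: str, genomes: list[GenomeRecord], truth: ForgeTruth,
               genome_modules: dict[str, dict[str, int]], rng: np.random.Generator,
               cfg: ForgeConfig) -> None:
    """Emit ``gid`` as a copy of ``source_id`` with exactly ``twin_snps``
    substitutions planted in intergenic spacers (keeping the SNP-count truth
    exact and every CDS intact)."""
    src = next(g for g in genomes if g.id == source_id)
    layout = truth.layouts[source_id]
    gene_mask = np.zeros(src.length_bp, dtype=bool)
    for e in layout:
        gene_mask[e["start"] - 1 : e["stop"]] = True
    att = truth.att[source_id]
    gene_mask[att["attP_start"] - 1 : att["attP_end"]] = True
    gene_mask[src.length_bp - cfg.cos_overhang_length :] = True
    spacer_pos = np.nonzero(~gene_mask)[0]
    chosen = rng.choice(spacer_pos, size=cfg.twin_snps, replace=False)
    arr = list(src.sequence)
    for pos in sorted(int(p) for p in chosen):
        arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
    seq = "".join(arr)
    genes = [GeneFeature(g.gene_number, g.start, g.stop, g.strand, g.product,
                         g.translation, g.kind) for g in src.genes]
    genomes.append(GenomeRecord(id=gid, sequence=seq, genes=genes, source="synthetic",
                                description=f"synthetic twin of {source_id}"))
    truth.layouts[gid] = [dict(e) for e in layout]
    truth.att[gid] = dict(att)
    truth.cos[gid] = dict(truth.cos[source_id])
    truth.twin_pair = (source_id, gid)
    genome_modules[gid] = dict(genome_modules[source_id])
    for e in layout:
        truth.pham_truth[f"{gid}_{e['gene_number']}"] = e["module_id"]


def _assemble_genome(gid: str, modules: list[_Module], att_core: str, overhang: str,
                     rng: np.random.Generator, cfg: ForgeConfig
                     ) -> tuple[GenomeRecord, list[dict], dict]:
    parts: list[str] = []
    genes: list[GeneFeature] = []
    layout: list[dict] = []
    att_info: dict = {}
    pos = 0
    lo, hi = cfg.spacer_length_range

    def add_spacer(length: int | None = None, with_core: bool = False) -> None:
        nonlocal pos
        n = int(rng.integers(lo, hi + 1)) if length is None else length
        spacer = _random_dna(rng, n, cfg.gc_target)
        if with_core:
            # plant the attP common core in the middle of this spacer
            pad = (n - len(att_core)) // 2
            spacer = spacer[:pad] + att_core + spacer[pad + len(att_core):]
            att_info["attP_start"] = pos + pad + 1
            att_info["attP_end"] = pos + pad + len(att_core)
            att_info["core_sequence"] = att_core
        parts.append(spacer)
        pos += n

    add_spacer()
    for i, m in enumerate(modules):
        if m.product == "tyrosine integrase":
            # attP core sits upstream of the integrase start (plus strand)
            add_spacer(length=max(len(att_core) + 60, hi), with_core=True)
        seq = m.sequence if m.strand == "+" else revcomp(m.sequence)
        start, stop = pos + 1, pos + len(seq)
        parts.append(seq)
        pos = stop
        number = str(i + 1)
        genes.append(GeneFeature(gene_number=number, start=start, stop=stop,
                                 strand=m.strand, product=m.product,
                                 translation=translate_cds(m.sequence)))
        layout.append({"module_id": m.module_id, "gene_number": number,
                       "start": start, "stop": stop, "strand": m.strand,
                       "product": m.product})
        add_spacer()
    # terminal spacer carries the 3' cohesive-end sequence at the very end
    tail = _random_dna(rng, max(hi, len(overhang) + 10), cfg.gc_target)
    parts.append(tail[: len(tail) - len(overhang)] + overhang)
    sequence = "".join(parts)
    record = GenomeRecord(id=gid, sequence=sequence, genes=genes, source="synthetic",
                          description="synthetic phage genome")
    return record, layout, att_info


def _verify_cohort_truth(genomes: list[GenomeRecord], truth: ForgeTruth) -> None:
    """Internal consistency of emitted truth vs emitted sequences."""
    by_id = {g.id: g for g in genomes}
    for gid, att in truth.att.items():
        g = by_id[gid]
        if g.subseq(att["attP_start"], att["attP_end"]) != att["core_sequence"]:
            raise AssertionError(f"{gid}: attP core not at stated coordinates")
    for gid, cos in truth.cos.items():
        g = by_id[gid]
        o = cos["overhang_length"]
        if g.sequence[-o:] != cos["overhang_sequence"]:
            raise AssertionError(f"{gid}: cos overhang not at genome end")
    for gid, layout in truth.layouts.items():
        g = by_id[gid]
        for e in layout:
            sub = g.subseq(e["start"], e["stop"])
            if e["strand"] == "-":
                sub = revcomp(sub)
            translate_cds(sub)  # raises if any CDS was corrupted


# ---------------------------------------------------------------------------
# host + prophage
# ---------------------------------------------------------------------------

def forge_host(config: ForgeConfig, donor_phages: Sequence[GenomeRecord],
               cohort_truth: ForgeTruth, with_prophage: bool = True,
               ) -> tuple[list[GenomeRecord], ForgeTruth]:
    """Generate a host genome with a tRNA-overlapping attB and (optionally) an
    integrated chimeric prophage split across two overlapping contigs.

    ``donor_phages`` must come from :func:`forge_cohort` (their module
    layouts are read from ``cohort_truth``).  With a prophage, the first
    donor contributes every gene left of the tape-measure module and the
    second donor the tape-measure module and everything right of it; the
    split into contigs falls at ``config.prophage_split_at`` (default: the
    middle of the tape-measure gene), with ``config.contig_overlap`` bases
    duplicated in both contigs.  Without a prophage the host carries only
    the attB site and tRNA.
    """
    if not donor_phages:
        raise ValueError("forge_host requires at least one donor phage")
    rng = np.random.default_rng(config.seed + 101)
    donor_a = donor_phages[0]
    att_core = cohort_truth.att[donor_a.id]["core_sequence"]

    truth = ForgeTruth()
    bg = _random_dna(rng, config.host_length, config.host_gc)
    att_a = cohort_truth.att[donor_a.id]
    # bases flanking the attP core on the donor phage; the corresponding host
    # flanks are forced to differ so the common core is exactly the planted
    # core and never extends by a chance flanking match
    donor_before = donor_a.sequence[att_a["attP_start"] - 2]
    donor_after = donor_a.sequence[att_a["attP_end"]]

    def _differing(base: str) -> str:
        return str(rng.choice([b for b in "ACGT" if b != base]))

    # attB position: middle of the host, tRNA overlapping the core's left edge
    attb_pos = config.host_length // 2
    trna_start = attb_pos - (config.trna_length - config.attb_trna_overlap)
    trna = GeneFeature(gene_number="trna1", start=trna_start,
                       stop=trna_start + config.trna_length - 1, strand="+",
                       product="tRNA-Pro", kind="tRNA")

    if not with_prophage:
        bg = (bg[: attb_pos - 2] + _differing(donor_before) + att_core
              + _differing(donor_after) + bg[attb_pos + len(att_core):])
        seq = bg
        host = GenomeRecord(id="host_c1", sequence=seq, genes=[trna], source="synthetic",
                            description="synthetic host, vacant attB")
        truth.host = {
            "attB_start": attb_pos, "attB_end": attb_pos + len(att_core) - 1,
            "core_sequence": att_core, "trna": {"start": trna.start, "stop": trna.stop},
            "prophage": None,
        }
        _verify_host_truth([host], truth)
        return [host], truth

    if len(donor_phages) < 2:
        raise ValueError("a chimeric prophage needs two donor phages")
    donor_b = donor_phages[1]
    body, body_genes, provenance, split_phage_coord = _build_prophage_body(
        donor_a, donor_b, cohort_truth, rng, config)

    left = bg[: attb_pos - 1]
    after_attr = bg[attb_pos - 1]
    # force mismatching flanks at both att junctions: the direct repeat shared
    # by the attL and attR neighbourhoods is then exactly the planted core
    before_l = next(b for b in "GATC" if b not in (body[-1], donor_before))
    left = left[:-1] + before_l
    first = next(b for b in "GATC" if b not in (after_attr, donor_after))
    body = first + body[1:]
    attl_start = attb_pos
    attl_end = attl_start + len(att_core) - 1
    body_offset = attl_end  # body starts at attl_end + 1
    attr_start = body_offset + len(body) + 1
    attr_end = attr_start + len(att_core) - 1
    seq = left + att_core + body + att_core + bg[attb_pos - 1:]

    genes = [trna]
    gene_map: list[dict] = []
    for gf, prov in zip(body_genes, provenance):
        shifted = GeneFeature(gf.gene_number, gf.start + body_offset, gf.stop + body_offset,
                              gf.strand, gf.product, gf.translation, gf.kind)
        genes.append(shifted)
        gene_map.append({**prov, "start": shifted.start, "stop": shifted.stop})

    split_host = body_offset + split_phage_coord
    if abs(split_host - attl_end) < config.contig_overlap or \
       abs(attr_start - split_host) < config.contig_overlap:
        raise ValueError("prophage split point collides with an att junction")

    c1_end = split_host + config.contig_overlap // 2
    c2_start = split_host - config.contig_overlap // 2
    contig1 = GenomeRecord(
        id="host_c1", sequence=seq[:c1_end],
        genes=[g for g in genes if g.stop <= c1_end],
        source="synthetic", description="synthetic host contig 1 (attL side)")
    contig2_genes = []
    for g in genes:
        if g.start > c2_start:
            contig2_genes.append(GeneFeature(g.gene_number, g.start - c2_start,
                                             g.stop - c2_start, g.strand, g.product,
                                             g.translation, g.kind))
    contig2 = GenomeRecord(id="host_c17", sequence=seq[c2_start:], genes=contig2_genes,
                           source="synthetic", description="synthetic host contig 2 (attR side)")

    truth.host = {
        "attL": {"contig": "host_c1", "start": attl_start, "end": attl_end},
        "attR": {"contig": "host_c17", "start": attr_start - c2_start,
                 "end": attr_end - c2_start},
        "core_sequence": att_core,
        "trna": {"start": trna.start, "stop": trna.stop},
        "prophage": {
            "donors": [donor_a.id, donor_b.id],
            "split_phage_coord": split_phage_coord,
            "split_host_coord": split_host,
            "contig_overlap": config.contig_overlap,
            "genes": gene_map,
        },
    }
    _verify_host_truth([contig1, contig2], truth)
    return [contig1, contig2], truth


def _build_prophage_body(donor_a: GenomeRecord, donor_b: GenomeRecord,
                         truth: ForgeTruth, rng: np.random.Generator,
                         cfg: ForgeConfig) -> tuple[str, list[GeneFeature], list[dict], int]:
    """Chimeric prophage: donor A's shared modules left of the tape measure,
    donor B's from the tape measure rightwards.  Returns (sequence, genes in
    body coordinates, per-gene provenance, split coordinate in body)."""
    layout_a = truth.layouts[donor_a.id]
    layout_b = truth.layouts[donor_b.id]
    shared_ids = {e["module_id"] for e in layout_a} & {e["module_id"] for e in layout_b}
    plan: list[tuple[GenomeRecord, dict]] = []
    for e in layout_a:
        if e["product"] == "tape measure protein":
            break
        if e["module_id"] in shared_ids or e["module_id"].startswith(f"{donor_a.id}_pv"):
            plan.append((donor_a, e))
    seen_tmp = False
    for e in layout_b:
        if e["product"] == "tape measure protein":
            seen_tmp = True
        if not seen_tmp:
            continue
        if e["module_id"] in shared_ids or e["module_id"].startswith(f"{donor_b.id}_pv"):
            plan.append((donor_b, e))

    lo, hi = cfg.spacer_length_range
    parts: list[str] = []
    genes: list[GeneFeature] = []
    provenance: list[dict] = []
    pos = 0
    tmp_middle = 0
    for k, (donor, e) in enumerate(plan):
        spacer = _random_dna(rng, int(rng.integers(lo, hi + 1)), cfg.gc_target)
        parts.append(spacer)
        pos += len(spacer)
        seg = donor.subseq(e["start"], e["stop"])
        start, stop = pos + 1, pos + len(seg)
        parts.append(seg)
        pos = stop
        number = f"{(len(plan) - k) * 5:05d}"   # descending locus-tag style labels
        coding = seg if e["strand"] == "+" else revcomp(seg)
        genes.append(GeneFeature(gene_number=number, start=start, stop=stop,
                                 strand=e["strand"], product=e["product"],
                                 translation=translate_cds(coding)))
        provenance.append({"gene_number": number, "module_id": e["module_id"],
                           "donor": donor.id, "donor_gene": e["gene_number"],
                           "product": e["product"]})
        if e["product"] == "tape measure protein":
            tmp_middle = (start + stop) // 2
    parts.append(_random_dna(rng, int(rng.integers(lo, hi + 1)), cfg.gc_target))
    split = cfg.prophage_split_at if cfg.prophage_split_at is not None else tmp_middle
    return "".join(parts), genes, provenance, split


def _verify_host_truth(contigs: list[GenomeRecord], truth: ForgeTruth) -> None:
    by_id = {c.id: c for c in contigs}
    host = truth.host
    core = host["core_sequence"]
    if host.get("prophage") is None:
        c = contigs[0]
        if c.subseq(host["attB_start"], host["attB_end"]) != core:
            raise AssertionError("attB core not at stated coordinates")
        return
    for key in ("attL", "attR"):
        site = host[key]
        c = by_id[site["contig"]]
        if c.subseq(site["start"], site["end"]) != core:
            raise AssertionError(f"{key} core not at stated coordinates")


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_cos_reads(genome: GenomeRecord, depth: float = 200.0, read_length: int = 150,
                       seed: int = 7, overhang_length: int = 12) -> ReadStartProfile:
    """Simulate a read-start profile for a linear cos genome.

    The model: virion molecules are linear; interior fragment starts are
    uniform over each strand, while every molecule also contributes a read
    beginning exactly at each strand's 5' terminus (the read-start pileup).
    The top strand spans the whole sequence ``1..L``; the bottom strand
    spans ``1..L-overhang``, so total coverage over the 3' overhang is
    roughly halved.  ``overhang_length = 0`` simulates blunt ends.
    Deterministic under ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    L = genome.length_bp
    if read_length >= L:
        raise ValueError("read length must be smaller than the genome")
    o = overhang_length
    rng = np.random.default_rng(seed)
    n_molecules = max(int(round(depth)), 1)
    n_interior = max(int(round(depth * L / (2 * read_length))), 1)

    plus = np.zeros(L, dtype=np.int64)
    minus = np.zeros(L, dtype=np.int64)
    cover = np.zeros(L + 1, dtype=np.int64)

    # plus strand: 5' terminus at position 1 (0-based 0)
    plus_starts = np.concatenate([
        np.zeros(n_molecules, dtype=np.int64),
        rng.integers(0, L - read_length + 1, size=n_interior),
    ])
    np.add.at(plus, plus_starts, 1)
    np.add.at(cover, plus_starts, 1)
    np.add.at(cover, plus_starts + read_length, -1)

    # minus strand: bottom strand spans 1..L-o, its 5' terminus at L-o
    bot_hi = L - o  # 1-based 5' end of the bottom strand
    minus_ends = np.concatenate([
        np.full(n_molecules, bot_hi - 1, dtype=np.int64),
        rng.integers(read_length - 1, bot_hi, size=n_interior),
    ])
    np.add.at(minus, minus_ends, 1)
    np.add.at(cover, minus_ends - read_length + 1, 1)
    np.add.at(cover, minus_ends + 1, -1)

    depth_arr = np.cumsum(cover[:-1])
    return ReadStartProfile(genome_id=genome.id, plus_starts=plus, minus_starts=minus,
                            depth=depth_arr)
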