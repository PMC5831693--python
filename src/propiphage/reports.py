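"""Pipeline orchestration, figure/table export and gene-content phylogenetics.

Every figure artifact has a machine-readable TSV/JSON twin; the heat map
and dotplots are rendered with matplotlib, the gene-content tree is a
neighbour-joining tree over ``1 - shared-gene-proportion`` distances, and a
Nexus DISTANCES block is exported so the network (NeighborNet) view can be
rendered externally with SplitsTree — the shared-gene computation is ours,
the network-drawing algorithm is not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from io import StringIO
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from propiphage import attscan, nuccomp, phams, termini
from propiphage.core_io import GenomeRecord, read_genbank
from propiphage.phams import SharedGeneMatrix


@dataclass
class PipelineConfig:
    """Serializable configuration for a full pipeline run."""

    genome_paths: list[str] = field(default_factory=list)
    out_dir: str = "propiphage_out"
    seed: int = 1
    word_nuc: int = 11
    evalue_max: float = 1e-5
    dotplot_word: int = 10
    pham_identity_threshold: float = 32.5
    pham_coverage_threshold: float = 50.0
    cluster_span_threshold: float = 50.0
    cluster_identity_threshold: float = 80.0
    att_window: int = 500
    att_min_core: int = 20
    make_plots: bool = True


def gene_content_distance(matrix: SharedGeneMatrix) -> dict:
    """Distances ``1 - shared fraction``, an NJ tree (Newick) and a Nexus
    DISTANCES block for external SplitsTree rendering."""
    values = np.asarray(matrix.values, dtype=float)
    if not np.allclose(values, values.T):
        raise ValueError("shared-gene matrix must be symmetric")
    dist = 1.0 - values
    np.fill_diagonal(dist, 0.0)
    dm = DistanceMatrix(dist, ids=matrix.ids)
    newick = ""
    if len(matrix.ids) >= 3:
        tree = nj(dm)
        buf = StringIO()
        tree.write(buf, format="newick")
        newick = buf.getvalue().strip()
    return {"ids": list(matrix.ids), "distances": dist,
            "newick": newick, "nexus": nexus_distances(matrix.ids, dist)}


def nexus_distances(ids: Sequence[str], dist: np.ndarray) -> str:
    """A Nexus file with TAXA and DISTANCES blocks (SplitsTree input)."""
    n = len(ids)
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"    DIMENSIONS NTAX={n};",
             "    TAXLABELS " + " ".join(ids) + ";", "END;", "",
             "BEGIN DISTANCES;", f"    DIMENSIONS NTAX={n};",
             "    FORMAT TRIANGLE=BOTH DIAGONAL LABELS;", "    MATRIX"]
    for i, gid in enumerate(ids):
        row = " ".join(f"{dist[i, j]:.6f}" for j in range(n))
        lines.append(f"        {gid} {row}")
    lines += ["    ;", "END;", ""]
    return "\n".join(lines)


def genome_map(genomes: Sequence[GenomeRecord], pham_list: Sequence[phams.Pham],
               pair_hsps: dict[tuple[str, str], list[nuccomp.HSP]] | None = None) -> dict:
    """Structured genome-map document: per-genome gene tracks with pham
    labels (rightwards genes above the baseline, leftwards below) and
    pairwise similarity shading segments between consecutive genomes."""
    table = phams.pham_table(pham_list)
    sizes = {p.pham_id: p.size for p in pham_list}
    tracks = []
    for g in genomes:
        boxes = []
        for gene in g.genes:
            if gene.kind != "CDS":
                continue
            pid = table.get(f"{g.id}_{gene.gene_number}")
            boxes.append({
                "gene_number": gene.gene_number,
                "start": gene.start,
                "stop": gene.stop,
                "strand": gene.strand,
                "row": "above" if gene.strand == "+" else "below",
                "product": gene.product,
                "pham_id": pid,
                "pham_size": sizes.get(pid),
            })
        tracks.append({"genome_id": g.id, "length_bp": g.length_bp, "genes": boxes})
    shading = []
    if pair_hsps:
        for (ga, gb), hsps in pair_hsps.items():
            for h in hsps:
                shading.append({
                    "genome_a": ga, "genome_b": gb,
                    "a_start": h.a_start, "a_end": h.a_end,
                    "b_start": h.b_start, "b_end": h.b_end,
                    "strand": h.strand, "identity_percent": round(h.identity_percent, 2),
                    "e_value": h.e_value,
                })
    return {"tracks": tracks, "shading": shading}


def _plot_dotplot(match: nuccomp.DotplotMatch, ga: str, gb: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    fwd = [(a, b) for a, b, s in match.matches if s == "+"]
    rev = [(a, b) for a, b, s in match.matches if s == "-"]
    if fwd:
        xs, ys = zip(*fwd)
        ax.plot(xs, ys, ".", ms=0.5, color="black")
    if rev:
        xs, ys = zip(*rev)
        ax.plot(xs, ys, ".", ms=0.5, color="red")
    ax.set_xlabel(ga)
    ax.set_ylabel(gb)
    ax.set_title(f"word={match.word_length}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_heatmap(matrix: SharedGeneMatrix, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix.values, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(matrix.ids)), matrix.ids, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.ids)), matrix.ids, fontsize=7)
    fig.colorbar(im, label="shared gene proportion")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: PipelineConfig,
                 genomes: Sequence[GenomeRecord] | None = None,
                 profiles: Sequence | None = None,
                 host_contigs: Sequence[GenomeRecord] | None = None) -> dict:
    """Run the comparative pipeline and write the report bundle.

    Emits: pairwise identity/coverage TSV, cluster table TSV, pham table,
    shared-gene matrix TSV (+ heat map PNG), Nexus distance block, Newick NJ
    tree, dotplot TSVs (+ PNGs), genome-map JSON, optional terminus JSON
    (when read profiles are given) and att/prophage JSON (when host contigs
    are given).  Any stage failure aborts with the stage name and input ids.
    """
    if genomes is None:
        genomes = [read_genbank(p) for p in config.genome_paths]
    genomes = list(genomes)
    if len(genomes) < 2:
        raise ValueError(">=2 genomes required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"out_dir": str(out)}
    log: dict = {"seed": config.seed, "thresholds": asdict(config),
                 "genomes": [g.id for g in genomes]}

    def stage(name: str):
        log.setdefault("stages", []).append(name)

    try:
        stage("pairwise_nucleotide")
        summaries = []
        pair_hsps: dict[tuple[str, str], list[nuccomp.HSP]] = {}
        for i, a in enumerate(genomes):
            for b in genomes[i + 1 :]:
                s = nuccomp.summarize_pair(a, b, word=config.word_nuc,
                                           evalue_max=config.evalue_max)
                summaries.append(s)
                pair_hsps[(a.id, b.id)] = s.hsps
        nuccomp.write_summary_table(summaries, out / "pairwise_identity.tsv")
        bundle["summaries"] = summaries
    except Exception as exc:
        raise RuntimeError(f"stage pairwise_nucleotide failed for {[g.id for g in genomes]}: {exc}") from exc

    try:
        stage("clustering")
        assignment = nuccomp.assign_clusters(summaries, config.cluster_span_threshold,
                                             config.cluster_identity_threshold)
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("genome\tcluster\n")
            for g, lab in sorted(assignment.labels.items()):
                fh.write(f"{g}\t{lab}\n")
        bundle["clusters"] = assignment
    except Exception as exc:
        raise RuntimeError(f"stage clustering failed: {exc}") from exc

    try:
        stage("phams")
        proteins, genome_of = phams.proteins_from_genomes(genomes)
        pham_list = phams.build_phams(proteins, config.pham_identity_threshold,
                                      config.pham_coverage_threshold)
        phams.write_pham_table(pham_list, out / "phams.tsv")
        matrix = phams.shared_gene_matrix([g.id for g in genomes], pham_list, genome_of)
        matrix.to_tsv(out / "shared_gene_matrix.tsv")
        bundle["phams"] = pham_list
        bundle["shared_gene_matrix"] = matrix
        if config.make_plots:
            _plot_heatmap(matrix, out / "shared_gene_heatmap.png")
    except Exception as exc:
        raise RuntimeError(f"stage phams failed: {exc}") from exc

    try:
        stage("gene_content_tree")
        gcd = gene_content_distance(matrix)
        (out / "gene_content.nex").write_text(gcd["nexus"])
        (out / "gene_content_nj.nwk").write_text(gcd["newick"] + "\n")
        bundle["gene_content"] = gcd
    except Exception as exc:
        raise RuntimeError(f"stage gene_content_tree failed: {exc}") from exc

    try:
        stage("dotplots")
        for i, a in enumerate(genomes):
            for b in genomes[i + 1 :]:
                match = nuccomp.dotplot(a, b, word=config.dotplot_word, max_points=200_000)
                tsv = out / f"dotplot_{a.id}_{b.id}.tsv"
                with open(tsv, "w") as fh:
                    fh.write("a_pos\tb_pos\tstrand\n")
                    for ap, bp_, st in match.matches:
                        fh.write(f"{ap}\t{bp_}\t{st}\n")
                if config.make_plots:
                    _plot_dotplot(match, a.id, b.id, out / f"dotplot_{a.id}_{b.id}.png")
    except Exception as exc:
        raise RuntimeError(f"stage dotplots failed: {exc}") from exc

    try:
        stage("genome_map")
        gmap = genome_map(genomes, pham_list, pair_hsps)
        with open(out / "genome_map.json", "w") as fh:
            json.dump(gmap, fh, indent=2)
        bundle["genome_map"] = gmap
    except Exception as exc:
        raise RuntimeError(f"stage genome_map failed: {exc}") from exc

    if profiles:
        try:
            stage("termini")
            by_id = {g.id: g for g in genomes}
            calls = {}
            for profile in profiles:
                call = termini.detect_cos_ends(profile, genome=by_id.get(profile.genome_id))
                calls[profile.genome_id] = call
                call.to_json(out / f"terminus_{profile.genome_id}.json")
            bundle["termini"] = calls
        except Exception as exc:
            raise RuntimeError(f"stage termini failed: {exc}") from exc

    if host_contigs:
        try:
            stage("attscan")
            att_sites = {}
            for g in genomes:
                integrases = [gene for gene in g.genes if "integrase" in gene.product.lower()]
                for contig in host_contigs:
                    for integrase in integrases:
                        site = attscan.find_att_core(g, integrase, contig,
                                                     window=config.att_window,
                                                     min_core=config.att_min_core)
                        if site is not None:
                            site.overlapping_trna = attscan.trna_overlap(site, contig.genes)
                            att_sites[f"{g.id}|{contig.id}"] = site
                            site.to_json(out / f"attsite_{g.id}_{contig.id}.json")
            bundle["att_sites"] = att_sites
            stage("prophages")
            calls = attscan.scan_prophages(host_contigs, genomes)
            for k, call in enumerate(calls):
                call.to_json(out / f"prophage_{k + 1}.json")
                call.to_bed(out / f"prophage_{k + 1}.bed")
                attscan.prophage_gff3(call, out / f"prophage_{k + 1}.gff3")
            bundle["prophages"] = calls
        except Exception as exc:
            raise RuntimeError(f"stage attscan/prophages failed: {exc}") from exc

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    bundle["log"] = log
    return bundle
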