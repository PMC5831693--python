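"""attP/attB common-core discovery and mosaic prophage reconstruction.

Site-specific integration by a tyrosine integrase requires a short region
of sequence identity (the *common core*) shared between the phage
attachment site (attP, typically just upstream of the integrase gene) and
the bacterial attachment site (attB, frequently overlapping a tRNA gene).
After integration the core is duplicated as a direct repeat flanking the
prophage (attL and attR).

Core discovery is an exact longest-common-substring problem: the window
upstream of the integrase is matched against both strands of the host
genome with a suffix automaton (linear time in the window, streaming over
the host).  The default minimum core of 20 bp suppresses chance matches:
the expected longest chance common substring between a 500 bp window and a
host of length ``n`` is about ``log4(500 * n) + O(1)``, i.e. ~15-16 bp for
a 2.6 Mb genome, so 20 bp sits comfortably above the noise floor while
remaining below the ~45-50 bp cores of real integration systems.

Prophage reconstruction chains nucleotide HSPs of a phage panel against
host contigs, joins split prophages across contig boundaries keyed on
phage-coordinate adjacency, locates the attL/attR direct repeat as the
longest common substring of the two junction neighbourhoods, and assigns
per-gene provenance by best protein identity against the panel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from propiphage.core_io import GeneFeature, GenomeRecord, revcomp
from propiphage.nuccomp import HSP, seed_extend_align
from propiphage.phams import ProteinEntry, align_protein_pair


# ---------------------------------------------------------------------------
# longest common substring via suffix automaton
# ---------------------------------------------------------------------------

class SuffixAutomaton:
    """Suffix automaton of a (short) pattern string; supports streaming a
    long text to find the longest substring common to both."""

    __slots__ = ("next", "link", "length")

    def __init__(self, s: str):
        self.next: list[dict[str, int]] = [{}]
        self.link: list[int] = [-1]
        self.length: list[int] = [0]
        last = 0
        for ch in s:
            cur = len(self.next)
            self.next.append({})
            self.link.append(-2)
            self.length.append(self.length[last] + 1)
            p = last
            while p != -1 and ch not in self.next[p]:
                self.next[p][ch] = cur
                p = self.link[p]
            if p == -1:
                self.link[cur] = 0
            else:
                q = self.next[p][ch]
                if self.length[p] + 1 == self.length[q]:
                    self.link[cur] = q
                else:
                    clone = len(self.next)
                    self.next.append(dict(self.next[q]))
                    self.link.append(self.link[q])
                    self.length.append(self.length[p] + 1)
                    while p != -1 and self.next[p].get(ch) == q:
                        self.next[p][ch] = clone
                        p = self.link[p]
                    self.link[q] = clone
                    self.link[cur] = clone
            last = cur

    def longest_common_with(self, text: str) -> tuple[int, int]:
        """(length, 0-based end index in ``text``) of the longest substring of
        ``text`` that is also a substring of the automaton's pattern."""
        v, length = 0, 0
        best, best_end = 0, -1
        for i, ch in enumerate(text):
            while v and ch not in self.next[v]:
                v = self.link[v]
                length = self.length[v]
            if ch in self.next[v]:
                v = self.next[v][ch]
                length += 1
            else:
                v, length = 0, 0
            if length > best:
                best, best_end = length, i
        return best, best_end


def longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    """(length, 0-based end in a, 0-based end in b) of the longest common
    substring; ends refer to the first maximal occurrence found in ``b``."""
    sam = SuffixAutomaton(a)
    length, b_end = sam.longest_common_with(b)
    if length == 0:
        return 0, -1, -1
    sub = b[b_end - length + 1 : b_end + 1]
    a_end = a.find(sub) + length - 1
    return length, a_end, b_end


# ---------------------------------------------------------------------------
# att sites
# ---------------------------------------------------------------------------

@dataclass
class AttSite:
    """attP/attB common core: identical subsequences on phage and host."""

    core_length: int
    core_sequence: str
    attP_start: int
    attP_end: int
    attB_start: int
    attB_end: int
    host_strand: str = "+"
    overlapping_trna: str | None = None

    def __post_init__(self) -> None:
        if self.core_length != len(self.core_sequence):
            raise ValueError("core_length must equal len(core_sequence)")
        for s, e in ((self.attP_start, self.attP_end), (self.attB_start, self.attB_end)):
            if e - s + 1 != self.core_length:
                raise ValueError("att coordinates inconsistent with core length")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _upstream_window(phage: GenomeRecord, integrase: GeneFeature,
                     window: int) -> tuple[str, int]:
    """Plus-strand slice of the strand-aware upstream window and its 1-based
    start coordinate; truncated (with a warning) at genome ends."""
    if integrase.strand == "+":
        start = integrase.start - window
        stop = integrase.start - 1
    else:
        start = integrase.stop + 1
        stop = integrase.stop + window
    if start < 1 or stop > phage.length_bp:
        warnings.warn(
            f"{phage.id}: upstream window of gene {integrase.gene_number} truncated "
            f"at the genome end", stacklevel=2)
        start = max(start, 1)
        stop = min(stop, phage.length_bp)
    if start > stop:
        raise ValueError("integrase has no upstream sequence inside the genome")
    return phage.subseq(start, stop), start


def find_att_core(phage: GenomeRecord, integrase: GeneFeature, host: GenomeRecord,
                  window: int = 500, min_core: int = 20) -> AttSite | None:
    """Longest exact common substring between the integrase upstream window
    and the host genome (both strands); the attP/attB common core.

    Returns ``None`` when no common substring reaches ``min_core``.  Among
    equally long cores the one closest to the integrase start is taken.
    """
    if not (1 <= integrase.start and integrase.stop <= phage.length_bp):
        raise ValueError("integrase feature does not lie on the phage genome")
    win, win_start = _upstream_window(phage, integrase, window)

    best: tuple[int, int, int, str] | None = None  # (length, win_end0, host_end0, strand)
    for strand, text in (("+", host.sequence), ("-", revcomp(host.sequence))):
        sam = SuffixAutomaton(win)
        length, host_end = sam.longest_common_with(text)
        if length >= min_core and (best is None or length > best[0]):
            sub = text[host_end - length + 1 : host_end + 1]
            # tie-break within the window: occurrence closest to the integrase
            positions = _all_occurrences(win, sub)
            win_end0 = _closest_to_gene(positions, length, win_start, integrase)
            best = (length, win_end0, host_end, strand)
    if best is None:
        return None
    length, win_end0, host_end0, strand = best
    core = win[win_end0 - length + 1 : win_end0 + 1]
    attp_start = win_start + win_end0 - length + 1
    if strand == "+":
        attb_start = host_end0 - length + 2  # 1-based
    else:
        attb_start = host.length_bp - host_end0  # map from revcomp coords
    site = AttSite(core_length=length, core_sequence=core,
                   attP_start=attp_start, attP_end=attp_start + length - 1,
                   attB_start=attb_start, attB_end=attb_start + length - 1,
                   host_strand=strand)
    host_sub = host.subseq(site.attB_start, site.attB_end)
    if strand == "-":
        host_sub = revcomp(host_sub)
    assert host_sub == core, "att core mismatch between phage and host coordinates"
    return site


def _all_occurrences(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _closest_to_gene(starts0: Sequence[int], length: int, win_start: int,
                     gene: GeneFeature) -> int:
    def distance(s0: int) -> int:
        lo = win_start + s0
        hi = lo + length - 1
        if hi < gene.start:
            return gene.start - hi
        if lo > gene.stop:
            return lo - gene.stop
        return 0
    best = min(starts0, key=distance)
    return best + length - 1


def trna_overlap(att: AttSite, host_features: Iterable[GeneFeature]) -> str | None:
    """First tRNA feature whose span intersects the attB core by >= 1 bp
    (inclusive-overlap rule: sharing a single terminal base counts)."""
    for feat in host_features:
        if feat.kind != "tRNA" and "tRNA" not in feat.product:
            continue
        if feat.start <= att.attB_end and feat.stop >= att.attB_start:
            return feat.gene_number
    return None


# ---------------------------------------------------------------------------
# prophage reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ProphageSegment:
    contig_id: str
    start: int
    end: int


@dataclass
class ProphageCall:
    """A reconstructed (possibly split-contig) prophage with per-gene provenance."""

    segments: list[ProphageSegment]
    attL: dict | None
    attR: dict | None
    best_phage: str
    genes: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"segments": [asdict(s) for s in self.segments],
                       "attL": self.attL, "attR": self.attR,
                       "best_phage": self.best_phage, "genes": self.genes}, fh, indent=2)

    def to_bed(self, path: str | Path) -> None:
        """BED of prophage segments and att cores (0-based half-open)."""
        with open(path, "w") as fh:
            for seg in self.segments:
                fh.write(f"{seg.contig_id}\t{seg.start - 1}\t{seg.end}\tprophage\n")
            for name, site in (("attL", self.attL), ("attR", self.attR)):
                if site:
                    fh.write(f"{site['contig']}\t{site['start'] - 1}\t{site['end']}\t{name}\n")


def _chain_intervals(intervals: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start - merged[-1][1] - 1 <= max_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _phage_projection(hsps: Sequence[HSP], lo: int, hi: int) -> tuple[int, int] | None:
    spans = [(h.a_start, h.a_end) for h in hsps
             if min(h.b_start, h.b_end) >= lo and max(h.b_start, h.b_end) <= hi]
    if not spans:
        return None
    return min(s for s, _ in spans), max(e for _, e in spans)


def scan_prophages(host_contigs: Sequence[GenomeRecord],
                   phage_panel: Sequence[GenomeRecord],
                   min_hit: int = 500, max_gap: int = 1500,
                   edge_tolerance: int = 200, junction_flank: int = 800,
                   min_core: int = 20,
                   panel_proteins: Sequence[ProteinEntry] | None = None,
                   ) -> list[ProphageCall]:
    """Detect integrated prophages on host contigs by similarity to a phage panel.

    HSPs of every panel phage against every contig are chained (gaps up to
    ``max_gap``, e.g. intergenic spacers) into candidate prophage regions.
    Regions that terminate within ``edge_tolerance`` of a contig end are
    joined across contigs when their phage-coordinate projections are
    adjacent or overlapping — the signature of one prophage split by the
    assembly.  The ``junction_flank`` neighbourhood is sized to reach past a
    terminal gene that fell below ``min_hit`` (plus a spacer), so the att
    repeat is still inside the searched windows.  The attL/attR direct repeat is recovered as the longest
    common substring of the two junction neighbourhoods (``junction_flank``
    around the outer region boundaries); per-gene provenance is assigned by
    best amino-acid identity against the panel proteins.

    Contigs with no hit of at least ``min_hit`` aligned bases yield no call.
    """
    if not host_contigs or not phage_panel:
        raise ValueError("need at least one contig and one panel phage")
    if panel_proteins is None:
        panel_proteins = [
            ProteinEntry(protein_id=f"{p.id}_{g.gene_number}", translation=g.translation,
                         genome_id=p.id)
            for p in phage_panel for g in p.genes if g.kind == "CDS" and g.translation
        ]

    per_contig: dict[str, dict] = {}
    for contig in host_contigs:
        all_hits: list[tuple[str, HSP]] = []
        for phage in phage_panel:
            for h in seed_extend_align(phage, contig):
                if h.alignment_length >= min_hit:
                    all_hits.append((phage.id, h))
        if not all_hits:
            continue
        intervals = [(min(h.b_start, h.b_end), max(h.b_start, h.b_end)) for _, h in all_hits]
        regions = _chain_intervals(intervals, max_gap)
        region = max(regions, key=lambda r: r[1] - r[0])  # dominant prophage region
        aligned_by_phage: dict[str, int] = {}
        for pid, h in all_hits:
            aligned_by_phage[pid] = aligned_by_phage.get(pid, 0) + h.alignment_length
        per_contig[contig.id] = {
            "contig": contig,
            "region": region,
            "hsps": all_hits,
            "aligned_by_phage": aligned_by_phage,
        }

    if not per_contig:
        return []

    # --- join split prophages across contig edges -------------------------
    entries = list(per_contig.values())
    used: set[str] = set()
    groups: list[list[dict]] = []
    for e in entries:
        cid = e["contig"].id
        if cid in used:
            continue
        lo, hi = e["region"]
        group = [e]
        used.add(cid)
        if hi >= e["contig"].length_bp - edge_tolerance:
            # region runs off the right end; look for a continuation contig
            best_pid = max(e["aligned_by_phage"], key=e["aligned_by_phage"].get)
            proj = _phage_projection([h for pid, h in e["hsps"] if pid == best_pid], lo, hi)
            for other in entries:
                ocid = other["contig"].id
                if ocid in used or other["region"][0] > edge_tolerance:
                    continue
                oproj = _phage_projection(
                    [h for pid, h in other["hsps"] if pid == best_pid], *other["region"])
                if proj and oproj and oproj[1] >= proj[0] and oproj[0] <= proj[1] + max_gap:
                    group.append(other)
                    used.add(ocid)
                    break
        groups.append(group)

    calls: list[ProphageCall] = []
    for group in groups:
        calls.append(_make_call(group, junction_flank, min_core, panel_proteins))
    return calls


def _make_call(group: list[dict], junction_flank: int, min_core: int,
               panel_proteins: Sequence[ProteinEntry]) -> ProphageCall:
    first, last = group[0], group[-1]
    c_first, c_last = first["contig"], last["contig"]
    lo_first = first["region"][0]
    hi_last = last["region"][1]

    # junction neighbourhoods around the outer boundaries
    lwin_start = max(1, lo_first - junction_flank)
    lwin = c_first.subseq(lwin_start, min(c_first.length_bp, lo_first + junction_flank))
    rwin_start = max(1, hi_last - junction_flank)
    rwin = c_last.subseq(rwin_start, min(c_last.length_bp, hi_last + junction_flank))
    length, l_end0, r_end0 = longest_common_substring(lwin, rwin)

    attL = attR = None
    seg_lo, seg_hi = lo_first, hi_last
    if length >= min_core:
        core = lwin[l_end0 - length + 1 : l_end0 + 1]
        l_start = lwin_start + l_end0 - length + 1
        r_start = rwin_start + r_end0 - length + 1
        attL = {"contig": c_first.id, "start": l_start, "end": l_start + length - 1,
                "core_sequence": core}
        attR = {"contig": c_last.id, "start": r_start, "end": r_start + length - 1,
                "core_sequence": core}
        seg_lo = attL["end"] + 1
        seg_hi = attR["start"] - 1

    segments = []
    for i, e in enumerate(group):
        lo, hi = e["region"]
        if i == 0:
            lo = seg_lo
        if i == len(group) - 1:
            hi = seg_hi
        else:
            hi = e["contig"].length_bp
        if i > 0:
            lo = 1
        segments.append(ProphageSegment(contig_id=e["contig"].id, start=lo, end=hi))

    totals: dict[str, int] = {}
    for e in group:
        for pid, n in e["aligned_by_phage"].items():
            totals[pid] = totals.get(pid, 0) + n
    best_phage = max(totals, key=totals.get)

    # genes inside the prophage segments, with provenance
    prophage_genes: list[tuple[str, GeneFeature]] = []
    for seg, e in zip(segments, group):
        for gene in e["contig"].genes:
            if gene.kind == "CDS" and gene.translation and \
               gene.start >= seg.start and gene.stop <= seg.end:
                prophage_genes.append((seg.contig_id, gene))
    provenance = gene_provenance(prophage_genes, panel_proteins)
    return ProphageCall(segments=segments, attL=attL, attR=attR,
                        best_phage=best_phage, genes=provenance)


def gene_provenance(prophage_genes: Sequence[tuple[str, GeneFeature]],
                    panel_proteins: Sequence[ProteinEntry],
                    prefilter_k: int = 6) -> list[dict]:
    """Best-matching panel protein for each prophage gene.

    Per gene the panel protein with maximal amino-acid identity is reported
    together with its source phage; equally good matches are listed under
    ``ties`` rather than broken silently.  An exact shared-k-mer prefilter
    narrows candidates; genes with no shared k-mer fall back to the full
    panel scan.
    """
    index: dict[str, set[int]] = {}
    for i, p in enumerate(panel_proteins):
        for j in range(len(p.translation) - prefilter_k + 1):
            index.setdefault(p.translation[j : j + prefilter_k], set()).add(i)

    table: list[dict] = []
    for contig_id, gene in prophage_genes:
        seq = gene.translation
        cand: set[int] = set()
        for j in range(len(seq) - prefilter_k + 1):
            cand |= index.get(seq[j : j + prefilter_k], set())
        if not cand:
            cand = set(range(len(panel_proteins)))
        scored: list[tuple[float, ProteinEntry]] = []
        for i in sorted(cand):
            p = panel_proteins[i]
            res = align_protein_pair(seq, p.translation)
            scored.append((res["identity_percent"], p))
        scored.sort(key=lambda t: (-t[0], t[1].protein_id))
        best_ident, best_prot = scored[0]
        ties = [p.protein_id for ident, p in scored[1:] if abs(ident - best_ident) < 1e-9]
        table.append({
            "contig": contig_id,
            "gene_number": gene.gene_number,
            "start": gene.start,
            "stop": gene.stop,
            "strand": gene.strand,
            "product": gene.product,
            "best_match": best_prot.protein_id,
            "source_phage": best_prot.genome_id,
            "identity_percent": round(best_ident, 2),
            "ties": ties,
        })
    return table


def prophage_gff3(call: ProphageCall, path: str | Path) -> None:
    """GFF3 of prophage genes with provenance attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in call.genes:
            attrs = (f"ID={g['gene_number']};product={g['product']};"
                     f"best_match={g['best_match']};source_phage={g['source_phage']};"
                     f"identity={g['identity_percent']}")
            strand = g.get("strand", "+")
            fh.write(f"{g['contig']}\tpropiphage\tCDS\t{g['start']}\t{g['stop']}\t.\t{strand}\t0\t{attrs}\n")
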