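"""Data model and readers/writers for genomes, annotations and read-start profiles.

Coordinates are 1-based and inclusive throughout, matching GenBank flat
files; every conversion to Python slices happens explicitly at the point of
use.  Sequences are restricted to the alphabet ``{A, C, G, T, N}`` — other
IUPAC ambiguity codes are rejected at parse time because the downstream
exact-match steps (dotplots, att-core discovery, cohesive-end extraction)
require a clean alphabet.

For a phage genome with cohesive (cos) ends the stored linear sequence is
taken to be the full virion top strand, i.e. it *includes* the
single-stranded 3' extension at the right end; terminus arithmetic in
:mod:`propiphage.termini` relies on this convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

_VALID_DNA = re.compile(r"^[ACGTN]+$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: NCBI translation table 11 (bacterial/archaeal/plant plastid).
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]


def revcomp(sequence: str) -> str:
    """Reverse complement of an ``{A,C,G,T,N}`` string."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _check_alphabet(sequence: str, what: str = "sequence") -> str:
    seq = sequence.upper()
    if not seq:
        raise ValueError(f"empty {what}")
    if not _VALID_DNA.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(
            f"{what} contains characters outside {{A,C,G,T,N}}: {bad}; "
            "ambiguity codes other than N are not supported"
        )
    return seq


@dataclass
class GeneFeature:
    """One annotated gene (CDS or tRNA) on a genome.

    ``start``/``stop`` are 1-based inclusive with ``start <= stop``
    regardless of strand; ``strand`` is ``'+'`` or ``'-'``.
    """

    gene_number: str
    start: int
    stop: int
    strand: str
    product: str = ""
    translation: str = ""
    kind: str = "CDS"

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError(f"gene {self.gene_number}: start {self.start} > stop {self.stop}")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_number}: strand must be '+' or '-'")

    @property
    def length_bp(self) -> int:
        return self.stop - self.start + 1


@dataclass
class GenomeRecord:
    """One phage or host replicon: sequence, annotations, provenance."""

    id: str
    sequence: str
    genes: list[GeneFeature] = field(default_factory=list)
    source: str = "deposited"
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = _check_alphabet(self.sequence, f"sequence of {self.id}")
        for gene in self.genes:
            if gene.stop > len(self.sequence) or gene.start < 1:
                raise ValueError(
                    f"gene {gene.gene_number} of {self.id} spans "
                    f"{gene.start}..{gene.stop}, outside 1..{len(self.sequence)}"
                )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        return gc_percent(self.sequence)

    def subseq(self, start: int, stop: int) -> str:
        """1-based inclusive slice of the plus strand."""
        if start < 1 or stop > self.length_bp or start > stop:
            raise ValueError(f"coordinates {start}..{stop} outside 1..{self.length_bp}")
        return self.sequence[start - 1 : stop]

    def gene_sequence(self, gene: GeneFeature) -> str:
        """Coding-strand nucleotide sequence of a gene."""
        s = self.subseq(gene.start, gene.stop)
        return revcomp(s) if gene.strand == "-" else s


@dataclass
class ReadStartProfile:
    """Per-position read-start counts on each strand plus total coverage depth.

    ``plus_starts[i]`` counts reads whose 5' end maps to position ``i+1`` on
    the plus strand; ``minus_starts[i]`` counts minus-strand reads whose
    5' end (the *rightmost* aligned base) maps to position ``i+1``.
    """

    genome_id: str
    plus_starts: np.ndarray
    minus_starts: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.plus_starts = np.asarray(self.plus_starts, dtype=np.int64)
        self.minus_starts = np.asarray(self.minus_starts, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        n = len(self.plus_starts)
        if len(self.minus_starts) != n or len(self.depth) != n:
            raise ValueError("profile arrays must have equal length")
        for name, arr in (("plus_starts", self.plus_starts),
                          ("minus_starts", self.minus_starts),
                          ("depth", self.depth)):
            if (arr < 0).any():
                raise ValueError(f"{name} contains negative counts")

    def __len__(self) -> int:
        return len(self.plus_starts)


# ---------------------------------------------------------------------------
# sequence-level operations
# ---------------------------------------------------------------------------

def gc_percent(sequence: str) -> float:
    """Percent G+C of a DNA string, with N excluded from both numerator and
    denominator.

    Raises ``ValueError`` for empty or all-N input.
    """
    seq = _check_alphabet(sequence)
    gc = seq.count("G") + seq.count("C")
    acgt = len(seq) - seq.count("N")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * gc / acgt


def translate_cds(sequence: str, start: int | None = None, stop: int | None = None,
                  strand: str = "+") -> str:
    """Translate a CDS under NCBI translation table 11.

    The CDS spans ``start..stop`` (1-based inclusive; defaults to the whole
    string) on the given strand; minus-strand spans are reverse-complemented
    before translation.  Alternative initiators (GTG, TTG, ...) are rendered
    as ``M``; a terminal stop codon is dropped.  An internal stop codon or a
    length not divisible by 3 raises ``ValueError``.
    """
    seq = _check_alphabet(sequence)
    if start is None:
        start = 1
    if stop is None:
        stop = len(seq)
    if start < 1 or stop > len(seq) or start > stop:
        raise ValueError(f"CDS span {start}..{stop} outside 1..{len(seq)}")
    cds = seq[start - 1 : stop]
    if strand == "-":
        cds = revcomp(cds)
    elif strand != "+":
        raise ValueError("strand must be '+' or '-'")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in _TABLE11.stop_codons:
        codons = codons[:-1]
    aa: list[str] = []
    for i, codon in enumerate(codons):
        if codon in _TABLE11.stop_codons:
            raise ValueError(f"internal stop codon {codon} at codon {i + 1} "
                             f"(CDS position {3 * i + 1})")
        if "N" in codon:
            aa.append("X")
        elif i == 0 and codon in _TABLE11.start_codons:
            aa.append("M")
        else:
            aa.append(_TABLE11.forward_table[codon])
    return "".join(aa)


# ---------------------------------------------------------------------------
# GenBank / FASTA
# ---------------------------------------------------------------------------

def _feature_to_gene(feat: SeqFeature, seq: str, record_id: str, index: int) -> GeneFeature:
    start = int(feat.location.start) + 1  # Biopython is 0-based half-open
    stop = int(feat.location.end)
    if stop > len(seq) or start < 1:
        name = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", [f"feature #{index}"]))[0]
        raise ValueError(f"CDS {name} of {record_id} exceeds sequence bounds "
                         f"({start}..{stop} vs length {len(seq)})")
    strand = "-" if feat.location.strand == -1 else "+"
    for key in ("gene", "locus_tag", "protein_id"):
        if key in feat.qualifiers:
            number = feat.qualifiers[key][0]
            break
    else:
        number = str(index)
    product = feat.qualifiers.get("product", [""])[0]
    translation = feat.qualifiers.get("translation", [""])[0]
    kind = feat.type
    if kind == "CDS" and not translation:
        sub = seq[start - 1 : stop]
        if strand == "-":
            sub = revcomp(sub)
        if len(sub) % 3 == 0:
            try:
                translation = translate_cds(sub)
            except ValueError:
                translation = ""
    return GeneFeature(gene_number=number, start=start, stop=stop, strand=strand,
                       product=product, translation=translation, kind=kind)


def read_genbank(path: str | Path, source: str = "deposited") -> GenomeRecord:
    """Read a flat GenBank record into a :class:`GenomeRecord`.

    Join/complement locations are resolved to an outer start/stop/strand.
    A record without an ORIGIN sequence is a hard error; a CDS extending
    past the sequence end raises an error naming the feature.
    """
    record = SeqIO.read(str(path), "genbank")
    try:
        seq = str(record.seq)
    except Exception as exc:  # undefined sequence
        raise ValueError(f"{path}: GenBank record has no ORIGIN sequence") from exc
    if not seq:
        raise ValueError(f"{path}: GenBank record has no ORIGIN sequence")
    seq = _check_alphabet(seq, f"ORIGIN of {record.id}")
    genes = [
        _feature_to_gene(feat, seq, record.id, i)
        for i, feat in enumerate(record.features)
        if feat.type in ("CDS", "tRNA")
    ]
    genes.sort(key=lambda g: (g.start, g.stop))
    return GenomeRecord(id=record.id, sequence=seq, genes=genes, source=source,
                        description=record.description)


def write_genbank(genome: GenomeRecord, path: str | Path) -> None:
    """Write a :class:`GenomeRecord` as a flat GenBank file (lossless for
    sequence, coordinates and strands)."""
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description=genome.description)
    record.annotations["molecule_type"] = "DNA"
    for gene in genome.genes:
        loc = FeatureLocation(gene.start - 1, gene.stop, strand=1 if gene.strand == "+" else -1)
        quals: dict[str, list[str]] = {"gene": [gene.gene_number]}
        if gene.product:
            quals["product"] = [gene.product]
        if gene.translation:
            quals["translation"] = [gene.translation]
        record.features.append(SeqFeature(loc, type=gene.kind, qualifiers=quals))
    SeqIO.write([record], str(path), "genbank")


def read_fasta(path: str | Path, source: str = "deposited") -> list[GenomeRecord]:
    """Read one or more FASTA records (no annotations)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(GenomeRecord(id=rec.id, sequence=str(rec.seq), source=source,
                                description=rec.description))
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(genomes: GenomeRecord | Iterable[GenomeRecord], path: str | Path) -> None:
    if isinstance(genomes, GenomeRecord):
        genomes = [genomes]
    records = [SeqRecord(Seq(g.sequence), id=g.id, description=g.description) for g in genomes]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# read-start profile TSV
# ---------------------------------------------------------------------------

_PROFILE_HEADER = ("pos", "plus_starts", "minus_starts", "depth")


def write_profile_tsv(profile: ReadStartProfile, path: str | Path) -> None:
    """Write a read-start profile as TSV: pos, plus_starts, minus_starts, depth."""
    with open(path, "w") as fh:
        fh.write(f"# genome_id={profile.genome_id}\n")
        fh.write("\t".join(_PROFILE_HEADER) + "\n")
        for i in range(len(profile)):
            fh.write(f"{i + 1}\t{profile.plus_starts[i]}\t{profile.minus_starts[i]}\t{profile.depth[i]}\n")


def read_profile_tsv(path: str | Path) -> ReadStartProfile:
    genome_id = Path(path).stem
    rows: list[tuple[int, int, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"genome_id=(\S+)", line)
                if m:
                    genome_id = m.group(1)
                continue
            if line.startswith("pos"):
                continue
            pos, plus, minus, depth = line.split("\t")
            rows.append((int(pos), int(plus), int(minus), int(depth)))
    if not rows:
        raise ValueError(f"{path}: empty profile")
    rows.sort()
    n = rows[-1][0]
    plus = np.zeros(n, dtype=np.int64)
    minus = np.zeros(n, dtype=np.int64)
    depth = np.zeros(n, dtype=np.int64)
    for pos, p, m, d in rows:
        plus[pos - 1], minus[pos - 1], depth[pos - 1] = p, m, d
    return ReadStartProfile(genome_id=genome_id, plus_starts=plus, minus_starts=minus, depth=depth)


def profile_from_alignments(genome_id: str, genome_length: int,
                            alignments: Sequence[tuple[int, int, str]]) -> ReadStartProfile:
    """Build a profile from aligned-read tuples ``(start, end, strand)``.

    ``start``/``end`` are 1-based inclusive reference coordinates of the
    aligned span; the biological read start is ``start`` for plus-strand
    reads and ``end`` for minus-strand reads.  This is the thin adapter for
    consuming standard alignment records (e.g. iterated from a SAM file)
    without taking an aligner dependency.
    """
    plus = np.zeros(genome_length, dtype=np.int64)
    minus = np.zeros(genome_length, dtype=np.int64)
    depth = np.zeros(genome_length + 1, dtype=np.int64)
    for start, end, strand in alignments:
        if not (1 <= start <= end <= genome_length):
            raise ValueError(f"read span {start}..{end} outside 1..{genome_length}")
        if strand == "+":
            plus[start - 1] += 1
        elif strand == "-":
            minus[end - 1] += 1
        else:
            raise ValueError("strand must be '+' or '-'")
        depth[start - 1] += 1
        depth[end] -= 1
    depth = np.cumsum(depth[:-1])
    return ReadStartProfile(genome_id=genome_id, plus_starts=plus, minus_starts=minus, depth=depth)


def profile_from_sam(path: str | Path, genome_id: str, genome_length: int) -> ReadStartProfile:
    """Read start positions and strands from a SAM/BAM file (requires pysam)."""
    import pysam  # local import: optional adapter

    spans: list[tuple[int, int, str]] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for read in bam:
            if read.is_unmapped or read.reference_name != genome_id:
                continue
            spans.append((read.reference_start + 1, read.reference_end,
                          "-" if read.is_reverse else "+"))
    return profile_from_alignments(genome_id, genome_length, spans)
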