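# propiphage

Comparative genomics of temperate *Propionibacterium freudenreichii*
bacteriophages — the phages of Swiss-type cheese fermentation — and, more
generally, of any small cohort of closely related, mosaic siphophage
genomes. The package is written for phage genomicists who have a handful
of annotated genomes (GenBank), read alignments, and draft host
assemblies, and want the standard cohort analyses reproducibly and
offline:

* **Phamilies (phams):** all-vs-all protein comparison (global alignment,
  BLOSUM62 11/1) clustered by single-linkage transitive closure at
  ≥ 32.5 % identity over ≥ 50 % of the shorter protein — the unit of
  gene-content comparison — plus shared-gene-content matrices, heat maps,
  a neighbour-joining tree over distance *d* = 1 − (mean shared-pham
  fraction), and a Nexus DISTANCES export for SplitsTree.
* **Nucleotide comparison:** a BLASTN-style seeded aligner (exact 11-mer
  seeds, ungapped X-drop extension, Karlin–Altschul E ≤ 10⁻⁵), pairwise
  ANI-style identity (alignment-length-weighted over HSPs) and *span
  coverage* (union of aligned spans ÷ shorter genome), SNP counts for
  near-collinear pairs, exact-word dotplots (word = 10), and single-linkage
  cluster assignment with span coverage ≥ 50 % as the primary criterion.
* **Genome termini:** cos-site detection from read-start profiles — two
  opposite-strand read-start pileups separated by a short region of
  depressed coverage give the physical ends and the single-stranded
  overhang (for these phages, 12-base 3′ extensions).
* **Integration sites:** the attP/attB common core as the longest exact
  common substring (suffix automaton) between the integrase upstream
  window and the host, with tRNA-overlap annotation; and mosaic prophage
  reconstruction across split contigs with attL/attR recovery and
  per-gene donor provenance.
* **A synthetic forge:** a generator of cohorts, hosts and read profiles
  with planted ground truth (cluster structure, pham membership, SNP
  counts, cos ends, att cores, prophage maps), so the whole pipeline is
  testable with no downloads.

## Worked example

Generate a seven-genome cohort (two clusters, 4 + 3, with a near-identical
twin pair), its host contigs and read profiles, then analyse it:

```bash
propiphage forge --seed 1 --out-dir cohort
propiphage cluster cohort/phi*.gbk
```

```
phiA1   A
phiA2   A
phiA3   A
phiA4   A
phiB1   B
phiB2   B
phiB3   B
```

The two clusters separate on span coverage: within-cluster pairs share
~75 % of their length at ~98 % identity, between-cluster pairs only ~35 %
(at ~90 % identity), so single linkage at the 50 % span threshold splits
them cleanly. Pairwise detail, including the twin pair that differs by
exactly two substitutions:

```bash
propiphage compare cohort/phiB1.gbk cohort/phiB2.gbk cohort/phiB3.gbk --out pair.tsv
```

```
genome_a  genome_b  identity_percent  coverage_percent  n_hsps  snp_count
phiB1     phiB2     99.99             100.00            1       2
phiB1     phiB3     98.06             73.71             28
phiB2     phiB3     98.06             73.71             28
```

(`snp_count` is only defined for near-collinear pairs, coverage ≥ 95 %.)

Genome termini from the simulated read-start profile — one plus-strand
pileup at position 1, one minus-strand pileup 12 bases before the end, and
halved coverage over the gap — a 12-base 3′ cohesive end:

```bash
propiphage termini cohort/phiA1.profile.tsv --genome cohort/phiA1.gbk
```

```
{
  "defined_ends": true,
  "left_end": 1,
  "right_end": 37881,
  "overhang_length": 12,
  "overhang_sequence": "CCGCAGAGGCCT",
  "overhang_polarity": "3prime",
  ...
}
```

The attP/attB common core upstream of the integrase, against the vacant
host (the 45 bp core is identical on phage and host, and the attB overlaps
a tRNA):

```bash
propiphage attscan cohort/phiA1.gbk cohort/host_vacant.gbk
```

```
{
  "core_length": 45,
  "attP_start": 4743, "attP_end": 4787,
  "attB_start": 50000, "attB_end": 50044,
  "host_strand": "+",
  "overlapping_trna": "trna1"
}
```

And the mosaic prophage split across two host contigs, reconstructed from
attL to attR with per-gene donor provenance:

```bash
propiphage prophage cohort/host_c1.gbk cohort/host_c17.gbk \
    --panel cohort/phiA1.gbk --panel cohort/phiA2.gbk \
    --panel cohort/phiA3.gbk --panel cohort/phiA4.gbk
```

```
prophage 1: best match phiA1, 33 genes -> prophage_1.json
```

with `prophage_1.bed` placing the attL/attR direct repeat and the prophage
segments on host coordinates, and `prophage_1.gff3` carrying each gene's
best-matching donor protein and identity. `propiphage all` runs the whole
pipeline (pairwise table, clusters, phams, heat map, NJ tree + Nexus,
dotplots, genome map) into one output directory.

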