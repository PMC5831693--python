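# Methods

`propiphage` re-implements, as a reusable offline pipeline, the comparative
analyses used to characterise small cohorts of temperate dairy
propionibacterium (*Propionibacterium freudenreichii*) siphophages:
gene-family ("pham") clustering, pairwise nucleotide identity and span
coverage with cluster assignment, dotplots, cos-type genome-terminus
detection from read pileups, attP/attB common-core discovery, and mosaic
prophage reconstruction. A synthetic-cohort generator with planted ground
truth makes every stage testable without any sequence download.

## The synthetic cohort (what the forge emulates)

The forge generates genomes as concatenations of coding *modules* —
synthetic ORFs under translation table 11 with GC-biased codon usage —
separated by short random spacers, emulating the observables of a real
two-cluster phage cohort:

* **Cohort shape.** Seven genomes in clusters of 4 and 3 (`genomes_per_cluster`),
  ~35–39 kb each (`genome_length_bp = 36000` before stochastic variation),
  ~65 % GC (`gc_target = 0.65`).
* **Modular sharing.** A backbone of modules shared by *all* genomes
  (~35 % of genome length), cluster-core modules shared *within* a cluster
  (a further ~40 %), and genome-private modules (~17 %); spacers make up
  the rest. Single-linkage clustering on span coverage at the 50 %
  threshold therefore separates the two clusters: within-cluster coverage
  measures ~75 %, between-cluster ~35 %.
* **Divergence.** Genome-specific copies of shared modules carry
  substitutions at 1 % (within-cluster pairwise identity ~98 %); the
  backbone additionally diverges 4 % per cluster (between-cluster identity
  ~90.5 %). Substitutions never touch start/stop codons and never create
  internal stops, so every emitted CDS re-translates cleanly. Indels are
  off by default, keeping SNP-count truth exact.
* **Twin pair.** One within-cluster pair is an exact copy except for
  `twin_snps = 2` substitutions planted in spacers — a near-identical pair
  whose substitution count is knowable exactly.
* **Cohesive ends.** The stored sequence is the full virion top strand; a
  12-base 3′ overhang occupies the terminal 12 bases (the bottom strand
  spans `1..L−12`, its own 3′ tail lying off-coordinate as the complement
  of the last 12 bases).
* **Integration.** Each cluster carries a tyrosine-integrase module with an
  attP common core (45 bp in one cluster, 49 bp in the other) planted in
  the spacer directly upstream. The host generator plants the same core as
  a vacant attB overlapping a tRNA by 20 bp, or as an attL/attR direct
  repeat flanking an integrated chimeric prophage (first donor left of the
  tape-measure gene, second donor from it rightwards), split into two
  contigs that overlap by 150 bp inside the tape-measure gene.

One deliberately artificial touch: the bases immediately flanking every
planted att core are forced to mismatch their counterparts on the other
replicon. Without this, a ¼-probability chance match at a flank would
extend the longest common substring past the planted core and exact
coordinate recovery would be ill-posed as a test criterion.

**What the forge does not emulate** — and hence what passing tests do not
show about real data: biological sequence content (modules are random
ORFs, so protein relatedness is bimodal: near-identical or unrelated, with
no twilight-zone homologs); rearrangements, inversions and indels;
sequencing error and coverage bias in read profiles; hosts at real scale
(default 100 kb versus ~2.6 Mb) or with multiple/partial prophages;
ambiguity codes.

## Nucleotide comparison

`seed_extend_align` is a BLASTN-style seeded local aligner: exact 11-mer
seeds on both strands, grouped by diagonal, extended ungapped under an
X-drop of 20 with match +1 / mismatch −2. Under this scoring any run of
> 10 consecutive mismatches exceeds the X-drop, so each diagonal is first
split at such runs (vectorised) and a maximal-scoring-subsegment scan
(Kadane with X-drop termination) finishes the job. Segments are trimmed to
their outermost intact seed words, so an HSP always starts and ends on an
11-mer exact match; this keeps net-positive chance tails at homology
boundaries out of the alignment, at the cost of shaving a few terminal
columns off genuinely diverged segment ends. E-values use the ungapped
Karlin–Altschul formula with λ solved at import time from
Σ pᵢpⱼ e^{λ sᵢⱼ} = 1 (λ ≈ 1.336 for +1/−2, uniform composition) and the
tabulated K = 0.46; the retention threshold is E ≤ 10⁻⁵.

Gapped (banded) extension is deliberately not implemented: with
substitution-only divergence collinear homology stays on one diagonal, and
identity/coverage summaries aggregate over HSPs, so bridging indels would
not change any summary here. Indel-containing *collinear* pairs are
handled by a separate path: `collinear_differences` globally aligns the
two sequences by edit distance (edlib) and reports substitution columns
and indel events separately. `count_snps` refuses pairs below 95 % span
coverage, where a substitution count is not meaningful.

Summary conventions (each exposed as configuration): identity is the
alignment-length-weighted mean over retained HSPs; the coverage
denominator is the *shorter* genome of the pair; clusters are the
single-linkage closure of {coverage ≥ 50 %} with identity ≥ 80 % as a
secondary guard; cluster labels are assigned by lexicographically smallest
member, making output order-independent.

## Phams

Proteins are compared by global alignment (BLOSUM62, gap open 11 /
extend 1, via Biopython's pairwise aligner); identity is identical columns
over aligned columns with terminal-gap columns excluded. Because
co-optimal global alignments can differ between `align(a,b)` and
`align(b,a)`, the argument pair is canonically ordered first, making
identity exactly symmetric. Two proteins are directly related at
≥ 32.5 % identity over ≥ 50 % of the shorter protein — the classical
actinobacteriophage gene-family operating point — and phams are the
single-linkage transitive closure of that relation, numbered
deterministically by smallest member id. An exact shared-6-mer (≥ 2)
prefilter skips alignments that cannot matter in the cohort regime
(related proteins near-identical, unrelated ones random); it can be
disabled, and tests assert prefilter-on/off equality and agreement with a
naive no-prefilter fixed-point-closure oracle.

Shared-gene content is reported directionally (|phams in both| / |phams in
A|) and as the symmetrised mean; gene-content distance is 1 − mean shared
fraction. The NJ tree uses scikit-bio's neighbour joining; a Nexus
DISTANCES block is exported so the network (NeighborNet) view can be drawn
externally in SplitsTree — the shared-gene computation is this package's,
the network-layout algorithm is not.

## Genome termini

For a cos phage, linear virion DNA yields a pileup of plus-strand read
starts at the top strand's 5′ terminus, a pileup of minus-strand read
starts (their 5′ ends) at the bottom strand's 5′ terminus, and — walking
circularly between the two pileups — a short stretch of roughly halved
total coverage where only one strand is present: the single-stranded
overhang. `detect_cos_ends` calls a terminus when each strand shows
exactly one pileup ≥ 20× the median per-position start rate (median
floored at one read so sparse profiles are well-defined); the
circular gap between the pileups must be ≤ 50 bp with mean depth below
0.75× the median. A gap running from the minus pileup forward to the plus
pileup is a 3′ overhang; the opposite arrangement is called 5′ and flagged
unusual. Profiles with no super-threshold pileup return a "no defined
ends" result (circularly permuted packaging is indistinct from this
signal); two separated pileups on one strand raise an error listing both.
The read simulator's forward model adds one terminal read per molecule per
strand on top of uniform interior starts, which reproduces both signals.

## att sites and prophages

The attP/attB common core is found as the longest exact common substring
between the 500 bp window upstream of the integrase (strand-aware) and
either strand of the host, via a suffix automaton built over the window
and streamed along the host — O(window) memory, O(host) time. Exact
matching (no mismatches) reflects that the integration core is a region of
strict sequence identity; a mismatch-tolerant mode is out of scope. The
minimum core of 20 bp sits above the chance-match ceiling: the expected
longest chance common substring between a 500 bp window and an n-base
genome is ≈ log₄(500·n), i.e. ~15–16 bp even for a 2.6 Mb host. Ties at
maximal length break toward the occurrence closest to the integrase.
tRNA overlap is inclusive: sharing a single base with the attB core
counts.

`scan_prophages` chains phage-vs-contig HSPs (gaps ≤ 1.5 kb, spanning
intergenic spacers) into candidate regions, keeps hits ≥ 500 aligned bases,
and joins regions across contigs when one ends and the other begins at a
contig edge *and* their projections onto the best-matching phage are
adjacent or overlapping — the signature of a single prophage split by the
assembly, keyed on phage coordinates rather than host scaffolding. The
attL/attR direct repeat is then recovered as the longest common substring
of the two junction neighbourhoods (±800 bp — wide enough to reach past a
terminal gene that fell below the 500 bp hit threshold plus a spacer);
prophage genes get per-gene provenance as the panel protein of maximal
amino-acid identity, with exact ties reported rather than silently broken.

## Numerical and design choices

* Coordinates are 1-based inclusive (GenBank convention) everywhere;
  Python slice conversion happens only at the point of use.
* Alphabet is strict {A,C,G,T,N}; other ambiguity codes are rejected at
  parse time because the exact-match stages (dotplots, cores, overhangs)
  require a clean alphabet. N never matches and is excluded from GC.
* Determinism: one seed fixes all forge randomness; pham and cluster
  labels are assigned by sorted member ids; pipeline reruns are
  byte-identical (timestamps are confined to the run log).
* Dotplots report every exact forward/reverse-complement word match
  (default word 10); optional down-sampling for rendering never removes
  main-diagonal self-matches.
* Problem sizes used by the test suite and the acceptance script (chosen
  to characterise behaviour well at desk scale): 50 seeded cohorts for the
  cluster/pham/SNP plant-and-recover sweep, 100 terminus simulations at
  depth 50 over overhang lengths 8–16, brute-force LCS oracle instances up
  to 5 kb, 20 seeded split-prophage reconstructions, and a 10-cohort sweep
  in the acceptance script; the brute-force pham oracle runs on a
  three-genome protein subset, with the planted module-family partition
  checked on every cohort.

## Known limitations

* The seeded aligner reports ungapped HSPs only; genomes related through
  many short indels would fragment into many HSPs and coverage would be
  slightly underestimated (the edit-distance path covers the collinear
  case).
* Pham building with the k-mer prefilter could in principle miss a real
  twilight-zone pair (~33 % identity with < 2 shared 6-mers); disable the
  prefilter for exhaustive runs on real proteins.
* `find_att_core` against a host that already carries a closely related
  prophage will return the (long) prophage match rather than the att core;
  use `scan_prophages`, whose junction-repeat logic is designed for that
  case.
* The terminus caller assumes cos-type (defined-end) packaging; pac-type /
  headful classification is out of scope, and such genomes return
  "no defined ends".
* Host-side validation against deposited accessions requires the records
  themselves (network access) and is therefore external to this package's
  test suite.
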