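"""Nucleotide-level genome comparison.

Implements a BLASTN-style seeded local aligner (exact-word seeds on both
strands, ungapped X-drop extension along each seed diagonal, Karlin-Altschul
E-value filtering), pairwise identity / span-coverage summaries, SNP
counting for near-collinear pairs, exact-word dotplots, and single-linkage
cluster assignment with span coverage as the primary criterion.

Scoring and statistics
----------------------
Ungapped extensions use match +1 / mismatch -2 with an X-drop of 20.  Under
this scheme any run of more than ``X // mismatch_penalty`` consecutive
mismatches triggers the X-drop, so each diagonal is first split at such
runs (vectorised) and a linear score scan inside each piece handles drops
accumulated over shorter mismatch runs.  E-values use the ungapped
Karlin-Altschul formula ``E = K * m * n * exp(-lambda * S)``; ``lambda`` is
solved at import time from ``sum_ij p_i p_j exp(lambda * s_ij) = 1`` under
uniform base composition (lambda ~= 1.336 for +1/-2) and ``K = 0.46``, the
standard tabulated value for this scoring scheme.

Identity aggregation across HSPs is alignment-length weighted, matching the
way BLASTN-derived genome identities are conventionally reported; the
coverage denominator is the shorter genome of the pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
from scipy.optimize import brentq

from propiphage.core_io import GenomeRecord, revcomp

MATCH_SCORE = 1
MISMATCH_PENALTY = 2
XDROP = 20
#: longest mismatch run an ungapped extension survives under the X-drop
MAX_MISMATCH_RUN = XDROP // MISMATCH_PENALTY
#: Karlin-Altschul K for +1/-2 ungapped nucleotide scoring (tabulated).
KA_K = 0.46


def _solve_lambda(match: int = MATCH_SCORE, mismatch: int = MISMATCH_PENALTY) -> float:
    # sum over ordered base pairs, uniform composition: 1/4 match, 3/4 mismatch
    f = lambda lam: 0.25 * math.exp(lam * match) + 0.75 * math.exp(-lam * mismatch) - 1.0
    return brentq(f, 1e-6, 10.0)


KA_LAMBDA = _solve_lambda()

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _words(enc: np.ndarray, w: int) -> np.ndarray:
    """Packed integer value of each w-mer; -1 where the window contains N."""
    n = len(enc) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for k in range(w):
        window = enc[k : k + n].astype(np.int64)
        vals = vals * 4 + np.where(window == 4, 0, window)
        bad |= window == 4
    vals[bad] = -1
    return vals


def _word_matches(aw: np.ndarray, bw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All (a_pos, b_pos) 0-based positions with identical valid words."""
    if len(aw) == 0 or len(bw) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(bw, kind="stable")
    bw_sorted = bw[order]
    valid = aw >= 0
    a_idx = np.nonzero(valid)[0]
    left = np.searchsorted(bw_sorted, aw[valid], side="left")
    right = np.searchsorted(bw_sorted, aw[valid], side="right")
    counts = right - left
    hit = counts > 0
    a_idx, left, counts = a_idx[hit], left[hit], counts[hit]
    a_pos = np.repeat(a_idx, counts)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    group_offsets = np.cumsum(counts) - counts
    flat = np.arange(total) - np.repeat(group_offsets, counts) + np.repeat(left, counts)
    b_pos = order[flat]
    return a_pos, b_pos


@dataclass
class HSP:
    """One local alignment (high-scoring segment pair) between two genomes.

    All coordinates are 1-based inclusive on the plus strand of the
    respective genome; ``strand`` refers to genome *b*.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    matches: int
    alignment_length: int
    score: float
    e_value: float

    def __post_init__(self) -> None:
        if self.a_start > self.a_end:
            raise ValueError("a_start must be <= a_end")
        if self.matches > self.alignment_length:
            raise ValueError("matches cannot exceed alignment_length")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")

    @property
    def identity_percent(self) -> float:
        return 100.0 * self.matches / self.alignment_length


@dataclass
class PairwiseNucSummary:
    genome_a: str
    genome_b: str
    identity_percent: float
    coverage_percent: float
    hsps: list[HSP] = field(default_factory=list)
    snp_count: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.identity_percent <= 100 and 0 <= self.coverage_percent <= 100):
            raise ValueError("identity and coverage must lie in [0, 100]")


@dataclass
class DotplotMatch:
    word_length: int
    matches: list[tuple[int, int, str]]  # (a_pos, b_pos, strand), 1-based word starts


@dataclass
class ClusterAssignment:
    labels: dict[str, str]
    span_threshold: float
    identity_threshold: float

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for genome, label in self.labels.items():
            out.setdefault(label, []).append(genome)
        return {k: sorted(v) for k, v in out.items()}


def _xdrop_segments(match: np.ndarray, xdrop: int = XDROP,
                    min_matches: int = 12, anchor: int = 11) -> list[tuple[int, int]]:
    """BLAST-style ungapped segmentation of a diagonal match mask.

    Scanning with cumulative score (+1 match / -2 mismatch), a segment ends
    where the score has dropped ``xdrop`` below its running maximum; the
    segment is reported up to the running-maximum position and the scan
    restarts after the drop.  Endpoints always fall on matching columns,
    and each reported segment is trimmed to its outermost runs of
    ``anchor`` consecutive matches — every HSP therefore starts and ends on
    an intact seed word, which keeps chance match tails at the edges of a
    homologous region out of the alignment.
    """
    idx = np.nonzero(match)[0]
    if len(idx) < min_matches:
        return []
    # A mismatch run longer than xdrop/penalty always triggers the X-drop,
    # so pre-split there (vectorised); the linear scan below handles drops
    # accumulated over several shorter mismatch runs.
    gaps = np.diff(idx) - 1
    run_breaks = np.nonzero(gaps > xdrop // MISMATCH_PENALTY)[0]
    piece_starts = np.concatenate([[0], run_breaks + 1])
    piece_ends = np.concatenate([run_breaks, [len(idx) - 1]])

    out: list[tuple[int, int]] = []
    for ps, pe in zip(piece_starts, piece_ends):
        if pe - ps + 1 < min_matches:
            continue
        positions = idx[ps : pe + 1].tolist()  # plain ints: fast scalar loop
        n = len(positions)
        k = 0
        while k < n:
            # maximal-scoring subsegment (Kadane) with X-drop termination:
            # negative prefixes are discarded so segment ends snap to the
            # high-identity core rather than chance matches at the edges
            cur = 0
            best = 0
            best_j = k
            best_start = k
            start = k
            prev = positions[k]
            j = k
            broke = False
            while j < n:
                pos = positions[j]
                if j > k:
                    cur -= MISMATCH_PENALTY * (pos - prev - 1)
                    if best > 0 and best - cur >= xdrop:
                        broke = True
                        break
                    if cur < 0:
                        cur = 0
                        start = j
                prev = pos
                cur += MATCH_SCORE
                if cur > best:
                    best = cur
                    best_j = j
                    best_start = start
                j += 1
            if best_j - best_start + 1 >= min_matches:
                trimmed = _anchor_trim(positions, best_start, best_j, anchor)
                if trimmed is not None and trimmed[1] - trimmed[0] + 1 >= min_matches:
                    out.append((positions[trimmed[0]], positions[trimmed[1]]))
            # restart at the match where the drop was detected; an exhausted
            # piece terminates
            k = j if broke else j + 1
    return out


def _anchor_trim(positions: list[int], lo: int, hi: int,
                 anchor: int) -> tuple[int, int] | None:
    """Indices of the outermost ``anchor``-long consecutive-match runs within
    ``positions[lo..hi]``; None when the segment contains no such run (and
    hence no intact seed word)."""
    last = hi - anchor + 1
    left = None
    for t in range(lo, last + 1):
        if positions[t + anchor - 1] - positions[t] == anchor - 1:
            left = t
            break
    if left is None:
        return None
    for t in range(last, lo - 1, -1):
        if positions[t + anchor - 1] - positions[t] == anchor - 1:
            return left, t + anchor - 1
    return None


def _extend_on_diagonals(ea: np.ndarray, eb: np.ndarray, a_pos: np.ndarray,
                         b_pos: np.ndarray, word: int, min_matches: int,
                         margin: int = 300) -> list[tuple[int, int, int, int, int, int]]:
    """Given seed word matches, return ungapped segments
    (a0, a1, b0, b1, matches, length) in 0-based inclusive coords.

    Extension is confined to a window ``margin`` beyond the outermost seeds
    of each diagonal; the X-drop terminates real extensions long before the
    window edge, so the window only bounds work on chance-seed diagonals.
    """
    if len(a_pos) == 0:
        return []
    la, lb = len(ea), len(eb)
    diags = a_pos - b_pos
    order = np.lexsort((a_pos, diags))
    diags_s, a_s = diags[order], a_pos[order]
    boundaries = np.nonzero(np.diff(diags_s))[0]
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries, [len(diags_s) - 1]])
    segments: list[tuple[int, int, int, int, int, int]] = []
    for s_i, e_i in zip(starts, ends):
        d = int(diags_s[s_i])
        # Overlap of the two sequences on diagonal d (a = b + d).
        a_lo = max(0, d, int(a_s[s_i]) - margin)
        a_hi = min(la, lb + d, int(a_s[e_i]) + word + margin)  # exclusive
        if a_hi - a_lo < word:
            continue
        sub_a = ea[a_lo:a_hi]
        sub_b = eb[a_lo - d : a_hi - d]
        match = (sub_a == sub_b) & (sub_a != 4)
        for s, e in _xdrop_segments(match, min_matches=min_matches, anchor=word):
            n_match = int(match[s : e + 1].sum())
            length = e - s + 1
            a0, a1 = a_lo + s, a_lo + e
            segments.append((a0, a1, a0 - d, a1 - d, n_match, length))
    return segments


def _segment_evalue(score: float, m: int, n: int) -> float:
    if score <= 0:
        return math.inf
    # exp underflows gracefully to 0.0 for long high-scoring segments
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def seed_extend_align(a: GenomeRecord | str, b: GenomeRecord | str, word: int = 11,
                      evalue_max: float = 1e-5, min_matches: int = 12) -> list[HSP]:
    """Seeded local alignment of two genomes on both strands.

    Exact ``word``-mers seed ungapped X-drop extensions along each diagonal;
    overlapping extensions on the same diagonal are merged; segments with
    Karlin-Altschul E-value above ``evalue_max`` are discarded.  Sequences
    shorter than the seed word yield an empty result.
    """
    sa = a.sequence if isinstance(a, GenomeRecord) else a
    sb = b.sequence if isinstance(b, GenomeRecord) else b
    la, lb = len(sa), len(sb)
    if la < word or lb < word:
        return []
    ea, eb = _encode(sa), _encode(sb)
    aw = _words(ea, word)
    hsps: list[HSP] = []

    # forward strand
    a_pos, b_pos = _word_matches(aw, _words(eb, word))
    for a0, a1, b0, b1, n_match, length in _extend_on_diagonals(ea, eb, a_pos, b_pos, word, min_matches):
        score = n_match * MATCH_SCORE - (length - n_match) * MISMATCH_PENALTY
        ev = _segment_evalue(score, la, lb)
        if ev <= evalue_max:
            hsps.append(HSP(a0 + 1, a1 + 1, b0 + 1, b1 + 1, "+", n_match, length, score, ev))

    # reverse strand: align a against revcomp(b), map coordinates back
    erb = _encode(revcomp(sb))
    a_pos, b_pos = _word_matches(aw, _words(erb, word))
    for a0, a1, b0, b1, n_match, length in _extend_on_diagonals(ea, erb, a_pos, b_pos, word, min_matches):
        score = n_match * MATCH_SCORE - (length - n_match) * MISMATCH_PENALTY
        ev = _segment_evalue(score, la, lb)
        if ev <= evalue_max:
            hsps.append(HSP(a0 + 1, a1 + 1, lb - b1, lb - b0, "-", n_match, length, score, ev))

    hsps.sort(key=lambda h: (h.a_start, h.a_end, h.b_start))
    return hsps


def _interval_union(intervals: Iterable[tuple[int, int]]) -> int:
    merged = 0
    last_end = 0
    for start, end in sorted(intervals):
        if start > last_end:
            merged += end - start + 1
            last_end = end
        elif end > last_end:
            merged += end - last_end
            last_end = end
    return merged


def summarize_pair(a: GenomeRecord, b: GenomeRecord,
                   hsps: Sequence[HSP] | None = None,
                   word: int = 11, evalue_max: float = 1e-5,
                   snp_coverage_min: float = 95.0) -> PairwiseNucSummary:
    """Identity / span-coverage summary of a genome pair.

    Identity is the alignment-length-weighted mean over retained HSPs;
    coverage is the union of HSP spans on the *shorter* genome divided by
    its length.  ``snp_count`` is populated only for near-collinear pairs
    (coverage >= ``snp_coverage_min``), where a substitution count is
    meaningful.
    """
    if hsps is None:
        hsps = seed_extend_align(a, b, word=word, evalue_max=evalue_max)
    hsps = list(hsps)
    if not hsps:
        return PairwiseNucSummary(a.id, b.id, 0.0, 0.0, [])
    total_len = sum(h.alignment_length for h in hsps)
    total_match = sum(h.matches for h in hsps)
    identity = 100.0 * total_match / total_len
    shorter_is_a = a.length_bp <= b.length_bp
    spans = [(h.a_start, h.a_end) if shorter_is_a else (min(h.b_start, h.b_end), max(h.b_start, h.b_end))
             for h in hsps]
    shorter_len = min(a.length_bp, b.length_bp)
    coverage = min(100.0, 100.0 * _interval_union(spans) / shorter_len)
    identity = min(100.0, identity)
    snp_count = None
    if coverage >= snp_coverage_min:
        snp_count = count_snps(a, b, _coverage=coverage)
    return PairwiseNucSummary(a.id, b.id, identity, coverage, hsps, snp_count)


def collinear_differences(a: GenomeRecord | str, b: GenomeRecord | str) -> dict[str, int]:
    """Substitution columns and indel events in the global alignment of two
    near-collinear sequences (edit-distance alignment)."""
    sa = a.sequence if isinstance(a, GenomeRecord) else a
    sb = b.sequence if isinstance(b, GenomeRecord) else b
    res = edlib.align(sa, sb, task="path")
    nice = edlib.getNiceAlignment(res, sa, sb)
    qa, ta = nice["query_aligned"], nice["target_aligned"]
    snps = sum(1 for x, y in zip(qa, ta) if x != y and x != "-" and y != "-")
    indel_events = 0
    in_gap = False
    for x, y in zip(qa, ta):
        gap = x == "-" or y == "-"
        if gap and not in_gap:
            indel_events += 1
        in_gap = gap
    return {"snp_count": snps, "indel_events": indel_events,
            "edit_distance": res["editDistance"]}


def count_snps(a: GenomeRecord, b: GenomeRecord, hsps: Sequence[HSP] | None = None,
               coverage_min: float = 95.0, _coverage: float | None = None) -> int:
    """Number of substitution columns between two near-collinear genomes.

    Indel columns are not counted as SNPs (see :func:`collinear_differences`
    for the indel-event count).  Raises for a low-coverage pair, directing
    the caller to :func:`summarize_pair`.
    """
    if _coverage is None:
        summary = summarize_pair(a, b, hsps=hsps, snp_coverage_min=math.inf)
        _coverage = summary.coverage_percent
    if _coverage < coverage_min:
        raise ValueError(
            f"{a.id} vs {b.id}: span coverage {_coverage:.1f}% < {coverage_min}%; "
            "SNP counting is only meaningful for near-collinear pairs — "
            "use summarize_pair for diverged genomes"
        )
    return collinear_differences(a, b)["snp_count"]


def dotplot(a: GenomeRecord | str, b: GenomeRecord | str, word: int = 10,
            max_points: int | None = None) -> DotplotMatch:
    """Exact-word dotplot: every forward and reverse-complement ``word``-mer
    match (1-based word start positions).

    Optional down-sampling to ``max_points`` keeps every main-diagonal
    self-match so a self-comparison always renders its diagonal.
    """
    if word < 4:
        raise ValueError("word length must be >= 4")
    sa = a.sequence if isinstance(a, GenomeRecord) else a
    sb = b.sequence if isinstance(b, GenomeRecord) else b
    ea, eb = _encode(sa), _encode(sb)
    aw = _words(ea, word)
    matches: list[tuple[int, int, str]] = []
    a_pos, b_pos = _word_matches(aw, _words(eb, word))
    matches.extend((int(x) + 1, int(y) + 1, "+") for x, y in zip(a_pos, b_pos))
    lb = len(sb)
    a_pos, b_pos = _word_matches(aw, _words(_encode(revcomp(sb)), word))
    matches.extend((int(x) + 1, int(lb - y - word + 1), "-") for x, y in zip(a_pos, b_pos))
    matches.sort()
    if max_points is not None and len(matches) > max_points:
        diagonal = [m for m in matches if m[2] == "+" and m[0] == m[1]]
        rest = [m for m in matches if not (m[2] == "+" and m[0] == m[1])]
        keep = max(0, max_points - len(diagonal))
        stride = max(1, len(rest) // keep) if keep else len(rest) + 1
        matches = sorted(diagonal + rest[::stride])
    return DotplotMatch(word_length=word, matches=matches)


def assign_clusters(summaries: Sequence[PairwiseNucSummary],
                    span_threshold: float = 50.0,
                    identity_threshold: float = 80.0) -> ClusterAssignment:
    """Single-linkage clustering over the relation
    {span coverage >= span_threshold AND identity >= identity_threshold}.

    Span coverage is the primary criterion; identity acts as a secondary
    guard.  Cluster labels ("A", "B", ...) are assigned in order of each
    cluster's lexicographically smallest member, so the result is invariant
    to input order.  A missing genome pair raises an error listing it.
    """
    genomes = sorted({s.genome_a for s in summaries} | {s.genome_b for s in summaries})
    seen = {frozenset((s.genome_a, s.genome_b)) for s in summaries}
    missing = [(x, y) for i, x in enumerate(genomes) for y in genomes[i + 1 :]
               if frozenset((x, y)) not in seen]
    if missing:
        raise ValueError(f"missing pairwise summaries for: {missing}")

    parent = {g: g for g in genomes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for s in summaries:
        if s.genome_a == s.genome_b:
            continue
        if s.coverage_percent >= span_threshold and s.identity_percent >= identity_threshold:
            ra, rb = find(s.genome_a), find(s.genome_b)
            if ra != rb:
                parent[rb] = ra
    groups: dict[str, list[str]] = {}
    for g in genomes:
        groups.setdefault(find(g), []).append(g)
    ordered = sorted(groups.values(), key=lambda members: min(members))
    labels: dict[str, str] = {}
    for k, members in enumerate(ordered):
        label = chr(ord("A") + k) if k < 26 else f"C{k + 1}"
        for g in members:
            labels[g] = label
    return ClusterAssignment(labels=labels, span_threshold=span_threshold,
                             identity_threshold=identity_threshold)


def write_summary_table(summaries: Sequence[PairwiseNucSummary], path: str | Path) -> None:
    """Pairwise TSV: identity, coverage, HSP count, SNP count (when defined)."""
    with open(path, "w") as fh:
        fh.write("genome_a\tgenome_b\tidentity_percent\tcoverage_percent\tn_hsps\tsnp_count\n")
        for s in summaries:
            snp = "" if s.snp_count is None else str(s.snp_count)
            fh.write(f"{s.genome_a}\t{s.genome_b}\t{s.identity_percent:.2f}\t"
                     f"{s.coverage_percent:.2f}\t{len(s.hsps)}\t{snp}\n")
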