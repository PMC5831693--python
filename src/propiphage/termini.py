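"""Physical genome-end (cos site) detection from read-start pileups.

Linear phage DNA with cohesive ends produces two diagnostic signals in a
read alignment: a large pileup of plus-strand read starts at the 5'
terminus of the top strand, a matching pileup of minus-strand read starts
(their 5' ends) at the 5' terminus of the bottom strand, and — between the
two pileup positions, walking circularly — a short region of depressed
total coverage corresponding to the single-stranded overhang, which only
one strand of the virion DNA spans.

Coordinate convention (see :mod:`propiphage.core_io`): the stored sequence
is the full virion top strand.  For a genome of length ``L`` with a
``o``-base 3' extension, the top strand occupies ``1..L``, the bottom
strand ``1..L-o`` (its own 3' tail hangs off coordinate 1 and is the
complement of ``L-o+1..L``).  Hence, in the canonical deposit, plus starts
pile at position 1, minus starts pile at ``L-o``, and positions
``L-o+1..L`` are covered at roughly half depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from propiphage.core_io import GenomeRecord, ReadStartProfile


@dataclass
class TerminusCall:
    """Physical genome ends and single-stranded overhang inferred from reads.

    ``left_end`` is the 5'-terminal coordinate of the top strand (the
    plus-strand pileup position); ``right_end`` its 3'-terminal coordinate.
    ``defined_ends`` is False for profiles with no pileup (circularly
    permuted / pac-type packaging is indistinct from this signal).
    """

    defined_ends: bool
    left_end: int | None = None
    right_end: int | None = None
    overhang_length: int = 0
    overhang_sequence: str = ""
    overhang_polarity: str | None = None  # "3prime" | "5prime"
    buildup_ratios: tuple[float, float] = (0.0, 0.0)
    minus_peak: int | None = None

    def __post_init__(self) -> None:
        if self.defined_ends:
            if self.overhang_sequence and len(self.overhang_sequence) != self.overhang_length:
                raise ValueError("overhang_length must equal len(overhang_sequence)")
            if self.overhang_polarity not in ("3prime", "5prime", None):
                raise ValueError("overhang_polarity must be 3prime or 5prime")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _peak(starts: np.ndarray, min_buildup: float, strand: str) -> tuple[int | None, float]:
    """Index of the unique pileup position exceeding the threshold.

    Returns (0-based index or None, fold-enrichment at the peak).  Two
    separated super-threshold pileups on one strand are ambiguous and raise.
    """
    # Median start rate over the bulk of the genome; floored at 1 read so the
    # enrichment ratio is defined for sparse profiles.
    baseline = max(float(np.median(starts)), 1.0)
    threshold = min_buildup * baseline
    candidates = np.nonzero(starts >= threshold)[0]
    if len(candidates) == 0:
        return None, float(starts.max()) / baseline if len(starts) else 0.0
    # Tolerate a little ragged-end jitter: candidates within 3 bp of the
    # strongest one belong to the same pileup.
    best = candidates[np.argmax(starts[candidates])]
    distant = candidates[np.abs(candidates - best) > 3]
    if len(distant):
        raise ValueError(
            f"two read-start buildups on the {strand} strand at positions "
            f"{int(best) + 1} and {int(distant[0]) + 1}; cannot call a unique terminus"
        )
    return int(best), float(starts[best]) / baseline


def detect_cos_ends(profile: ReadStartProfile, genome: GenomeRecord | None = None,
                    min_buildup: float = 20.0, max_overhang: int = 50,
                    low_coverage_fraction: float = 0.75) -> TerminusCall:
    """Deduce cos-type genome ends from read-start buildups.

    A terminus is called when one plus-strand and one minus-strand position
    each show a start pileup at least ``min_buildup``-fold above the median
    per-position start rate of that strand.  The circular interval between
    the two pileups whose total coverage is depressed (below
    ``low_coverage_fraction`` of the median depth) is the single-stranded
    overhang; it must not exceed ``max_overhang``.  Polarity is ``3prime``
    when the depressed interval runs from the minus pileup forward to the
    plus pileup (the overhang lies 3' of each strand's double-stranded
    span), ``5prime`` in the opposite arrangement.

    No super-threshold pileup on either strand yields a "no defined ends"
    call (not an exception); two separated pileups on one strand raise.
    """
    L = len(profile)
    plus_peak, plus_ratio = _peak(profile.plus_starts, min_buildup, "plus")
    minus_peak, minus_ratio = _peak(profile.minus_starts, min_buildup, "minus")
    if plus_peak is None or minus_peak is None:
        return TerminusCall(defined_ends=False, buildup_ratios=(plus_ratio, minus_ratio))

    median_depth = max(float(np.median(profile.depth)), 1.0)

    def gap_stats(lo: int, hi_exclusive: int) -> tuple[int, float]:
        """Circular open interval (lo, hi) between the peaks: length, mean depth."""
        length = (hi_exclusive - lo - 1) % L
        if length == 0:
            return 0, median_depth
        idx = (np.arange(lo + 1, lo + 1 + length)) % L
        return length, float(profile.depth[idx].mean())

    # candidate overhang between minus pileup and plus pileup (3' layout) …
    len3, depth3 = gap_stats(minus_peak, plus_peak)
    # … or between plus pileup and minus pileup (5' layout)
    len5, depth5 = gap_stats(plus_peak, minus_peak)

    three_ok = 0 < len3 <= max_overhang and depth3 < low_coverage_fraction * median_depth
    five_ok = 0 < len5 <= max_overhang and depth5 < low_coverage_fraction * median_depth
    if three_ok:
        polarity, overhang_len = "3prime", len3
    elif five_ok:
        polarity, overhang_len = "5prime", len5
    elif len3 == 0 or len5 == 0:
        polarity, overhang_len = "3prime", 0  # blunt ends: pileups adjacent
    else:
        return TerminusCall(defined_ends=False, buildup_ratios=(plus_ratio, minus_ratio))

    left_end = plus_peak + 1  # 1-based top-strand 5' terminus
    right_end = (plus_peak - 1) % L + 1  # circularly one before the 5' terminus
    overhang_seq = ""
    if genome is not None and overhang_len:
        if genome.length_bp != L:
            raise ValueError("profile length does not match genome length")
        if polarity == "3prime":
            idx = [(minus_peak + 1 + k) % L for k in range(overhang_len)]
        else:
            idx = [(plus_peak + 1 + k) % L for k in range(overhang_len)]
        overhang_seq = "".join(genome.sequence[i] for i in idx)
    return TerminusCall(
        defined_ends=True,
        left_end=left_end,
        right_end=right_end,
        overhang_length=overhang_len,
        overhang_sequence=overhang_seq,
        overhang_polarity=polarity,
        buildup_ratios=(plus_ratio, minus_ratio),
        minus_peak=minus_peak + 1,
    )


def extract_overhang(genome: GenomeRecord, call: TerminusCall) -> str:
    """Single-stranded overhang in 5'->3' orientation of the strand carrying it.

    For a 3' overhang in the canonical deposit this is the top strand's
    terminal ``overhang_length`` bases read as stored.
    """
    if not call.defined_ends or call.overhang_length == 0:
        return ""
    if call.minus_peak is None or call.left_end is None:
        raise ValueError("terminus call carries no peak coordinates")
    L = genome.length_bp
    if not (1 <= call.left_end <= L and 1 <= call.minus_peak <= L):
        raise ValueError("terminus call coordinates lie outside the genome")
    start0 = call.minus_peak if call.overhang_polarity == "3prime" else call.left_end
    idx = [(start0 + k) % L for k in range(call.overhang_length)]
    return "".join(genome.sequence[i] for i in idx)
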