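"""Repeat–spacer array extraction, orientation, divergence and hairpin stems.

The array is found by consensus-anchored search: the user supplies the direct
repeat consensus (21–47 bp, the canonical CRISPR repeat size range) and the
module locates its approximate occurrences, chains consecutive occurrences
whose gaps are spacer-sized into an array, orients the array by the AT-richer
flank (the leader, where new spacers are inserted), and numbers spacers
trailer-first, so spacer #1 is the oldest spacer, farthest from the leader.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError
from .genome_io import GenomeRecord, revcomp

REPEAT_LENGTH_BAND = (21, 47)
DEFAULT_SPACER_BAND = (21, 47)


@dataclass(frozen=True)
class RepeatConsensus:
    """The direct-repeat consensus sequence of a CRISPR locus."""

    seq: str

    def __post_init__(self) -> None:
        lo, hi = REPEAT_LENGTH_BAND
        if not (lo <= len(self.seq) <= hi):
            raise ParameterError(
                f"repeat consensus length {len(self.seq)} outside [{lo}, {hi}]"
            )
        if set(self.seq) - set("ACGT"):
            raise ParameterError("repeat consensus must be over {A,C,G,T}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RepeatUnit:
    """One repeat copy: 0-based half-open interval plus consensus distance."""

    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class Spacer:
    seq: str
    start: int
    end: int


@dataclass
class CrisprArray:
    """An ordered repeat–spacer array on one contig.

    ``spacers`` are in genome (left-to-right) order; ``spacer_numbers`` holds
    the trailer-first number of each spacer in the same order, so
    ``spacer_numbers[i] == 1`` marks the trailer-end (oldest) spacer.
    """

    genome_id: str
    repeats: list[RepeatUnit]
    spacers: list[Spacer]
    leader_side: str = "undetermined"  # {left, right, undetermined}
    spacer_numbers: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.repeats) != len(self.spacers) + 1:
            raise ParameterError(
                f"array must satisfy repeats = spacers + 1 "
                f"({len(self.repeats)} vs {len(self.spacers)})"
            )
        if not self.spacer_numbers:
            self.spacer_numbers = list(range(1, len(self.spacers) + 1))

    @property
    def span(self) -> tuple[int, int]:
        return self.repeats[0].start, self.repeats[-1].end

    def spacer_by_number(self, number: int) -> Spacer:
        return self.spacers[self.spacer_numbers.index(number)]


@dataclass(frozen=True)
class HairpinStem:
    """A perfect Watson–Crick stem within a repeat (intervals are repeat-local)."""

    arm1: tuple[int, int]
    arm2: tuple[int, int]
    stem_len: int
    loop_len: int


@dataclass
class ArrayBuildResult:
    array: Optional[CrisprArray]
    unchained: list[RepeatUnit]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_repeat_occurrences(
    genome: GenomeRecord,
    consensus: RepeatConsensus,
    max_mm_per_copy: int = 6,
) -> list[RepeatUnit]:
    """All forward-strand ungapped occurrences of the consensus.

    Every offset where the Hamming distance to the consensus is at most
    ``max_mm_per_copy`` is reported; overlapping occurrences are resolved
    greedily left-to-right, keeping the lower-mismatch one.
    """
    g = _encode(genome.seq)
    c = _encode(consensus.seq)
    L = len(c)
    n = len(g) - L + 1
    if n <= 0:
        return []
    mm = np.zeros(n, dtype=np.int32)
    for j in range(L):
        mm += g[j:j + n] != c[j]
    positions = np.nonzero(mm <= max_mm_per_copy)[0]
    kept: list[RepeatUnit] = []
    for pos in positions:
        unit = RepeatUnit(start=int(pos), end=int(pos) + L, mismatches=int(mm[pos]))
        if kept and unit.start < kept[-1].end:
            if unit.mismatches < kept[-1].mismatches:
                kept[-1] = unit
            continue
        kept.append(unit)
    return kept


def build_array(
    units: Sequence[RepeatUnit],
    genome: GenomeRecord,
    spacer_band: tuple[int, int] = DEFAULT_SPACER_BAND,
) -> ArrayBuildResult:
    """Chain consecutive repeat units with spacer-sized gaps into an array.

    The longest chain (leftmost on ties) of at least two units becomes the
    array; its gaps become spacers. Units outside the chosen chain are
    returned as ``unchained``. Fewer than two chainable units yields
    ``array=None`` rather than an exception.
    """
    units = sorted(units, key=lambda u: u.start)
    lo, hi = spacer_band
    # runs[i] = index list of a maximal chain starting at units[i]
    best: list[int] = []
    i = 0
    runs: list[list[int]] = []
    while i < len(units):
        run = [i]
        while run[-1] + 1 < len(units):
            gap = units[run[-1] + 1].start - units[run[-1]].end
            if lo <= gap <= hi:
                run.append(run[-1] + 1)
            else:
                break
        runs.append(run)
        i = run[-1] + 1
    for run in runs:
        if len(run) > len(best):
            best = run
    if len(best) < 2:
        return ArrayBuildResult(array=None, unchained=list(units))
    chain = [units[j] for j in best]
    spacers = [
        Spacer(seq=genome.seq[a.end:b.start], start=a.end, end=b.start)
        for a, b in zip(chain, chain[1:])
    ]
    in_chain = set(best)
    unchained = [u for j, u in enumerate(units) if j not in in_chain]
    return ArrayBuildResult(
        array=CrisprArray(genome_id=genome.id, repeats=chain, spacers=spacers),
        unchained=unchained,
    )


def _at_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("A") + seq.count("T")) / len(seq)


def orient_and_number(
    array: CrisprArray,
    genome: GenomeRecord,
    flank_window: int = 150,
    tie_margin: float = 0.02,
) -> CrisprArray:
    """Assign the leader side by flank AT-richness and renumber trailer-first.

    The leader is the flank (a ``flank_window``-bp window beyond the terminal
    repeats) with the higher A+T fraction; spacer #1 is the spacer at the
    opposite (trailer) end. When the two flank AT fractions differ by less
    than ``tie_margin`` the orientation is left undetermined, numbering
    follows genome order, and a warning is issued. Flanks truncated by a
    contig edge are scored on the available bases.
    """
    start, end = array.span
    left = genome.seq[max(0, start - flank_window):start]
    right = genome.seq[end:end + flank_window]
    at_left, at_right = _at_fraction(left), _at_fraction(right)
    n = len(array.spacers)
    if abs(at_left - at_right) < tie_margin:
        warnings.warn(
            f"{genome.id}: flank AT fractions {at_left:.3f}/{at_right:.3f} "
            "within tie margin; leader undetermined, numbering in genome order"
        )
        return replace_array(array, leader_side="undetermined",
                             spacer_numbers=list(range(1, n + 1)))
    if at_left > at_right:
        # leader left => trailer right => rightmost spacer is #1
        numbers = list(range(n, 0, -1))
        side = "left"
    else:
        numbers = list(range(1, n + 1))
        side = "right"
    return replace_array(array, leader_side=side, spacer_numbers=numbers)


def replace_array(array: CrisprArray, **kw) -> CrisprArray:
    new = CrisprArray(
        genome_id=array.genome_id,
        repeats=list(array.repeats),
        spacers=list(array.spacers),
        leader_side=kw.get("leader_side", array.leader_side),
        spacer_numbers=list(kw.get("spacer_numbers", array.spacer_numbers)),
    )
    return new


@dataclass(frozen=True)
class RepeatDivergence:
    repeat_index: int
    mismatches: int
    alignment: str  # '|' match, '*' mismatch, per consensus column
    flanks_spacer1: bool


def repeat_divergence(
    array: CrisprArray,
    consensus: RepeatConsensus,
    genome: GenomeRecord,
) -> list[RepeatDivergence]:
    """Per-repeat Hamming distance to the consensus.

    The two repeats flanking spacer #1 (the trailer-end spacer) are flagged:
    elevated divergence there is the classic signature of a poorly processed,
    tolerated self-targeting spacer.
    """
    sp1 = array.spacer_by_number(1)
    flanking = {
        i for i, r in enumerate(array.repeats)
        if r.end == sp1.start or r.start == sp1.end
    }
    out: list[RepeatDivergence] = []
    for i, unit in enumerate(array.repeats):
        seq = genome.seq[unit.start:unit.end]
        aln = "".join("|" if a == b else "*" for a, b in zip(seq, consensus.seq))
        out.append(RepeatDivergence(
            repeat_index=i,
            mismatches=aln.count("*"),
            alignment=aln,
            flanks_spacer1=i in flanking,
        ))
    return out


def find_hairpin(repeat_seq: str, min_stem: int = 4, min_loop: int = 2
                 ) -> Optional[HairpinStem]:
    """Longest perfect inverted repeat (hairpin stem) within a repeat.

    Among all pairs of non-overlapping intervals (arm1 before arm2, separated
    by at least ``min_loop`` bases) where arm2 is the exact Watson–Crick
    reverse complement of arm1, returns the longest stem; ties broken by the
    smallest loop, then the leftmost arm1. Only A:T and G:C pairs count (no
    wobble pairs, no N). Returns ``None`` when no stem of at least
    ``min_stem`` exists.
    """
    L = len(repeat_seq)
    max_stem = (L - min_loop) // 2
    for s in range(max_stem, min_stem - 1, -1):
        best: Optional[HairpinStem] = None
        for i in range(0, L - 2 * s - min_loop + 1):
            arm = repeat_seq[i:i + s]
            if "N" in arm:
                continue
            rc = revcomp(arm)
            for j in range(i + s + min_loop, L - s + 1):
                if repeat_seq[j:j + s] == rc:
                    cand = HairpinStem(arm1=(i, i + s), arm2=(j, j + s),
                                       stem_len=s, loop_len=j - (i + s))
                    if best is None or (cand.loop_len, cand.arm1[0]) < (
                            best.loop_len, best.arm1[0]):
                        best = cand
        if best is not None:
            return best
    return None


def array_report_rows(array: CrisprArray, divergence: list[RepeatDivergence]
                      ) -> list[dict]:
    """Flat rows for the TSV array report (1-based inclusive coordinates)."""
    rows = []
    for i, unit in enumerate(array.repeats):
        row = {
            "record_type": "repeat",
            "repeat_index": i,
            "start_1based": unit.start + 1,
            "end": unit.end,
            "mismatches": divergence[i].mismatches if divergence else unit.mismatches,
            "spacer_number": "",
            "spacer_seq": "",
        }
        rows.append(row)
        if i < len(array.spacers):
            sp = array.spacers[i]
            rows.append({
                "record_type": "spacer",
                "repeat_index": "",
                "start_1based": sp.start + 1,
                "end": sp.end,
                "mismatches": "",
                "spacer_number": array.spacer_numbers[i],
                "spacer_seq": sp.seq,
            })
    return rows
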