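"""Seeded mismatch search of CRISPR spacers against target genomes.

The sensitivity criterion mirrors a BLASTN run at the minimum word size:
a hit is a full-length ungapped alignment of the spacer with at most ``k``
mismatches that also contains at least one exact ``w``-mer seed (default
w=7, k=5 — the classic "five or fewer mismatches out of 32 bases"
significance rule for 32-bp spacers). The exact-seed requirement reproduces
the word-size sensitivity floor of a seeded aligner rather than guaranteeing
full Hamming-ball completeness; for L=32, w=7 it is automatically satisfied
whenever k <= 3, and is part of the defined criterion for k=4,5.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .crispr_array import CrisprArray
from .errors import ParameterError
from .genome_io import CdsFeature, GenomeRecord, revcomp

CATEGORY_OWN_ARRAY = "inside_own_array"
CATEGORY_SPACER_SPACER = "spacer_spacer"
CATEGORY_PROTO_SPACER = "proto_spacer_in_cds"
CATEGORY_INTERGENIC = "intergenic"


@dataclass(frozen=True)
class SearchParams:
    """Seeded-search sensitivity settings."""

    word_size: int = 7
    max_mismatches: int = 5
    allow_bulge: bool = False
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.word_size < 1:
            raise ParameterError("word_size must be >= 1")
        if self.max_mismatches < 0:
            raise ParameterError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class Bulge:
    """A single-base bulge in a spacer/target alignment."""

    kind: str  # {insertion_in_target, insertion_in_spacer}
    position: int


@dataclass
class SpacerHit:
    """One ungapped alignment of a spacer to a genome interval."""

    genome_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    spacer_number: Optional[int] = None
    bulge: Optional[Bulge] = None
    pam: Optional[str] = None
    category: Optional[str] = None
    gene_id: Optional[str] = None


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    pos = haystack.find(needle)
    while pos != -1:
        out.append(pos)
        pos = haystack.find(needle, pos + 1)
    return out


def seeded_search(
    spacer: str,
    genome: GenomeRecord,
    params: SearchParams = SearchParams(),
    spacer_number: Optional[int] = None,
) -> list[SpacerHit]:
    """All seeded, full-length ungapped matches of ``spacer`` in ``genome``.

    Every genome position (both strands when configured) where the spacer
    aligns full-length with at most ``params.max_mismatches`` mismatches and
    the alignment contains at least one exact ``word_size``-mer is reported,
    deduplicated by (interval, strand) and sorted by mismatches then position.
    A minus-strand hit means the proto-spacer lies on the reverse strand of
    the reported forward-strand interval.
    """
    w, k = params.word_size, params.max_mismatches
    L = len(spacer)
    if L < w:
        raise ParameterError(f"spacer length {L} shorter than word size {w}")
    gseq = genome.seq
    strands = ("+", "-") if params.both_strands else ("+",)
    hits: dict[tuple[int, str], SpacerHit] = {}
    for strand in strands:
        query = spacer if strand == "+" else revcomp(spacer)
        seen_offsets: set[int] = set()
        for p in range(L - w + 1):
            word = query[p:p + w]
            for gpos in _find_all(gseq, word):
                offset = gpos - p
                if offset < 0 or offset + L > len(gseq) or offset in seen_offsets:
                    continue
                seen_offsets.add(offset)
                mm = _hamming(query, gseq[offset:offset + L])
                if mm <= k:
                    hits[(offset, strand)] = SpacerHit(
                        genome_id=genome.id, start=offset, end=offset + L,
                        strand=strand, mismatches=mm, spacer_number=spacer_number,
                    )
    return sorted(hits.values(), key=lambda h: (h.mismatches, h.start, h.strand))


def align_with_bulge(spacer: str, target_window: str
                     ) -> tuple[int, Optional[Bulge]]:
    """Best ungapped-or-one-bulge alignment of spacer vs a target window.

    When the lengths are equal the alignment is plain Hamming (no bulge).
    When the target is one base longer, every single-base deletion of the
    target is tried (``insertion_in_target``); one base shorter, every
    single-base deletion of the spacer (``insertion_in_spacer``). Returns the
    minimum mismatch count and the leftmost bulge position achieving it.
    """
    dlen = len(target_window) - len(spacer)
    if abs(dlen) > 1:
        raise ParameterError(
            f"length difference {dlen} exceeds the single-bulge model"
        )
    if dlen == 0:
        return _hamming(spacer, target_window), None
    if dlen == 1:
        longer, shorter, kind = target_window, spacer, "insertion_in_target"
    else:
        longer, shorter, kind = spacer, target_window, "insertion_in_spacer"
    best_mm, best_pos = len(shorter) + 1, -1
    for i in range(len(longer)):
        mm = _hamming(shorter, longer[:i] + longer[i + 1:])
        if mm < best_mm:
            best_mm, best_pos = mm, i
    return best_mm, Bulge(kind=kind, position=best_pos)


def extract_pam(hit: SpacerHit, genome: GenomeRecord,
                side: str = "3prime", length: int = 3) -> str:
    """Proto-spacer-adjacent motif: bases flanking the hit on its own strand.

    Default is the ``length`` bases immediately 3' of the proto-spacer (the
    convention for cluster-2 repeats, whose captured proto-spacers are
    followed by CTT). For a minus-strand hit the 3' flank lies 5' of the
    interval on the forward strand and is reverse-complemented. At a contig
    edge the missing bases are padded with N.
    """
    if side not in {"3prime", "5prime"}:
        raise ParameterError("side must be '3prime' or '5prime'")
    downstream = (side == "3prime") == (hit.strand == "+")
    gseq = genome.seq
    if downstream:
        raw = gseq[hit.end:hit.end + length]
        raw = raw + "N" * (length - len(raw))
    else:
        lo = max(0, hit.start - length)
        raw = gseq[lo:hit.start]
        raw = "N" * (length - len(raw)) + raw
    return raw if hit.strand == "+" else revcomp(raw)


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def classify_hit(
    hit: SpacerHit,
    array: Optional[CrisprArray],
    cds_features: Sequence[CdsFeature],
) -> SpacerHit:
    """Assign a category (and gene id) to a hit on the array's own genome.

    A hit overlapping the query's own array is ``inside_own_array``, except
    that a hit lying within the interval of a *different* spacer is
    ``spacer_spacer`` (a spacer matching another spacer of the same locus).
    Outside the array, a hit overlapping a CDS is ``proto_spacer_in_cds``
    with that gene id; anything else is ``intergenic``.
    """
    category, gene_id = CATEGORY_INTERGENIC, None
    if array is not None and array.genome_id == hit.genome_id:
        a_start, a_end = array.span
        if _overlaps(hit.start, hit.end, a_start, a_end):
            category = CATEGORY_OWN_ARRAY
            for sp, number in zip(array.spacers, array.spacer_numbers):
                if (sp.start <= hit.start and hit.end <= sp.end
                        and number != hit.spacer_number):
                    category = CATEGORY_SPACER_SPACER
                    break
            hit.category = category
            return hit
    for feat in cds_features:
        if feat.contig_id == hit.genome_id and _overlaps(
                hit.start, hit.end, feat.start, feat.end):
            category, gene_id = CATEGORY_PROTO_SPACER, feat.gene_id
            break
    hit.category = category
    hit.gene_id = gene_id
    return hit


def search_array_spacers(
    array: CrisprArray,
    genome: GenomeRecord,
    cds_features: Sequence[CdsFeature],
    params: SearchParams = SearchParams(),
    pam_length: int = 3,
) -> list[SpacerHit]:
    """Search every spacer of an array against a genome and annotate hits.

    Convenience pipeline step: runs :func:`seeded_search` for each spacer,
    classifies each hit against the array and CDS features, and extracts the
    3' PAM. Self-hits of a spacer to its own array position are reported
    (category ``inside_own_array``), not suppressed, so whole-genome hit
    accounting is reproducible.
    """
    all_hits: list[SpacerHit] = []
    for sp, number in zip(array.spacers, array.spacer_numbers):
        for hit in seeded_search(sp.seq, genome, params, spacer_number=number):
            hit = classify_hit(hit, array, cds_features)
            hit.pam = extract_pam(hit, genome, length=pam_length)
            all_hits.append(hit)
    all_hits.sort(key=lambda h: (h.spacer_number or 0, h.mismatches, h.start))
    return all_hits


def hit_report_rows(hits: Sequence[SpacerHit]) -> list[dict]:
    """Flat rows for the TSV hit report (1-based inclusive coordinates)."""
    rows = []
    for h in hits:
        rows.append({
            "spacer_number": h.spacer_number,
            "genome": h.genome_id,
            "start_1based": h.start + 1,
            "end": h.end,
            "strand": h.strand,
            "mismatches": h.mismatches,
            "bulge": f"{h.bulge.kind}@{h.bulge.position}" if h.bulge else "none",
            "pam": h.pam or "",
            "category": h.category or "",
            "gene_id": h.gene_id or "",
        })
    return rows
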