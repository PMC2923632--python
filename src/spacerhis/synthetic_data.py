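"""Synthetic genomes, proteomes and family tables with known ground truth.

The generator emulates the study conditions end to end: a bacterial genome
carrying a planted repeat–spacer array (default 112 repeat copies of a 29-bp
consensus separated by 32-bp spacers, per-copy substitutions, an AT-rich
leader on one side), with the trailer-most spacer (spacer #1 under
trailer-first numbering) copied verbatim from inside a planted CDS whose 3'
flank is the CTT proto-spacer-adjacent motif; and proteomes with a
controlled background histidine frequency plus a high-demand subclass of
genes carrying clustered histidines. A single integer seed drives one
documented pseudo-random stream; per-component substreams are spawned
deterministically so adding a generator does not shift the others.

Background sequence is i.i.d. with configurable GC and no repeat structure
beyond the planted array, which keeps the search oracle exact.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq as _Seq

from .comparative_screen import FamilyRow
from .errors import ConfigError
from .genome_io import CdsFeature, GenomeRecord, Proteome, revcomp

# The P. carbinolicus CRISPR direct repeat; default planted consensus.
PCAR_REPEAT = "GAGTTCCCCGCAGATGCGGGGATGAACCG"
# The G. sulfurreducens CRISPR2 direct repeat (close relative of the above).
GSU_CRISPR2_REPEAT = "GTGTTCCCCGCATGCGCGGGGATGAACCG"

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))

# NCBI table 11, stops excluded; used to pick codons for synthetic proteins.
_CODONS_BY_AA: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            if _codon in _STOPS:
                continue
            _aa = str(_Seq(_codon).translate(table=11))
            _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
_AA_NON_HIS = sorted(set(_CODONS_BY_AA) - {"H"})


@dataclass(frozen=True)
class ArraySpec:
    """Geometry and mutation settings of the planted repeat–spacer array."""

    n_repeats: int = 112
    consensus: str = PCAR_REPEAT
    per_copy_sub_prob: float = 0.02
    spacer_length: int = 32
    leader_side: str = "left"
    leader_at_fraction: float = 0.75
    leader_length: int = 150

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ConfigError("n_repeats must be >= 2")
        if not 0.0 <= self.per_copy_sub_prob <= 1.0:
            raise ConfigError("per_copy_sub_prob must be in [0, 1]")
        if not 0.0 <= self.leader_at_fraction <= 1.0:
            raise ConfigError("leader_at_fraction must be in [0, 1]")
        if self.leader_side not in {"left", "right"}:
            raise ConfigError("leader_side must be 'left' or 'right'")


@dataclass(frozen=True)
class ProtoSpacerSpec:
    """The planted self-target: a CDS containing one spacer's proto-spacer."""

    cds_length: int = 1203  # nucleotides including the stop codon
    pam: str = "CTT"
    cds_strand: str = "+"
    n_decoy_cds: int = 2

    def __post_init__(self) -> None:
        if self.cds_length % 3 != 0 or self.cds_length < 150:
            raise ConfigError("cds_length must be a multiple of 3 and >= 150")
        if self.cds_strand not in {"+", "-"}:
            raise ConfigError("cds_strand must be '+' or '-'")


@dataclass(frozen=True)
class ProteomeSpec:
    """Two-population histidine structure of a synthetic proteome."""

    n_proteins: int = 300
    mean_length: int = 300
    min_length: int = 60
    max_length: int = 3000
    background_his_prob: float = 0.0225
    n_high_demand: int = 10
    cluster_size: int = 6    # histidines per cluster
    cluster_gap: int = 1     # residue distance between clustered histidines
    target_his: int = 35     # clusters total at least this many histidines

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_his_prob <= 1.0:
            raise ConfigError("background_his_prob must be in [0, 1]")
        if self.cluster_size < 2:
            raise ConfigError("cluster_size must be >= 2")
        if self.cluster_gap < 1:
            raise ConfigError("cluster_gap must be >= 1")
        if self.n_high_demand > self.n_proteins:
            raise ConfigError("n_high_demand exceeds n_proteins")


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    genome_length: int = 60_000
    gc: float = 0.55
    array: ArraySpec = field(default_factory=ArraySpec)
    proto: ProtoSpacerSpec = field(default_factory=ProtoSpacerSpec)
    proteome: ProteomeSpec = field(default_factory=ProteomeSpec)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ConfigError("gc must be in [0, 1]")


@dataclass
class GenomeTruth:
    """Everything needed to verify array extraction and self-target search."""

    repeat_intervals: list[tuple[int, int]]
    repeat_mismatches: list[int]
    spacer_seqs: list[str]          # genome (left-to-right) order
    spacer_numbers: list[int]       # trailer-first numbers, genome order
    leader_side: str
    selftarget_spacer_number: int
    protospacer_interval: tuple[int, int]
    protospacer_strand: str
    protospacer_gene_id: str
    pam: str


@dataclass
class ProteomeTruth:
    high_demand_gene_ids: list[str]


@dataclass
class ProteomeBundle:
    """A synthetic proteome with its CDS sequences and truth labels."""

    proteome: Proteome
    cds_seqs: dict[str, str]
    truth: ProteomeTruth


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _mutate(rng: np.random.Generator, seq: str, p: float) -> tuple[str, int]:
    """Substitute each base independently with probability p; no indels."""
    chars = list(seq)
    n_sub = 0
    for i in range(len(chars)):
        if rng.random() < p:
            choices = [b for b in "ACGT" if b != chars[i]]
            chars[i] = choices[rng.integers(0, 3)]
            n_sub += 1
    return "".join(chars), n_sub


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + uniform non-stop codons + TAA."""
    codons = sorted(c for cs in _CODONS_BY_AA.values() for c in cs)
    body = [codons[rng.integers(0, len(codons))] for _ in range(n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def _plant_in_cds(rng: np.random.Generator, cds_len: int, insert: str
                  ) -> Optional[tuple[str, int]]:
    """Overwrite a CDS-internal window with ``insert``, keeping the frame clean.

    Returns (cds, offset) or None when an in-frame stop falls entirely inside
    the protected window (the caller then redraws the insert).
    """
    n_codons = cds_len // 3
    cds = list(_random_cds(rng, n_codons))
    lo, hi = 3, cds_len - 3 - len(insert)
    offset = int(rng.integers(lo, hi + 1))
    cds[offset:offset + len(insert)] = list(insert)
    protected = range(offset, offset + len(insert))
    for ci in range(1, n_codons - 1):
        codon = "".join(cds[3 * ci:3 * ci + 3])
        if codon not in _STOPS:
            continue
        free = [3 * ci + j for j in range(3) if 3 * ci + j not in protected]
        fixed = False
        for pos in free:
            j = pos - 3 * ci
            for b in "CG":
                cand = codon[:j] + b + codon[j + 1:]
                if cand not in _STOPS:
                    cds[pos] = b
                    fixed = True
                    break
            if fixed:
                break
        if not fixed:
            return None
    return "".join(cds), offset


def synth_genome(config: SynthConfig
                 ) -> tuple[GenomeRecord, list[CdsFeature], GenomeTruth]:
    """Generate a genome with a planted array and one self-targeting spacer.

    The trailer-most spacer is an exact copy of 32 bp inside a planted CDS
    whose 3' flank (on the CDS strand) is the configured PAM. Reproducible
    for a fixed seed.
    """
    a, pr = config.array, config.proto
    ss = np.random.SeedSequence(config.seed)
    rng_bg, rng_arr, rng_cds, rng_misc = (
        np.random.default_rng(c) for c in ss.spawn(4))
    rl = len(a.consensus)
    sl = a.spacer_length
    n_sp = a.n_repeats - 1
    array_len = a.n_repeats * rl + n_sp * sl
    cds_len = pr.cds_length
    decoy_len = 903
    margin = 500
    need = (margin + a.leader_length + array_len + margin + cds_len
            + pr.n_decoy_cds * (decoy_len + margin) + margin)
    if need > config.genome_length:
        raise ConfigError(
            f"genome_length {config.genome_length} too short for the planted "
            f"array and CDS layout (need >= {need})"
        )

    genome = list(_random_dna(rng_bg, config.genome_length, config.gc))

    # planted CDS with the proto-spacer followed by the PAM
    insert_len = sl + len(pr.pam)
    for _ in range(200):
        protospacer = _random_dna(rng_cds, sl, config.gc)
        planted = _plant_in_cds(rng_cds, cds_len, protospacer + pr.pam)
        if planted is not None:
            cds, proto_off = planted
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise ConfigError("could not plant a frame-clean proto-spacer")

    # spacers: random, except the trailer-most one which copies the proto-spacer
    spacers = [_random_dna(rng_arr, sl, config.gc) for _ in range(n_sp)]
    if a.leader_side == "left":
        trailer_idx = n_sp - 1             # trailer is the right end
        numbers = list(range(n_sp, 0, -1))
    else:
        trailer_idx = 0
        numbers = list(range(1, n_sp + 1))
    spacers[trailer_idx] = protospacer

    repeats: list[str] = []
    repeat_mm: list[int] = []
    for _ in range(a.n_repeats):
        seq, nm = _mutate(rng_arr, a.consensus, a.per_copy_sub_prob)
        repeats.append(seq)
        repeat_mm.append(nm)

    # layout: [bg | leader | array | bg | CDS | bg | decoys | bg]
    pos = margin
    if a.leader_side == "left":
        leader_start = pos
        array_start = leader_start + a.leader_length
    else:
        array_start = pos
        leader_start = array_start + array_len
    leader_seq = _random_dna(rng_misc, a.leader_length,
                             1.0 - a.leader_at_fraction)
    genome[leader_start:leader_start + a.leader_length] = list(leader_seq)

    cursor = array_start
    repeat_intervals: list[tuple[int, int]] = []
    spacer_seqs: list[str] = []
    for i, rep in enumerate(repeats):
        genome[cursor:cursor + rl] = list(rep)
        repeat_intervals.append((cursor, cursor + rl))
        cursor += rl
        if i < n_sp:
            genome[cursor:cursor + sl] = list(spacers[i])
            spacer_seqs.append(spacers[i])
            cursor += sl

    after_array = max(array_start + array_len, leader_start + a.leader_length)
    cds_start = after_array + margin
    fwd_cds = cds if pr.cds_strand == "+" else revcomp(cds)
    genome[cds_start:cds_start + cds_len] = list(fwd_cds)
    features = [CdsFeature(gene_id="cds0001", contig_id="synth_contig",
                           start=cds_start, end=cds_start + cds_len,
                           strand=pr.cds_strand)]
    if pr.cds_strand == "+":
        proto_start = cds_start + proto_off
    else:
        proto_start = cds_start + cds_len - (proto_off + sl)
    cursor = cds_start + cds_len + margin
    for d in range(pr.n_decoy_cds):
        decoy = _random_cds(rng_misc, decoy_len // 3)
        genome[cursor:cursor + decoy_len] = list(decoy)
        features.append(CdsFeature(
            gene_id=f"cds{d + 2:04d}", contig_id="synth_contig",
            start=cursor, end=cursor + decoy_len, strand="+"))
        cursor += decoy_len + margin

    record = GenomeRecord(id="synth_contig", seq="".join(genome))
    n_fwd = record.seq.count(protospacer)
    n_rev = record.seq.count(revcomp(protospacer))
    expected = (2, 0) if pr.cds_strand == "+" else (1, 1)
    if (n_fwd, n_rev) != expected:  # pragma: no cover - ~zero probability
        raise ConfigError("proto-spacer collided with background sequence")
    truth = GenomeTruth(
        repeat_intervals=repeat_intervals,
        repeat_mismatches=repeat_mm,
        spacer_seqs=spacer_seqs,
        spacer_numbers=numbers,
        leader_side=a.leader_side,
        selftarget_spacer_number=1,
        protospacer_interval=(proto_start, proto_start + sl),
        protospacer_strand=pr.cds_strand,
        protospacer_gene_id="cds0001",
        pam=pr.pam,
    )
    return record, features, truth


def _protein_and_cds(rng: np.random.Generator, length: int,
                     forced_his: set[int], p0: float) -> tuple[str, str]:
    """A protein of ``length`` residues plus a matching CDS (table 11).

    Residue 0 is M (ATG start). Positions in ``forced_his`` are H; every other
    position is H with probability ``p0``, else a uniform non-H residue.
    Histidine codons are drawn uniformly from {CAT, CAC}; a TAA stop is
    appended to the CDS only.
    """
    residues: list[str] = []
    for i in range(length):
        if i in forced_his:
            residues.append("H")
        elif i == 0:
            residues.append("M")
        elif rng.random() < p0:
            residues.append("H")
        else:
            residues.append(_AA_NON_HIS[rng.integers(0, len(_AA_NON_HIS))])
    codons: list[str] = []
    for aa in residues:
        opts = _CODONS_BY_AA[aa]
        codons.append(opts[rng.integers(0, len(opts))])
    return "".join(residues), "".join(codons) + "TAA"


def _cluster_positions(rng: np.random.Generator, length: int, n_clusters: int,
                       c: int, g: int) -> set[int]:
    span = (c - 1) * g + 1
    segment = (length - 1) // n_clusters
    if span + 2 > segment:
        raise ConfigError(
            f"protein length {length} too short for {n_clusters} clusters of "
            f"{c} histidines at gap {g}"
        )
    positions: set[int] = set()
    for k in range(n_clusters):
        lo = 1 + k * segment
        start = lo + int(rng.integers(0, segment - span - 1))
        positions.update(start + i * g for i in range(c))
    return positions


def synth_proteome(config: SynthConfig, genome_id: str = "synthP",
                   seed: Optional[int] = None) -> ProteomeBundle:
    """Generate a proteome with background and high-demand populations.

    Background genes draw histidine per residue with probability
    ``background_his_prob``; the first ``n_high_demand`` genes additionally
    carry ceil(target_his / cluster_size) clusters of ``cluster_size``
    histidines at residue gap ``cluster_gap`` (so h >= target_his and
    D is approximately h / cluster_gap).
    """
    p = config.proteome
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence([seed, zlib.crc32(genome_id.encode())])
    rng = np.random.default_rng(ss)
    n_clusters = math.ceil(p.target_his / p.cluster_size)
    span_needed = n_clusters * ((p.cluster_size - 1) * p.cluster_gap + 3) + 2
    if p.n_high_demand > 0 and span_needed > p.max_length:
        raise ConfigError(
            f"proteins of at most {p.max_length} residues are too short for "
            f"{n_clusters} cluster(s) of {p.cluster_size} histidines at gap "
            f"{p.cluster_gap}"
        )
    proteome = Proteome(genome_id=genome_id)
    cds_seqs: dict[str, str] = {}
    high_ids: list[str] = []
    for i in range(p.n_proteins):
        gid = f"{genome_id}_g{i:04d}"
        length = int(rng.gamma(4.0, p.mean_length / 4.0))
        length = max(length, p.min_length)
        forced: set[int] = set()
        if i < p.n_high_demand:
            length = max(length, span_needed)
            forced = _cluster_positions(rng, length, n_clusters,
                                        p.cluster_size, p.cluster_gap)
            high_ids.append(gid)
        protein, cds = _protein_and_cds(rng, length, forced,
                                        p.background_his_prob)
        proteome.proteins.append((gid, protein))
        cds_seqs[gid] = cds
    return ProteomeBundle(proteome=proteome, cds_seqs=cds_seqs,
                          truth=ProteomeTruth(high_demand_gene_ids=high_ids))


# (n_his, gap) recipes per planted status: reference members always pass the
# default cutoffs; the focal member is engineered to force the status.
_STATUS_RECIPES: dict[str, dict[str, Optional[tuple[int, int]]]] = {
    "lost": {"nonfocal": (36, 1), "focal": None},
    "reduced": {"nonfocal": (36, 1), "focal": (8, 40)},
    "retained": {"nonfocal": (36, 1), "focal": (36, 2)},
    "increased": {"nonfocal": (36, 3), "focal": (36, 1)},
}


def _engineered_member(rng: np.random.Generator, n_his: int, gap: int
                       ) -> tuple[str, str]:
    """One protein with a single cluster of ``n_his`` histidines at ``gap``."""
    span = (n_his - 1) * gap + 1
    length = span + 40
    forced = {10 + i * gap for i in range(n_his)}
    return _protein_and_cds(rng, length, forced, p0=0.0)


def synth_family_table(
    bundles: Mapping[str, ProteomeBundle],
    focal_genome: str,
    statuses: Sequence[str],
    seed: int,
) -> tuple[list[FamilyRow], dict[str, str]]:
    """Plant ortholog families realizing the requested focal statuses.

    Engineered member genes are appended to the supplied proteome bundles
    (reference members in every non-focal genome, a focal member only where
    the status calls for one). Returns the family rows and the truth mapping
    family_id -> planted status. Statuses outside
    {lost, reduced, retained, increased} are a config error.
    """
    if focal_genome not in bundles:
        raise ConfigError(f"focal genome {focal_genome!r} not among bundles")
    if len(bundles) < 2:
        raise ConfigError("need at least two genomes to plant families")
    bad = set(statuses) - set(_STATUS_RECIPES)
    if bad:
        raise ConfigError(f"unknown planted statuses: {sorted(bad)}")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(b"family_table")]))
    rows: list[FamilyRow] = []
    truth: dict[str, str] = {}
    for fi, status in enumerate(statuses):
        fam = f"fam{fi:03d}"
        truth[fam] = status
        recipe = _STATUS_RECIPES[status]
        for genome_id, bundle in bundles.items():
            params = (recipe["focal"] if genome_id == focal_genome
                      else recipe["nonfocal"])
            if params is None:
                continue
            protein, cds = _engineered_member(rng, *params)
            gid = f"{genome_id}_{fam}"
            bundle.proteome.proteins.append((gid, protein))
            bundle.cds_seqs[gid] = cds
            rows.append(FamilyRow(family_id=fam, genome_id=genome_id,
                                  gene_id=gid))
    return rows, truth
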