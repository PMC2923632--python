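"""Histidine counting, clustering statistics, and the demand index.

For a protein with histidines at residue positions p_1 < ... < p_h, the
consecutive distances are d_i = p_{i+1} - p_i (adjacent histidines give
d = 1). The demand index is

    D = h / H_harm,    H_harm = (h-1) / sum_i (1 / d_i)

the histidine count divided by the harmonic mean of the consecutive
distances. The harmonic mean is dominated by the smallest gaps, so D is
large for proteins with many and/or tightly clustered histidines (a protein
whose h histidines are all mutually adjacent has D = h). Distances are in
residues; h < 2 leaves H_harm and D undefined.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

from scipy.stats import hmean

from .errors import ConsistencyError, UndefinedValueError
from .genome_io import HIS_CODONS, STOP_CODONS, Proteome


def harmonic_mean(distances: Sequence[float]) -> float:
    """n / sum(1/d_i) over a non-empty list of positive distances."""
    if len(distances) == 0:
        raise UndefinedValueError("harmonic mean of an empty list is undefined")
    if any(d <= 0 for d in distances):
        raise UndefinedValueError("distances must be strictly positive")
    return float(hmean(distances))


@dataclass(frozen=True)
class HistidineProfile:
    """Per-protein histidine statistics."""

    gene_id: str
    h: int
    positions: tuple[int, ...]
    distances: tuple[int, ...]
    H_harm: Optional[float]
    D: Optional[float]


def histidine_profile(gene_id: str, protein: str, residue: str = "H",
                      mode: str = "consecutive") -> HistidineProfile:
    """Histidine profile of one protein.

    ``mode='consecutive'`` (default) uses gaps between successive histidines;
    ``mode='all_pairs'`` uses all pairwise distances instead (a sensitivity
    variant — it changes H_harm and D but not h).
    """
    positions = tuple(i for i, aa in enumerate(protein) if aa == residue)
    h = len(positions)
    if mode == "consecutive":
        distances = tuple(b - a for a, b in zip(positions, positions[1:]))
    elif mode == "all_pairs":
        distances = tuple(b - a for a, b in combinations(positions, 2))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if h >= 2:
        H = harmonic_mean(distances)
        D = h / H
    else:
        H = D = None
    return HistidineProfile(gene_id=gene_id, h=h, positions=positions,
                            distances=distances, H_harm=H, D=D)


@dataclass
class GenomeHisSummary:
    """Per-genome histidine statistics: profiles plus codon-frequency totals."""

    genome_id: str
    profiles: list[HistidineProfile]
    n_proteins: int
    total_codons: int          # non-stop codons (the per-thousand denominator)
    total_his_codons: int
    his_codon_freq_per_thousand: float

    def profile_by_id(self) -> dict[str, HistidineProfile]:
        return {p.gene_id: p for p in self.profiles}


def proteome_summary(
    proteome: Proteome,
    cds_seqs: Mapping[str, str],
    residue: str = "H",
    include_stop_codons: bool = False,
    mode: str = "consecutive",
) -> GenomeHisSummary:
    """Profiles for every protein plus the His-codon frequency per thousand.

    The frequency is 1000 x (CAT+CAC codons) / (non-stop codons) over all
    supplied CDS; set ``include_stop_codons=True`` to keep stop codons in the
    denominator. The proteome and CDS gene-id sets must match exactly.
    """
    if len(proteome) == 0:
        raise ConsistencyError(f"{proteome.genome_id}: empty proteome")
    prot_ids = set(proteome.ids())
    cds_ids = set(cds_seqs)
    if prot_ids != cds_ids:
        missing = sorted(prot_ids ^ cds_ids)[:10]
        raise ConsistencyError(
            f"{proteome.genome_id}: proteome and CDS gene ids disagree "
            f"(e.g. {missing})"
        )
    profiles = [histidine_profile(gid, prot, residue=residue, mode=mode)
                for gid, prot in proteome.proteins]
    total = his = stops = 0
    for dna in cds_seqs.values():
        for i in range(0, len(dna) - len(dna) % 3, 3):
            codon = dna[i:i + 3]
            if codon in STOP_CODONS:
                stops += 1
            elif codon in HIS_CODONS:
                his += 1
            total += 1
    denom = total if include_stop_codons else total - stops
    if denom == 0:
        raise ConsistencyError(f"{proteome.genome_id}: no codons in CDS set")
    return GenomeHisSummary(
        genome_id=proteome.genome_id,
        profiles=profiles,
        n_proteins=len(profiles),
        total_codons=denom,
        total_his_codons=his,
        his_codon_freq_per_thousand=1000.0 * his / denom,
    )


def fraction_min_his(summary: GenomeHisSummary, m: int) -> float:
    """Fraction of proteins with at least ``m`` histidines."""
    if summary.n_proteins == 0:
        raise UndefinedValueError("empty summary")
    return sum(p.h >= m for p in summary.profiles) / summary.n_proteins


def fraction_min_demand(summary: GenomeHisSummary, x: float) -> float:
    """Among proteins with h >= 2, the fraction with demand index >= x."""
    eligible = [p for p in summary.profiles if p.h >= 2]
    if not eligible:
        raise UndefinedValueError(
            f"{summary.genome_id}: no protein has two or more histidines"
        )
    return sum(p.D >= x for p in eligible) / len(eligible)


@dataclass(frozen=True)
class HighDemandGene:
    gene_id: str
    h: int
    D: Optional[float]
    by_count: bool   # h >= min_h
    by_demand: bool  # D > min_D (strictly above)


def high_demand_genes(summary: GenomeHisSummary, min_h: int = 35,
                      min_D: float = 5.0) -> list[HighDemandGene]:
    """Genes with h >= min_h OR demand index strictly above min_D.

    The count cutoff is inclusive ("35 or more histidines") while the demand
    cutoff is exclusive ("demand index above 5.0").
    """
    out = []
    for p in summary.profiles:
        by_count = p.h >= min_h
        by_demand = p.D is not None and p.D > min_D
        if by_count or by_demand:
            out.append(HighDemandGene(gene_id=p.gene_id, h=p.h, D=p.D,
                                      by_count=by_count, by_demand=by_demand))
    return out


def passes_cutoffs(profile: HistidineProfile, min_h: int = 35,
                   min_D: float = 5.0) -> bool:
    """The high-demand criterion for a single profile (h >= min_h or D > min_D)."""
    return profile.h >= min_h or (profile.D is not None and profile.D > min_D)


def his_count_curve(summary: GenomeHisSummary, max_m: Optional[int] = None
                    ) -> list[tuple[int, float]]:
    """(m, fraction of proteins with >= m histidines) for m = 0..max_m."""
    if max_m is None:
        max_m = max((p.h for p in summary.profiles), default=0)
    return [(m, fraction_min_his(summary, m)) for m in range(max_m + 1)]


def demand_curve(summary: GenomeHisSummary, thresholds: Sequence[float]
                 ) -> list[tuple[float, float]]:
    """(x, fraction of h>=2 proteins with D >= x) over the given thresholds."""
    return [(float(x), fraction_min_demand(summary, x)) for x in thresholds]


def profile_report_rows(summary: GenomeHisSummary) -> list[dict]:
    """Flat rows for the per-gene profile TSV."""
    rows = []
    for p in summary.profiles:
        rows.append({
            "gene_id": p.gene_id,
            "h": p.h,
            "H_harm": f"{p.H_harm:.4f}" if p.H_harm is not None else "",
            "D": f"{p.D:.4f}" if p.D is not None else "",
            "positions": ",".join(str(x) for x in p.positions),
        })
    return rows
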