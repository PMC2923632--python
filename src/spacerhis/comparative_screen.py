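"""Cross-genome classification of high-histidine-demand gene families.

Given ortholog families spanning a focal genome and one or more reference
genomes, each family in which some reference member exceeds the high-demand
cutoffs (h >= 35 histidines or demand index above 5.0) is classified by the
focal genome's status: the family was *lost* (no focal member), *reduced*
(focal members exist but none passes the cutoffs), *retained* (a focal
member passes, with demand no higher than the best reference member), or
*increased* (the focal maximum demand exceeds the reference maximum).
Families whose reference members all fall below the cutoffs are
*not_applicable*. Ortholog families are an input (curation-dependent), not
inferred here.
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ConsistencyError
from .histidine_demand import GenomeHisSummary, HistidineProfile, passes_cutoffs

STATUS_ORDER = ["lost", "reduced", "retained", "increased", "not_applicable"]


@dataclass(frozen=True)
class FamilyRow:
    family_id: str
    genome_id: str
    gene_id: str


@dataclass(frozen=True)
class FamilyComparison:
    """Per-family focal-genome status with the numbers behind it."""

    family_id: str
    focal_status: str
    max_nonfocal_h: Optional[int]
    max_nonfocal_D: Optional[float]
    focal_h: Optional[int]
    focal_D: Optional[float]


def read_family_table(path: str | os.PathLike) -> list[FamilyRow]:
    """Read a family TSV (family_id, genome_id, gene_id; header optional).

    Each (genome_id, gene_id) may appear in exactly one family; duplicates
    are rejected with the offending line number.
    """
    rows: list[FamilyRow] = []
    seen: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() == "family_id":
                continue
            if len(parts) != 3:
                raise ConsistencyError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns, "
                    f"got {len(parts)}"
                )
            fam, genome, gene = parts
            key = (genome, gene)
            if key in seen:
                raise ConsistencyError(
                    f"{path}: line {lineno}: gene {gene!r} of genome "
                    f"{genome!r} already assigned at line {seen[key]}"
                )
            seen[key] = lineno
            rows.append(FamilyRow(family_id=fam, genome_id=genome, gene_id=gene))
    return rows


def _max_or_none(values):
    values = [v for v in values if v is not None]
    return max(values) if values else None


def classify_family(
    family_id: str,
    members: Mapping[str, Sequence[HistidineProfile]],
    focal_genome: str,
    min_h: int = 35,
    min_D: float = 5.0,
) -> FamilyComparison:
    """Classify one family's focal-genome status.

    ``members`` maps genome id to that genome's member profiles. Rule: if no
    non-focal member passes the cutoffs the family is not_applicable;
    otherwise no focal member at all means lost; focal members present but
    none passing means reduced; a passing focal member means retained when
    the focal maximum demand index is at most the non-focal maximum, and
    increased when it exceeds it.
    """
    focal = list(members.get(focal_genome, []))
    nonfocal = [p for g, ps in members.items() if g != focal_genome for p in ps]
    nf_h = _max_or_none([p.h for p in nonfocal])
    nf_D = _max_or_none([p.D for p in nonfocal])
    f_h = _max_or_none([p.h for p in focal])
    f_D = _max_or_none([p.D for p in focal])
    if not nonfocal:
        warnings.warn(f"family {family_id}: only focal members present")
        status = "not_applicable"
    elif not any(passes_cutoffs(p, min_h, min_D) for p in nonfocal):
        status = "not_applicable"
    elif not focal:
        status = "lost"
    elif not any(passes_cutoffs(p, min_h, min_D) for p in focal):
        status = "reduced"
    else:
        # both sides pass, so h >= 2 on both and the max D values are defined
        status = "retained" if f_D <= nf_D else "increased"
    return FamilyComparison(
        family_id=family_id, focal_status=status,
        max_nonfocal_h=nf_h, max_nonfocal_D=nf_D,
        focal_h=f_h, focal_D=f_D,
    )


def screen_report(
    family_rows: Sequence[FamilyRow],
    summaries: Mapping[str, GenomeHisSummary],
    focal_genome: str,
    min_h: int = 35,
    min_D: float = 5.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every family with at least one member above the cutoffs.

    Returns a DataFrame (one row per reported family, sorted
    lost -> reduced -> retained -> increased -> not_applicable, then by
    family id) and a per-status totals dict. Families whose members all fall
    below the cutoffs are omitted entirely. A gene referenced by the table
    but absent from the summaries raises a consistency error.
    """
    lookup = {g: s.profile_by_id() for g, s in summaries.items()}
    families: dict[str, dict[str, list[HistidineProfile]]] = {}
    for row in family_rows:
        if row.genome_id not in lookup:
            raise ConsistencyError(
                f"family {row.family_id}: genome {row.genome_id!r} has no summary"
            )
        profile = lookup[row.genome_id].get(row.gene_id)
        if profile is None:
            raise ConsistencyError(
                f"family {row.family_id}: gene {row.gene_id!r} not profiled "
                f"in genome {row.genome_id!r}"
            )
        families.setdefault(row.family_id, {}).setdefault(
            row.genome_id, []).append(profile)
    comparisons: list[FamilyComparison] = []
    for fam_id in sorted(families):
        members = families[fam_id]
        any_pass = any(passes_cutoffs(p, min_h, min_D)
                       for ps in members.values() for p in ps)
        if not any_pass:
            continue
        comparisons.append(
            classify_family(fam_id, members, focal_genome, min_h, min_D))
    rank = {s: i for i, s in enumerate(STATUS_ORDER)}
    comparisons.sort(key=lambda c: (rank[c.focal_status], c.family_id))
    df = pd.DataFrame([{
        "family_id": c.family_id,
        "focal_status": c.focal_status,
        "max_nonfocal_h": c.max_nonfocal_h,
        "max_nonfocal_D": c.max_nonfocal_D,
        "focal_h": c.focal_h,
        "focal_D": c.focal_D,
    } for c in comparisons],
        columns=["family_id", "focal_status", "max_nonfocal_h",
                 "max_nonfocal_D", "focal_h", "focal_D"])
    totals = {s: 0 for s in STATUS_ORDER}
    for c in comparisons:
        totals[c.focal_status] += 1
    return df, totals
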