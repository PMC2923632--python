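"""Genome, annotation and proteome I/O.

Coordinate convention: 0-based half-open intervals everywhere in memory;
1-based inclusive only at file boundaries (feature-table input, TSV reports).
Translation uses the bacterial genetic code (NCBI table 11); the two histidine
codons are CAT and CAC.
"""
from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConsistencyError, CoordinateError, FastaFormatError, FrameError

DNA_ALPHABET = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})  # table 11
HIS_CODONS = frozenset({"CAT", "CAC"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """One contig: an identifier and an uppercase DNA string."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("empty record identifier")
        if not self.seq:
            raise FastaFormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise FastaFormatError(
                f"record {self.id!r}: disallowed characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature on the forward-strand coordinate system.

    ``start``/``end`` are 0-based half-open on the forward strand regardless of
    the coding strand; ``strand`` is '+' or '-'.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise CoordinateError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )


@dataclass
class Proteome:
    """Ordered (gene_id, amino-acid sequence) pairs for one genome."""

    genome_id: str
    proteins: list[tuple[str, str]] = field(default_factory=list)

    def ids(self) -> list[str]:
        return [g for g, _ in self.proteins]

    def __len__(self) -> int:
        return len(self.proteins)


def _validate_fasta_text(path: str | os.PathLike) -> None:
    """Line-level structural check so errors can name the offending line."""
    seen_header = False
    seen_any = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            seen_any = True
            if line.startswith(">"):
                if len(line) == 1:
                    raise FastaFormatError(f"line {lineno}: empty FASTA header")
                seen_header = True
            else:
                if not seen_header:
                    raise FastaFormatError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                bad = set(line.upper().replace("U", "T")) - DNA_ALPHABET
                if bad:
                    raise FastaFormatError(
                        f"line {lineno}: disallowed characters {sorted(bad)}"
                    )
    if not seen_any:
        raise FastaFormatError("line 1: empty FASTA file")


def read_fasta(path: str | os.PathLike) -> list[GenomeRecord]:
    """Read a DNA FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased and U is mapped to T. Duplicate identifiers and
    characters outside {A,C,G,T,N} are rejected.
    """
    _validate_fasta_text(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(GenomeRecord(id=rec.id, seq=seq))
    return records


def write_fasta(records: Iterable[GenomeRecord | tuple[str, str]],
                path: str | os.PathLike) -> None:
    """Write records (GenomeRecord or (id, seq) pairs) as FASTA."""
    seqrecords = []
    for rec in records:
        if isinstance(rec, GenomeRecord):
            rid, seq = rec.id, rec.seq
        else:
            rid, seq = rec
        seqrecords.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seqrecords, str(path), "fasta")


def extract_cds(genome: GenomeRecord, feat: CdsFeature) -> str:
    """Strand-aware coding sequence for ``feat`` on ``genome``."""
    if feat.end > len(genome.seq):
        raise CoordinateError(
            f"{feat.gene_id}: interval [{feat.start}, {feat.end}) exceeds "
            f"contig {genome.id!r} length {len(genome.seq)}"
        )
    sub = genome.seq[feat.start:feat.end]
    return sub if feat.strand == "+" else revcomp(sub)


def translate_cds(dna: str) -> tuple[str, bool]:
    """Translate a CDS with the bacterial code (table 11).

    Returns ``(protein, pseudo)``. The terminal stop is removed; a protein
    retaining an internal stop is flagged ``pseudo=True`` (such genes are
    excluded from histidine statistics upstream). A length not divisible by
    three raises :class:`FrameError`.
    """
    if len(dna) % 3 != 0:
        raise FrameError(f"CDS length {len(dna)} not divisible by 3")
    protein = str(Seq(dna).translate(table=11))
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein, "*" in protein


def read_gff3(path: str | os.PathLike, attr_key: str = "locus_tag") -> list[CdsFeature]:
    """Load CDS features from a GFF3 file.

    The gene identifier is taken from attribute ``attr_key`` (default
    ``locus_tag``), falling back to ``ID``. GFF3 1-based inclusive coordinates
    are converted to 0-based half-open.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats: list[CdsFeature] = []
    for f in db.features_of_type("CDS", order_by=("seqid", "start")):
        if attr_key in f.attributes:
            gid = f.attributes[attr_key][0]
        elif "ID" in f.attributes:
            gid = f.attributes["ID"][0]
        else:
            gid = f.id
        feats.append(CdsFeature(gene_id=gid, contig_id=f.seqid,
                                start=f.start - 1, end=f.end, strand=f.strand))
    return feats


def write_gff3(features: Sequence[CdsFeature], path: str | os.PathLike,
               attr_key: str = "locus_tag") -> None:
    """Write CDS features as minimal GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.contig_id}\tspacerhis\tCDS\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t0\tID={f.gene_id};{attr_key}={f.gene_id}\n"
            )


def read_feature_table(path: str | os.PathLike) -> list[CdsFeature]:
    """Read the fallback tab-delimited feature table.

    Columns: gene_id, contig_id, start, end, strand — 1-based inclusive in the
    file, converted to 0-based half-open on load. A header row is optional.
    """
    feats: list[CdsFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() == "gene_id":
                continue
            if len(parts) != 5:
                raise ConsistencyError(
                    f"{path}: line {lineno}: expected 5 tab-separated columns, "
                    f"got {len(parts)}"
                )
            gid, contig, start_s, end_s, strand = parts
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ConsistencyError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            feats.append(CdsFeature(gene_id=gid, contig_id=contig,
                                    start=start1 - 1, end=end1, strand=strand))
    return feats


@dataclass(frozen=True)
class QcFlag:
    """A feature excluded from downstream statistics, with the reason."""

    gene_id: str
    reason: str


def build_proteome(
    contigs: Mapping[str, GenomeRecord] | Sequence[GenomeRecord],
    features: Sequence[CdsFeature],
    genome_id: str,
) -> tuple[Proteome, dict[str, str], list[QcFlag]]:
    """Extract and translate every CDS of a genome.

    Returns the proteome (non-pseudo, in-frame proteins only), the matching
    CDS nucleotide sequences keyed by gene id, and QC flags for every feature
    that was excluded (frame error, internal stop, bad coordinates). The
    proteome and CDS dict always cover exactly the same gene ids.
    """
    if not isinstance(contigs, Mapping):
        contigs = {c.id: c for c in contigs}
    proteome = Proteome(genome_id=genome_id)
    cds_seqs: dict[str, str] = {}
    flags: list[QcFlag] = []
    for feat in features:
        contig = contigs.get(feat.contig_id)
        if contig is None:
            flags.append(QcFlag(feat.gene_id, f"unknown contig {feat.contig_id!r}"))
            continue
        try:
            dna = extract_cds(contig, feat)
            protein, pseudo = translate_cds(dna)
        except (CoordinateError, FrameError) as exc:
            flags.append(QcFlag(feat.gene_id, str(exc)))
            continue
        if pseudo:
            flags.append(QcFlag(feat.gene_id, "internal stop codon (pseudo)"))
            continue
        if feat.gene_id in cds_seqs:
            flags.append(QcFlag(feat.gene_id, "duplicate gene id"))
            continue
        proteome.proteins.append((feat.gene_id, protein))
        cds_seqs[feat.gene_id] = dna
    return proteome, cds_seqs, flags
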