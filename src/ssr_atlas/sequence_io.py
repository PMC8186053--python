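"""Reading and writing the formats the survey touches.

Genomes come in as FASTA, annotation as GFF3; detected repeat loci go out
as TSV, BED or GFF3. Length accounting distinguishes *total* length from
*valid* length (total minus unknown ``N`` bases): every per-megabase
statistic downstream is normalized by valid length.

Conventions
-----------
* Residues are uppercased on input; soft-masked (lowercase) sequence is
  treated as ordinary sequence.
* IUPAC ambiguity codes other than ``N`` count toward valid length but can
  never sit inside a repeat tract (the scanner breaks tracts on any
  non-ACGT character).
* Coordinates are 1-based inclusive internally (the GFF3 convention);
  BED's 0-based half-open starts appear only at the output boundary.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

LOCUS_COLUMNS = (
    "chrom", "start", "end", "motif", "canonical_class",
    "unit_count", "tract_length", "region",
)


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


class DuplicateSequenceError(ValueError):
    """Raised when two FASTA records share an identifier."""


class GffFormatError(ValueError):
    """Raised for structurally invalid GFF3 (e.g. start > end)."""


@dataclass
class GenomeSequence:
    """One chromosome/scaffold with length bookkeeping."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()

    @property
    def total_length(self) -> int:
        return len(self.residues)

    @property
    def valid_length(self) -> int:
        """Total length minus unknown bases (Ns)."""
        return len(self.residues) - self.residues.count("N")

    @property
    def n_pct(self) -> float:
        if not self.residues:
            return 0.0
        return 100.0 * self.residues.count("N") / len(self.residues)


class GenomeCollection:
    """Ordered, name-indexed set of :class:`GenomeSequence`."""

    def __init__(self, sequences: Iterable[GenomeSequence] = ()):
        self.sequences: list[GenomeSequence] = []
        self._index: dict[str, GenomeSequence] = {}
        for seq in sequences:
            self.add(seq)

    def add(self, seq: GenomeSequence) -> None:
        if seq.name in self._index:
            raise DuplicateSequenceError(
                f"duplicate sequence identifier {seq.name!r}"
            )
        self.sequences.append(seq)
        self._index[seq.name] = seq

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> GenomeSequence:
        return self._index[name]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sequences]

    @property
    def total_length(self) -> int:
        return sum(s.total_length for s in self.sequences)

    @property
    def valid_length(self) -> int:
        return sum(s.valid_length for s in self.sequences)

    @property
    def n_pct(self) -> float:
        total = self.total_length
        if total == 0:
            return 0.0
        return 100.0 * (total - self.valid_length) / total


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class ExonRecord:
    transcript_id: str
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int


@dataclass
class AnnotationModel:
    """Gene/transcript/exon structure extracted from GFF3.

    Exons are recorded once per parent transcript; isoform-level
    deduplication happens downstream when the region partition merges
    exon intervals.
    """

    genes: list[GeneRecord] = field(default_factory=list)
    exons: list[ExonRecord] = field(default_factory=list)
    orphan_exons: list[str] = field(default_factory=list)

    @property
    def chroms(self) -> set[str]:
        return {g.chrom for g in self.genes} | {e.chrom for e in self.exons}

    def flag_unknown_chroms(self, known: Sequence[str]) -> set[str]:
        """Chromosome names used by features but absent from the genome."""
        return self.chroms - set(known)


def read_fasta(path: str | Path) -> GenomeCollection:
    """Read a (multi-)FASTA file into a :class:`GenomeCollection`.

    Residues are uppercased and record order is preserved.

    Raises
    ------
    FastaFormatError
        If the file is empty or does not start with a ``>`` header.
    DuplicateSequenceError
        If two records share an identifier.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
        if not first:
            raise FastaFormatError(f"{path}: empty file (line 1)")
        if not first.startswith(">"):
            raise FastaFormatError(
                f"{path}: line 1 does not start with a FASTA header ('>')"
            )
    collection = GenomeCollection()
    for record in SeqIO.parse(str(path), "fasta"):
        collection.add(GenomeSequence(name=record.id, residues=str(record.seq)))
    if len(collection) == 0:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return collection


def compute_length_report(gc: GenomeCollection) -> pd.DataFrame:
    """Per-sequence and genome-total length accounting.

    Columns: ``name``, ``total_bp``, ``valid_bp``, ``n_pct`` with
    ``n_pct = 100 * (total - valid) / total``. The final row (name
    ``TOTAL``) sums the collection.
    """
    if len(gc) == 0:
        raise ValueError("empty genome collection")
    rows = [
        {"name": s.name, "total_bp": s.total_length,
         "valid_bp": s.valid_length, "n_pct": round(s.n_pct, 4)}
        for s in gc
    ]
    rows.append({
        "name": "TOTAL", "total_bp": gc.total_length,
        "valid_bp": gc.valid_length, "n_pct": round(gc.n_pct, 4),
    })
    return pd.DataFrame(rows, columns=["name", "total_bp", "valid_bp", "n_pct"])


_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def read_gff3(path: str | Path) -> AnnotationModel:
    """Parse gene/mRNA(or transcript)/exon features from a GFF3 file.

    Parent links are resolved through ``Parent`` attributes (exon →
    transcript → gene; exons parented directly by a gene are accepted).
    Exons whose parent cannot be resolved are collected in
    ``orphan_exons`` and a warning is emitted. Features of other types
    (CDS, UTR, ...) are ignored: the three-way exon/intron/intergenic
    partition needs only gene spans and exon intervals.
    """
    import gffutils

    path = Path(path)
    db = gffutils.create_db(
        str(path), ":memory:",
        merge_strategy="create_unique", keep_order=True,
    )

    genes: dict[str, GeneRecord] = {}
    for f in db.features_of_type("gene"):
        if f.start > f.end:
            raise GffFormatError(
                f"{path}: gene {f.id} has start > end ({f.start} > {f.end})"
            )
        genes[f.id] = GeneRecord(
            gene_id=f.id, chrom=f.seqid, strand=f.strand or ".",
            start=f.start, end=f.end,
        )

    tx_to_gene: dict[str, str] = {}
    tx_chrom: dict[str, str] = {}
    for ttype in _TRANSCRIPT_TYPES:
        for f in db.features_of_type(ttype):
            parents = f.attributes.get("Parent", [])
            tx_to_gene[f.id] = parents[0] if parents else f.id
            tx_chrom[f.id] = f.seqid

    exons: list[ExonRecord] = []
    orphans: list[str] = []
    for f in db.features_of_type("exon"):
        if f.start > f.end:
            raise GffFormatError(
                f"{path}: exon at {f.seqid}:{f.start}-{f.end} has start > end"
            )
        parents = f.attributes.get("Parent", [])
        if not parents:
            orphans.append(f"{f.seqid}:{f.start}-{f.end}")
            continue
        for parent in parents:
            if parent in tx_to_gene:
                gene_id = tx_to_gene[parent]
                exons.append(ExonRecord(parent, gene_id, f.seqid, f.start, f.end))
            elif parent in genes:
                exons.append(ExonRecord(parent, parent, f.seqid, f.start, f.end))
            else:
                orphans.append(f"{f.seqid}:{f.start}-{f.end} (parent {parent})")
    if orphans:
        warnings.warn(
            f"{path}: {len(orphans)} exon(s) with unresolvable parents "
            "were skipped", stacklevel=2,
        )

    # genes absent as explicit features but referenced by transcripts:
    # substitute the union span of their transcripts
    missing = {g for g in tx_to_gene.values() if g not in genes}
    if missing:
        spans: dict[str, list[int]] = {}
        for f in db.all_features():
            if f.id in tx_to_gene and tx_to_gene[f.id] in missing:
                g = tx_to_gene[f.id]
                if g not in spans:
                    spans[g] = [f.seqid, f.strand or ".", f.start, f.end]
                else:
                    spans[g][2] = min(spans[g][2], f.start)
                    spans[g][3] = max(spans[g][3], f.end)
        for g, (chrom, strand, start, end) in spans.items():
            genes[g] = GeneRecord(g, chrom, strand, start, end)

    return AnnotationModel(
        genes=list(genes.values()), exons=exons, orphan_exons=orphans,
    )


def write_fasta(gc: GenomeCollection, path: str | Path, width: int = 70) -> None:
    """Write a collection back to FASTA (fixed line width)."""
    with open(path, "w") as out:
        for seq in gc:
            out.write(f">{seq.name}\n")
            for i in range(0, len(seq.residues), width):
                out.write(seq.residues[i:i + width] + "\n")


def write_loci(loci: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write repeat loci as TSV, BED or GFF3.

    TSV columns: chrom, start, end (1-based inclusive), motif,
    canonical_class, unit_count, tract_length, region. BED uses 0-based
    half-open starts; GFF3 keeps 1-based inclusive coordinates with the
    remaining fields in the attribute column. ``read_loci`` round-trips
    the TSV form losslessly.
    """
    fmt = format.lower()
    if fmt not in {"tsv", "bed", "gff3"}:
        raise ValueError(f"unknown locus output format {format!r}")
    with open(path, "w", newline="") as out:
        if fmt == "tsv":
            w = csv.writer(out, delimiter="\t", lineterminator="\n")
            w.writerow(LOCUS_COLUMNS)
            for lc in loci:
                w.writerow([
                    lc.chrom, lc.start, lc.end, lc.motif, lc.canonical_class,
                    lc.unit_count, lc.tract_length, lc.region,
                ])
        elif fmt == "bed":
            for lc in loci:
                name = f"{lc.motif};class={lc.canonical_class};region={lc.region}"
                out.write(
                    f"{lc.chrom}\t{lc.start - 1}\t{lc.end}\t{name}"
                    f"\t{lc.unit_count}\t+\n"
                )
        else:  # gff3
            out.write("##gff-version 3\n")
            for i, lc in enumerate(loci, 1):
                attrs = (
                    f"ID=ssr{i};motif={lc.motif};"
                    f"canonical_class={lc.canonical_class};"
                    f"unit_count={lc.unit_count};region={lc.region}"
                )
                out.write(
                    f"{lc.chrom}\tssr-atlas\tmicrosatellite\t{lc.start}"
                    f"\t{lc.end}\t.\t+\t.\t{attrs}\n"
                )


def read_loci(path: str | Path) -> list:
    """Read loci back from the TSV written by :func:`write_loci`."""
    from .scanner import RepeatLocus

    loci = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            motif = row["motif"]
            loci.append(RepeatLocus(
                chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
                motif=motif, motif_size=len(motif),
                unit_count=int(row["unit_count"]),
                canonical_class=row["canonical_class"] or None,
                region=row["region"],
            ))
    return loci
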