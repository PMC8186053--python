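"""End-to-end survey orchestration: scan → canonicalize → classify → summarize.

``run_survey`` produces one coherent output bundle from a genome (and
optionally its annotation): the length report, the locus table, the
frequency/density/GC summary, percent motif abundance by region, canonical
motif count tables, iteration-number bins, and a manifest with input
checksums so a run can be reproduced and audited. All statistics derive
from a single locus set; the survey itself is fully deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .motif import annotate_loci
from .regions import build_partition, classify_loci
from .scanner import ScanThresholds, scan_collection
from .sequence_io import (GenomeCollection, compute_length_report,
                          read_fasta, read_gff3, write_loci)
from .stats import (iteration_bins, loci_to_frame, motif_count_table,
                    percent_motif_abundance, summarize)

logger = logging.getLogger(__name__)


class ChromosomeMismatchError(RuntimeError):
    """Genome and annotation appear to come from different builds."""


@dataclass
class SurveyResult:
    loci: list
    length_report: pd.DataFrame
    summary: pd.DataFrame
    percent_abundance: pd.DataFrame
    motif_counts: pd.DataFrame
    bins: pd.DataFrame
    manifest: dict
    partition: object | None = None
    outputs: dict[str, Path] = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_survey(fasta: str | Path,
               gff3: str | Path | None = None,
               thresholds: ScanThresholds | None = None,
               outdir: str | Path | None = None,
               assign: str = "start",
               alias_map: dict[str, str] | None = None) -> SurveyResult:
    """Run the full survey on a genome.

    Without ``gff3`` the survey runs in genome-only mode and every locus
    is ``unassigned``. ``alias_map`` renames annotation chromosome names
    to genome names before matching. If more than half of the loci fall
    on chromosomes that the annotation does not cover, a
    :class:`ChromosomeMismatchError` is raised (the annotation most
    likely belongs to a different assembly).
    """
    t = thresholds or ScanThresholds()
    genome = read_fasta(fasta)
    loci = scan_collection(genome, t)
    annotate_loci(loci)

    partition = None
    unassigned = len(loci)
    if gff3 is not None:
        ann = read_gff3(gff3)
        if alias_map:
            from .sequence_io import ExonRecord, GeneRecord
            ann.genes = [
                GeneRecord(g.gene_id, alias_map.get(g.chrom, g.chrom),
                           g.strand, g.start, g.end) for g in ann.genes]
            ann.exons = [
                ExonRecord(e.transcript_id, e.gene_id,
                           alias_map.get(e.chrom, e.chrom), e.start, e.end)
                for e in ann.exons]
        unknown = ann.flag_unknown_chroms(genome.names)
        if unknown:
            logger.warning("annotation names %d chromosome(s) absent from "
                           "the genome: %s", len(unknown),
                           ", ".join(sorted(unknown)[:5]))
        partition = build_partition(ann, genome)
        annotated_chroms = {g.chrom for g in ann.genes}
        covered = sum(lc.chrom in annotated_chroms for lc in loci)
        if loci and covered < 0.5 * len(loci):
            raise ChromosomeMismatchError(
                f"only {covered}/{len(loci)} loci fall on annotated "
                "chromosomes; genome and annotation probably come from "
                "different builds")
        unassigned = classify_loci(loci, partition, assign=assign)

    length_report = compute_length_report(genome)
    valid = genome.valid_length
    summary = summarize(loci, valid)
    pct = percent_motif_abundance(loci)
    counts_frames = [motif_count_table(loci, region=r)
                     for r in (["exon", "intron", "intergenic"]
                               if gff3 is not None else [None])]
    motif_counts = pd.concat(counts_frames, ignore_index=True)
    bins = iteration_bins(loci)

    manifest = {
        "tool": "ssr-atlas",
        "version": __version__,
        "inputs": {
            "fasta": {"path": str(fasta), "sha256": _sha256(fasta)},
            "gff3": ({"path": str(gff3), "sha256": _sha256(gff3)}
                     if gff3 is not None else None),
        },
        "thresholds": {
            "min_tract_bp": {str(k): v
                             for k, v in sorted(t.min_tract_bp.items())},
            "flank_bp": t.flank_bp,
        },
        "assign": assign,
        "counts": {
            "sequences": len(genome),
            "total_bp": genome.total_length,
            "valid_bp": valid,
            "loci": len(loci),
            "unassigned_loci": unassigned,
        },
    }

    result = SurveyResult(loci, length_report, summary, pct, motif_counts,
                          bins, manifest, partition)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "lengths": outdir / "length_report.tsv",
            "loci": outdir / "loci.tsv",
            "summary": outdir / "summary.tsv",
            "percent_abundance": outdir / "percent_abundance.tsv",
            "motif_counts": outdir / "motif_counts.tsv",
            "iteration_bins": outdir / "iteration_bins.tsv",
            "manifest": outdir / "manifest.json",
        }
        length_report.to_csv(paths["lengths"], sep="\t", index=False)
        write_loci(loci, paths["loci"], "tsv")
        summary.round(2).to_csv(paths["summary"], sep="\t")
        pct.round(2).to_csv(paths["percent_abundance"], sep="\t")
        motif_counts.to_csv(paths["motif_counts"], sep="\t", index=False)
        bins.round(2).to_csv(paths["iteration_bins"], sep="\t", index=False)
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        result.outputs = paths
    return result
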