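"""Exon/intron/intergenic partition and locus region assignment.

Every base of every chromosome gets exactly one of three labels:

* **exon** — covered by any isoform's exon (union across transcripts);
* **intron** — inside a gene span but not exonic;
* **intergenic** — outside all gene spans.

The partition is strand-agnostic and exhaustive: per chromosome the three
interval sets are disjoint and cover ``[1, length]`` exactly, so region
lengths always sum to chromosome length. Loci are labeled by the region
containing their start base by default; a majority-overlap rule is
available for boundary-spanning loci.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .sequence_io import AnnotationModel, GenomeCollection

logger = logging.getLogger(__name__)

REGION_LABELS = ("exon", "intron", "intergenic")

Interval = tuple[int, int]  # 1-based inclusive


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of 1-based inclusive intervals as a sorted disjoint list."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def subtract_intervals(base: Sequence[Interval],
                       minus: Sequence[Interval]) -> list[Interval]:
    """Set difference of two sorted disjoint interval lists."""
    out: list[Interval] = []
    j = 0
    for s, e in base:
        cur = s
        while j < len(minus) and minus[j][1] < cur:
            j += 1
        jj = j
        while jj < len(minus) and minus[jj][0] <= e:
            ms, me = minus[jj]
            if ms > cur:
                out.append((cur, ms - 1))
            cur = max(cur, me + 1)
            jj += 1
            if cur > e:
                break
        if cur <= e:
            out.append((cur, e))
    return out


def _clip(intervals: Iterable[Interval], length: int) -> list[Interval]:
    out = []
    for s, e in intervals:
        s, e = max(1, s), min(length, e)
        if s <= e:
            out.append((s, e))
    return out


@dataclass
class RegionPartition:
    """Per-chromosome exhaustive three-way labeling.

    ``intervals[chrom][label]`` is a sorted disjoint interval list;
    ``region_lengths`` totals bp per label over all chromosomes.
    """

    intervals: dict[str, dict[str, list[Interval]]] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    skipped_features: int = 0
    # per chromosome: sorted segment starts + labels for O(log n) lookup
    _lookup: dict[str, tuple[list[int], list[int], list[str]]] = field(
        default_factory=dict, repr=False)

    @property
    def region_lengths(self) -> dict[str, int]:
        totals = {label: 0 for label in REGION_LABELS}
        for chrom in self.intervals:
            for label in REGION_LABELS:
                totals[label] += sum(
                    e - s + 1 for s, e in self.intervals[chrom][label]
                )
        return totals

    def region_lengths_for(self, chrom: str) -> dict[str, int]:
        return {
            label: sum(e - s + 1 for s, e in self.intervals[chrom][label])
            for label in REGION_LABELS
        }

    def _build_lookup(self, chrom: str) -> None:
        segs = []
        for label in REGION_LABELS:
            for s, e in self.intervals[chrom][label]:
                segs.append((s, e, label))
        segs.sort()
        self._lookup[chrom] = (
            [s for s, _, _ in segs],
            [e for _, e, _ in segs],
            [lab for _, _, lab in segs],
        )

    def label_at(self, chrom: str, pos: int) -> str:
        """Region label of a single base (1-based); 'unassigned' off-chrom."""
        if chrom not in self.intervals:
            return "unassigned"
        if chrom not in self._lookup:
            self._build_lookup(chrom)
        starts, ends, labels = self._lookup[chrom]
        i = bisect_right(starts, pos) - 1
        if i < 0 or pos > ends[i]:
            return "unassigned"  # outside [1, chrom length]
        return labels[i]

    def overlap_bp(self, chrom: str, start: int, end: int) -> dict[str, int]:
        """bp of overlap of [start, end] with each region label."""
        out = {label: 0 for label in REGION_LABELS}
        if chrom not in self.intervals:
            return out
        if chrom not in self._lookup:
            self._build_lookup(chrom)
        starts, ends, labels = self._lookup[chrom]
        i = max(0, bisect_right(starts, start) - 1)
        while i < len(starts) and starts[i] <= end:
            ov = min(end, ends[i]) - max(start, starts[i]) + 1
            if ov > 0:
                out[labels[i]] += ov
            i += 1
        return out


def build_partition(ann: AnnotationModel,
                    gc: GenomeCollection) -> RegionPartition:
    """Build the three-way partition from annotation + genome lengths.

    Exons are merged across isoforms (a base exonic in any isoform is
    exonic); introns are genic space minus exons; intergenic is the
    complement of gene spans. Features on chromosomes absent from the
    genome are skipped and counted. Overlapping genes merge by union.
    """
    part = RegionPartition()
    known = set(gc.names)

    genes_by_chrom: dict[str, list[Interval]] = {}
    skipped = 0
    for g in ann.genes:
        if g.chrom not in known:
            skipped += 1
            continue
        genes_by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    exons_by_chrom: dict[str, list[Interval]] = {}
    for ex in ann.exons:
        if ex.chrom not in known:
            skipped += 1
            continue
        exons_by_chrom.setdefault(ex.chrom, []).append((ex.start, ex.end))
    if skipped:
        logger.warning(
            "%d annotation feature(s) on chromosomes absent from the "
            "genome were skipped", skipped)
    part.skipped_features = skipped

    for seq in gc:
        length = seq.total_length
        chrom = seq.name
        exon = merge_intervals(_clip(exons_by_chrom.get(chrom, []), length))
        genic = merge_intervals(
            _clip(genes_by_chrom.get(chrom, []), length) + exon
        )
        intron = subtract_intervals(genic, exon)
        intergenic = subtract_intervals([(1, length)] if length else [], genic)
        part.intervals[chrom] = {
            "exon": exon, "intron": intron, "intergenic": intergenic,
        }
        part.chrom_lengths[chrom] = length
    return part


def classify_locus(locus, part: RegionPartition, assign: str = "start") -> str:
    """Region label for one locus.

    ``assign='start'`` (default) uses the region of the start base —
    deterministic and order-independent for boundary-spanning loci.
    ``assign='majority'`` picks the label with the largest overlap,
    falling back to the start-base label on ties.
    """
    if assign == "start":
        return part.label_at(locus.chrom, locus.start)
    if assign == "majority":
        ov = part.overlap_bp(locus.chrom, locus.start, locus.end)
        if not any(ov.values()):
            return "unassigned"
        best = max(ov.values())
        winners = [lab for lab in REGION_LABELS if ov[lab] == best]
        if len(winners) == 1:
            return winners[0]
        start_label = part.label_at(locus.chrom, locus.start)
        return start_label if start_label in winners else winners[0]
    raise ValueError(f"unknown assignment rule {assign!r}")


def classify_loci(loci, part: RegionPartition, assign: str = "start") -> int:
    """Label loci in place; returns the number left unassigned."""
    unassigned = 0
    for lc in loci:
        lc.region = classify_locus(lc, part, assign)
        if lc.region == "unassigned":
            unassigned += 1
    if unassigned:
        logger.info("%d locus/loci on unannotated chromosomes left "
                    "unassigned", unassigned)
    return unassigned
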