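"""Synthetic genomes with planted microsatellites and known truth.

The generator emulates the inputs a genome-wide SSR survey consumes:
chromosome-scale FASTA with N blocks, a matching GFF3 with multi-exon
(optionally multi-isoform) gene models, and a truth table recording every
planted repeat (coordinates, motif, class, unit count, region) plus exact
valid length and region lengths. Everything is deterministic given the
config's seed.

Two properties make recovery tests exact rather than tolerance-based:

* the background is *clean* — any accidental above-threshold repeat in
  the random background is broken by single-base substitution until a
  scan finds exactly the planted loci and nothing else;
* every plant is flanked by guard bases chosen so the repeat cannot
  extend beyond its recorded coordinates, and plants are mutually
  separated and wholly inside one interval of their target region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .motif import canonical_class
from .regions import Interval, merge_intervals, subtract_intervals
from .scanner import (RepeatLocus, ScanThresholds, is_primitive,
                      scan_sequence)
from .sequence_io import (AnnotationModel, ExonRecord, GeneRecord,
                          GenomeCollection, GenomeSequence, write_fasta)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationConfigError(ValueError):
    """Raised for infeasible or invalid generator configurations."""


@dataclass(frozen=True)
class PlantSpec:
    """A batch of repeats to plant.

    Either ``motif`` (explicit unit, as planted on the forward strand) or
    ``motif_size`` (random primitive unit of that size per plant) must be
    given. ``unit_count`` is a fixed count or an inclusive ``(lo, hi)``
    range sampled uniformly. ``region`` targets ``exon``, ``intron``,
    ``intergenic`` or ``any``.
    """

    count: int
    motif: str | None = None
    motif_size: int | None = None
    unit_count: int | tuple[int, int] = 10
    region: str = "any"

    def __post_init__(self) -> None:
        if (self.motif is None) == (self.motif_size is None):
            raise SimulationConfigError(
                "give exactly one of motif or motif_size")
        if self.motif is not None and not is_primitive(self.motif):
            raise SimulationConfigError(
                f"planted motif {self.motif!r} is not primitive")
        if self.region not in {"exon", "intron", "intergenic", "any"}:
            raise SimulationConfigError(f"unknown region {self.region!r}")
        if self.count < 0:
            raise SimulationConfigError("count must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic genome."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 500_000
    n_fraction: float = 0.03
    gene_density: float = 25.0          # genes per Mb
    exons_per_gene: int = 5
    isoform_rate: float = 0.2           # fraction of genes with a 2nd isoform
    plants: tuple[PlantSpec, ...] = ()
    base_composition: tuple[float, float, float, float] = (.25, .25, .25, .25)
    thresholds: ScanThresholds = field(default_factory=ScanThresholds)

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.chrom_length_bp < 1000:
            raise SimulationConfigError(
                "need >= 1 chromosome of >= 1 kb")
        if not (0 <= self.n_fraction < 0.9):
            raise SimulationConfigError("n_fraction must be in [0, 0.9)")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise SimulationConfigError("base_composition must sum to 1")


@dataclass
class SimResult:
    """Generated genome + annotation + truth."""

    genome: GenomeCollection
    annotation: AnnotationModel
    truth_loci: pd.DataFrame
    truth_genome: pd.DataFrame
    region_intervals: dict[str, dict[str, list[Interval]]]
    config: SimConfig
    paths: dict[str, Path] = field(default_factory=dict)


def _make_gene_models(rng, chrom: str, length: int, cfg: SimConfig,
                      gene_offset: int):
    """Place non-overlapping multi-exon genes in equal slots."""
    n_genes = int(round(cfg.gene_density * length / 1e6))
    genes, exons = [], []
    if n_genes == 0:
        return genes, exons
    slot = length // n_genes
    min_exon, max_exon = 120, 320
    min_intron = 400
    for gi in range(n_genes):
        exon_lens = rng.integers(min_exon, max_exon + 1,
                                 size=cfg.exons_per_gene)
        n_introns = cfg.exons_per_gene - 1
        gene_len_min = int(exon_lens.sum()) + n_introns * min_intron
        cap = max(gene_len_min, int(slot * 0.7))
        if cap > slot - 2:
            raise SimulationConfigError(
                "gene models do not fit: increase chrom_length_bp or "
                "decrease gene_density/exons_per_gene")
        gene_len = int(rng.integers(gene_len_min, cap + 1))
        slot_start = gi * slot + 1
        start = slot_start + int(rng.integers(0, slot - gene_len))
        # split the non-exon interior into introns (each >= min_intron)
        spare = gene_len - int(exon_lens.sum()) - n_introns * min_intron
        if n_introns:
            cuts = np.sort(rng.integers(0, spare + 1, size=n_introns - 1)) \
                if n_introns > 1 else np.array([], dtype=int)
            parts = np.diff(np.concatenate(([0], cuts, [spare])))
            intron_lens = parts + min_intron
        else:
            intron_lens = np.array([], dtype=int)
        gid = f"gene{gene_offset + gi}"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(gid, chrom, strand, start,
                                start + gene_len - 1))
        tx1 = f"{gid}.t1"
        pos = start
        gene_exons = []
        for ei in range(cfg.exons_per_gene):
            e_end = pos + int(exon_lens[ei]) - 1
            gene_exons.append((pos, e_end))
            pos = e_end + 1
            if ei < n_introns:
                pos += int(intron_lens[ei])
        for s, e in gene_exons:
            exons.append(ExonRecord(tx1, gid, chrom, s, e))
        if cfg.exons_per_gene >= 3 and rng.random() < cfg.isoform_rate:
            # second isoform skipping one internal exon
            skip = int(rng.integers(1, cfg.exons_per_gene - 1))
            tx2 = f"{gid}.t2"
            for ei, (s, e) in enumerate(gene_exons):
                if ei != skip:
                    exons.append(ExonRecord(tx2, gid, chrom, s, e))
    return genes, exons


class _FreeSpace:
    """Disjoint free intervals per region label, with slot carving."""

    def __init__(self, region_intervals: dict[str, list[Interval]]):
        self.free = {lab: list(iv) for lab, iv in region_intervals.items()}

    def capacity(self, label: str, need: int) -> int:
        return sum(e - s + 1 - need + 1
                   for s, e in self.free[label] if e - s + 1 >= need)

    def carve(self, rng, label: str, need: int) -> int | None:
        """Reserve a sub-interval of ``need`` bases; returns its start."""
        slots = [(i, s, e) for i, (s, e) in enumerate(self.free[label])
                 if e - s + 1 >= need]
        if not slots:
            return None
        weights = np.array([e - s + 1 - need + 1 for _, s, e in slots],
                           dtype=float)
        pick = int(rng.choice(len(slots), p=weights / weights.sum()))
        i, s, e = slots[pick]
        start = s + int(rng.integers(0, e - s + 1 - need + 1))
        del self.free[label][i]
        if start - 1 >= s:
            self.free[label].append((s, start - 1))
        if start + need <= e:
            self.free[label].append((start + need, e))
        self.free[label].sort()
        return start


def _sample_motif(rng, k: int) -> str:
    while True:
        m = "".join("ACGT"[i] for i in rng.integers(0, 4, size=k))
        if is_primitive(m):
            return m


def generate(config: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Generate FASTA + GFF3 + truth for a config; optionally write files.

    Raises :class:`SimulationConfigError` (before writing anything) when
    the plants cannot fit into their target regions.
    """
    rng = np.random.default_rng(config.seed)
    t = config.thresholds

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    length = config.chrom_length_bp

    # --- gene models and the true region partition ---
    all_genes: list[GeneRecord] = []
    all_exons: list[ExonRecord] = []
    region_intervals: dict[str, dict[str, list[Interval]]] = {}
    gene_offset = 1
    for chrom in chrom_names:
        genes, exons = _make_gene_models(rng, chrom, length, config,
                                         gene_offset)
        gene_offset += len(genes)
        all_genes.extend(genes)
        all_exons.extend(exons)
        exon_iv = merge_intervals([(e.start, e.end) for e in exons])
        genic = merge_intervals([(g.start, g.end) for g in genes])
        region_intervals[chrom] = {
            "exon": exon_iv,
            "intron": subtract_intervals(genic, exon_iv),
            "intergenic": subtract_intervals([(1, length)], genic),
        }

    # --- background sequence ---
    arrays: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        arrays[chrom] = _BASES[rng.choice(4, size=length,
                                          p=config.base_composition)].copy()

    # --- plan the plants (feasibility first, then write) ---
    free = {chrom: _FreeSpace(region_intervals[chrom])
            for chrom in chrom_names}
    plant_rows = []
    protected = {chrom: [] for chrom in chrom_names}
    for spec in config.plants:
        for _ in range(spec.count):
            motif = spec.motif or _sample_motif(rng, spec.motif_size)
            k = len(motif)
            if isinstance(spec.unit_count, tuple):
                lo, hi = spec.unit_count
                units = int(rng.integers(lo, hi + 1))
            else:
                units = int(spec.unit_count)
            if units * k < t.min_tract_bp[k]:
                raise SimulationConfigError(
                    f"plant ({motif})x{units} is below the detection "
                    f"threshold of {t.min_tract_bp[k]} bp")
            tract = units * k
            need = tract + 2  # one guard base each side
            labels = ([spec.region] if spec.region != "any"
                      else ["exon", "intron", "intergenic"])
            # pick a chromosome (and label for 'any') with room
            options = [(chrom, lab) for chrom in chrom_names
                       for lab in labels
                       if free[chrom].capacity(lab, need) > 0]
            if not options:
                raise SimulationConfigError(
                    f"no room to plant a {tract}-bp repeat in region "
                    f"{spec.region!r}: planted bp exceeds region bp")
            caps = np.array([free[c].capacity(lab, need)
                             for c, lab in options], dtype=float)
            chrom, lab = options[int(rng.choice(len(options),
                                                p=caps / caps.sum()))]
            slot_start = free[chrom].carve(rng, lab, need)  # 1-based
            pos0 = slot_start  # 0-based tract start = slot_start-1+1
            a = arrays[chrom]
            tract_bytes = (motif * units).encode("ascii")
            a[pos0:pos0 + tract] = np.frombuffer(tract_bytes, dtype=np.uint8)
            # guards: block single-base (hence full-unit) extension
            left_choices = [b for b in b"ACGT" if b != ord(motif[-1])]
            right_choices = [b for b in b"ACGT" if b != ord(motif[0])]
            a[pos0 - 1] = left_choices[int(rng.integers(0, 3))]
            a[pos0 + tract] = right_choices[int(rng.integers(0, 3))]
            protected[chrom].append((pos0 - 1, pos0 + tract))  # 0-based incl.
            plant_rows.append({
                "chrom": chrom, "start": pos0 + 1, "end": pos0 + tract,
                "motif": motif,
                "canonical_class": canonical_class(motif).representative,
                "motif_size": k, "unit_count": units, "region": lab,
            })

    # --- N blocks (intron/intergenic only), exact total per chromosome ---
    for chrom in chrom_names:
        target = int(round(config.n_fraction * length))
        placed = 0
        a = arrays[chrom]
        while placed < target:
            block = min(int(rng.integers(500, 5001)), target - placed)
            lab = None
            for candidate in ("intergenic", "intron"):
                if free[chrom].capacity(candidate, block) > 0:
                    lab = candidate
                    break
            if lab is None:
                # shrink into whatever still fits
                best = max(
                    ((min(e - s + 1, target - placed), candidate)
                     for candidate in ("intergenic", "intron")
                     for s, e in free[chrom].free[candidate]),
                    default=(0, None),
                )
                if best[0] <= 0:
                    raise SimulationConfigError(
                        "cannot reach n_fraction: no free space left for "
                        "N blocks")
                block, lab = best[0], best[1]
            start = free[chrom].carve(rng, lab, block)
            a[start:start + block] = ord("N")
            placed += block

    # --- clean the background: only planted loci may pass the scan ---
    truth_by_chrom: dict[str, set] = {c: set() for c in chrom_names}
    for row in plant_rows:
        truth_by_chrom[row["chrom"]].add(
            (row["start"], row["end"], row["motif"], row["unit_count"]))
    for chrom in chrom_names:
        a = arrays[chrom]
        prot = np.zeros(length, dtype=bool)
        for s0, e0 in protected[chrom]:
            prot[s0:e0 + 1] = True
        for _attempt in range(40):
            s = a.tobytes().decode("ascii")
            found = {(lc.start, lc.end, lc.motif, lc.unit_count)
                     for lc in scan_sequence(s, t, chrom=chrom)}
            extras = found - truth_by_chrom[chrom]
            missing = truth_by_chrom[chrom] - found
            if not extras:
                if missing:  # nothing left to mutate, so truly lost
                    raise RuntimeError(
                        f"internal error: planted loci not recovered on "
                        f"{chrom}: {sorted(missing)[:3]}")
                break
            for (st, en, _m, _u) in extras:
                # mutate the middle-most unprotected base of the run
                idxs = np.flatnonzero(~prot[st - 1:en])
                if idxs.size == 0:  # cannot happen: plants are exact
                    raise RuntimeError("extra locus fully protected")
                i = int(st - 1 + idxs[idxs.size // 2])
                avoid = {a[i]}
                if i > 0:
                    avoid.add(a[i - 1])
                if i < length - 1:
                    avoid.add(a[i + 1])
                choices = [b for b in _BASES if int(b) not in
                           {int(x) for x in avoid}]
                a[i] = choices[int(rng.integers(0, len(choices)))] \
                    if choices else ord("A")
        else:
            raise RuntimeError("background cleaning did not converge")

    # --- assemble outputs ---
    genome = GenomeCollection(
        GenomeSequence(c, arrays[c].tobytes().decode("ascii"))
        for c in chrom_names
    )
    annotation = AnnotationModel(genes=all_genes, exons=all_exons)
    truth_loci = pd.DataFrame(
        plant_rows, columns=["chrom", "start", "end", "motif",
                             "canonical_class", "motif_size", "unit_count",
                             "region"],
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    genome_rows = []
    for c in chrom_names:
        seq = genome[c]
        lens = {lab: sum(e - s + 1 for s, e in region_intervals[c][lab])
                for lab in ("exon", "intron", "intergenic")}
        genome_rows.append({
            "chrom": c, "total_bp": seq.total_length,
            "valid_bp": seq.valid_length, **{f"{lab}_bp": v
                                             for lab, v in lens.items()},
        })
    truth_genome = pd.DataFrame(genome_rows)

    result = SimResult(genome, annotation, truth_loci, truth_genome,
                       region_intervals, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "annotation.gff3",
            "truth_loci": outdir / "truth_loci.tsv",
            "truth_genome": outdir / "truth_genome.tsv",
        }
        write_fasta(genome, paths["fasta"])
        _write_gff3(annotation, genome, paths["gff3"])
        truth_loci.to_csv(paths["truth_loci"], sep="\t", index=False)
        truth_genome.to_csv(paths["truth_genome"], sep="\t", index=False)
        result.paths = paths
    return result


def _write_gff3(ann: AnnotationModel, genome: GenomeCollection,
                path: Path) -> None:
    tx_exons: dict[str, list[ExonRecord]] = {}
    for ex in ann.exons:
        tx_exons.setdefault(ex.transcript_id, []).append(ex)
    by_gene: dict[str, list[str]] = {}
    for tx, exs in tx_exons.items():
        by_gene.setdefault(exs[0].gene_id, []).append(tx)
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for seq in genome:
            out.write(f"##sequence-region {seq.name} 1 {seq.total_length}\n")
        for g in ann.genes:
            out.write(f"{g.chrom}\tssr-atlas-sim\tgene\t{g.start}\t{g.end}"
                      f"\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            for tx in sorted(by_gene.get(g.gene_id, [])):
                exs = sorted(tx_exons[tx], key=lambda e: e.start)
                out.write(
                    f"{g.chrom}\tssr-atlas-sim\tmRNA\t{exs[0].start}"
                    f"\t{exs[-1].end}\t.\t{g.strand}\t.\tID={tx};"
                    f"Parent={g.gene_id}\n")
                for i, ex in enumerate(exs, 1):
                    out.write(
                        f"{g.chrom}\tssr-atlas-sim\texon\t{ex.start}"
                        f"\t{ex.end}\t.\t{g.strand}\t.\tID={tx}.e{i};"
                        f"Parent={tx}\n")


def emulate_survey_profile(template: str, scale: float,
                           seed: int = 0) -> SimConfig:
    """Config whose planted composition follows a surveyed species.

    ``template`` is a species abbreviation from the packaged survey
    tables (e.g. ``"Drer"``); per-size locus counts and per-region
    percentages are scaled by ``scale`` and planted accordingly.
    Categories that scale below one locus are dropped with a warning.
    """
    from . import tables

    if not (0 < scale <= 1):
        raise ValueError("scale must be in (0, 1]")
    summary = tables.repeat_summary()
    comp = tables.region_composition()
    if template not in tables.SPECIES_ABBREVS:
        raise ValueError(f"unknown species template {template!r}")

    total_loci = int(summary.loc[(template, "total"), "n_loci"])
    size_cols = {1: "mono", 2: "di", 3: "tri", 4: "tetra",
                 5: "penta", 6: "hexa"}
    t = ScanThresholds()
    plants = []
    planted_bp = {"exon": 0, "intron": 0, "intergenic": 0}
    for k, col in size_cols.items():
        min_u = t.min_units(k)
        for region in ("intergenic", "intron", "exon"):
            pct = float(comp.loc[(template, region), col])
            n = int(round(total_loci * pct / 100.0 * scale))
            if n == 0:
                if pct > 0:
                    warnings.warn(
                        f"{template}: {col}/{region} scales below one "
                        "locus and is omitted", stacklevel=2)
                continue
            plants.append(PlantSpec(
                count=n, motif_size=k,
                unit_count=(min_u, min_u + 8), region=region,
            ))
            planted_bp[region] += n * (min_u + 4) * k

    # size the genome so each region can host its plants with headroom
    cfg0 = SimConfig()
    exon_frac = (cfg0.gene_density / 1e6) * cfg0.exons_per_gene * 220
    gene_frac = (cfg0.gene_density / 1e6) * 11000
    frac = {"exon": exon_frac, "intron": max(gene_frac - exon_frac, 0.01),
            "intergenic": max(1 - gene_frac, 0.1)}
    need = max(planted_bp[lab] / frac[lab] * 6 for lab in planted_bp)
    chrom_len = int(max(200_000, need))
    return SimConfig(
        seed=seed, n_chroms=1, chrom_length_bp=chrom_len,
        n_fraction=0.02, plants=tuple(plants),
    )
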