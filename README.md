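# ssr-atlas

Genome-wide microsatellite surveys from Python.

Microsatellites (simple sequence repeats, SSRs) are tandem repetitions of
1–6 bp units. Their abundance, length distribution and placement relative
to genes vary strongly between species and genomic compartments, which
makes a standardized whole-genome census — how many repeats, of which
motifs, how long, and where — a recurring need in comparative genomics and
marker development. `ssr-atlas` implements that census as a reusable
pipeline for anyone with a genome FASTA and (optionally) a GFF3
annotation:

1. **Scan** — detect every *perfect* repeat tract (no mismatches or
   indels) whose length meets the per-unit-size minimums: ≥12 bp for
   mononucleotide, ≥14 bp di-, ≥15 bp tri-, ≥16 bp tetra-, ≥20 bp penta-
   and ≥24 bp hexanucleotide repeats. Tracts are maximal, non-overlapping,
   counted in complete units, never contain `N`, and are reported under
   their primitive motif (an ACAC tract is an AC repeat). Up to 200 bp of
   flanking sequence per side is available for marker design.
2. **Canonicalize** — group motifs that are circular permutations and/or
   reverse complements of each other into one class (AC = CA = GT = TG).
   For unit sizes 1–6 there are 2, 4, 10, 33, 102 and 350 classes — 501
   distinct repeat types in total.
3. **Partition** — label every base of every chromosome as exon (union
   across isoforms), intron (genic minus exon) or intergenic, and assign
   each locus the label of its start base.
4. **Summarize** — per motif size and genome-wide: locus counts, repeat
   bp, relative abundance (loci/Mb), relative density (bp/Mb), coverage
   (%), and GC content of the tracts; per-region percent motif abundance;
   per-class count tables; iteration-number bins (<20, 20–50, 50–100,
   100–200, 200–300, >300 unit copies). All per-Mb statistics are
   normalized by **valid length** — assembly length minus `N` bases.

A synthetic-genome generator (`ssr_atlas.simulate`) produces
chromosome-scale FASTA + GFF3 + truth tables with planted repeats on a
background guaranteed free of above-threshold repeats, so the whole
pipeline is testable end to end with exact expectations — including
profiles that mimic the composition of published fish-genome surveys
(packaged in `ssr_atlas.tables`).

## Worked example

`examples/03_simulate_and_survey.py` simulates a 2 × 300 kb genome (4%
N blocks, multi-exon genes) with 260 planted repeats, then runs the full
survey:

```
frequency/density/GC summary (per motif size + total):
            n_loci  total_bp  rel_abundance  rel_density  coverage_pct  gc_bp  gc_pct
motif_size
1              100      2575         173.61      4470.49          0.45   1087   42.21
2              100      3886         173.61      6746.53          0.67   1995   51.34
3               40      1080          69.44      1875.00          0.19    494   45.74
4               20       480          34.72       833.33          0.08    240   50.00
5                0         0           0.00         0.00          0.00      0    0.00
6                0         0           0.00         0.00          0.00      0    0.00
total          260      8021         451.39     13925.35          1.39   3816   47.58

planted loci: 260, recovered: 260, exact match: True
```

Reading the total row: the genome carries 451.39 repeat loci per Mb of
valid sequence, repeat tracts cover 1.39% of it (equivalently
13,925 bp/Mb — coverage% × 10,000 = density by construction), and 47.58%
of tract bases are G or C. "Exact match" means every planted locus was
recovered with identical coordinates, motif and region label, and
nothing else was reported.

The other examples scan a toy sequence (`02`), enumerate the 501 motif
classes (`01`), and recompute the derived columns of a published
14-species fish survey from its raw counts (`04`), e.g. *Oryzias
latipes*: 145,528 loci / 582.14 Mb valid = 249.99 loci/Mb, matching the
printed value.

## Command line

```bash
ssr-atlas run genome.fa --gff3 genes.gff3 --out survey/   # full survey
ssr-atlas scan genome.fa --out loci.tsv --format tsv      # loci only
ssr-atlas lengths genome.fa                               # valid-length report
ssr-atlas motifs --k 4                                    # the 33 tetramer classes
ssr-atlas simulate --seed 17 --out sim/ --plant ATCC:5:exon:10
```

`run` writes a bundle: length report, locus TSV, summary table,
percent-abundance table, per-class counts, iteration bins, and a
manifest with input checksums (re-running reproduces byte-identical
outputs).

## Layout

- `src/ssr_atlas/` — library (`scanner`, `motif`, `regions`, `stats`,
  `sequence_io`, `simulate`, `survey`, `tables`, `cli`)
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — models, parameter choices, numerical conventions
- `tests/` — pytest suite with independent brute-force oracles
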