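# Methods

## Repeat model

A microsatellite locus is a perfect tandem repetition of a primitive
1–6 bp unit. "Perfect" means zero mismatches and indels inside the tract;
"primitive" means the unit is not itself an exact repetition of a shorter
unit, so every tract is reported exactly once, under its shortest unit
(ACACAC… is an AC repeat, never ACAC). Note that primitivity is
*power-freeness*, not the string-period condition: `ATA` has string
period 2 but is a perfectly good trinucleotide unit, and the class
catalogue (10 trinucleotide classes) is only correct under the
power-freeness definition.

Minimum tract lengths default to 12, 14, 15, 16, 20 and 24 bp for unit
sizes 1–6 (at least 12, 7, 5, 4, 4 and 4 complete copies). These are the
conventional "short cutoff" settings used by genome surveys that want to
include repeats liable to disruption by single substitutions; they are
configurable per unit size but every minimum must cover at least two
units. Flanking sequence extraction defaults to 200 bp per side.

### Scanning semantics

The scanner walks each sequence left to right. At a position it
evaluates unit sizes k = 1…6 in increasing order: the run of period k is
extended as far as perfect copies continue, the unit must be primitive
and all-ACGT, and the tract of *complete* units must meet the minimum.
The first qualifying k is emitted, and scanning resumes at the first
base past the whole maximal run — including any trailing partial unit —
so loci never overlap and a poly-A core is never recounted inside a
dinucleotide candidate. Consequences of these tie-breaks:

- `unit_count` ("iteration number") counts complete copies only, and
  `end − start + 1 = motif_size × unit_count` always holds;
- a tract is maximal: it cannot be extended by one unit on either side;
  any non-ACGT character (N or IUPAC ambiguity) is a hard boundary;
- adjacent tracts of different motifs are reported separately; there is
  no compound/imperfect-repeat merging;
- when a partial trailing unit exists, the few trailing bases are
  consumed but unreported; a mirrored scan of the reverse complement
  can therefore differ at such boundaries by the partial offset. On
  complete-unit tracts (e.g. all simulator plants) reverse-complement
  covariance is exact, and the test suite checks it there.

The production implementation vectorizes run discovery (shifted-equality
arrays per period, numpy) and replays the same greedy walk over the few
candidate runs; the test suite holds it to *exact* agreement with an
independent per-base reference walk on tens of thousands of random
sequences, so the semantics above, not the implementation, define the
tool.

## Motif classes

Motifs related by circular permutation and/or reverse complement are one
type; the class representative is the lexicographically smallest member
of the orbit (alphabet A < C < G < T), which matches the conventional
class names (AAT, ACAG, …). Over primitive motifs this yields 2, 4, 10,
33, 102 and 350 classes for sizes 1–6 (501 total); the enumeration is
tested against a brute-force BFS orbit partition rather than asserted as
constants. Counts are kept at class level only; per-strand counts are
not retained.

## Region partition

From GFF3 annotation every base receives exactly one label: exon (union
of exon intervals across all isoforms), intron (gene span minus exon) or
intergenic (complement of gene spans). The partition is strand-agnostic
and exhaustive — per chromosome the three lengths sum exactly to the
sequence length, which the tests assert. Choices where conventions
differ:

- **Isoform precedence**: a base exonic in any isoform is exonic. The
  survey reports a single three-way partition, so the union is the only
  order-independent choice.
- **Boundary-spanning loci** are labeled by their start base (default).
  This is deterministic and independent of locus length; a
  majority-overlap rule is available (`assign="majority"`, ties fall
  back to the start label) to quantify the difference.
- Genes without explicit `gene` features take the union span of their
  transcripts. Features on chromosomes absent from the genome are
  skipped and counted; loci on unannotated chromosomes are `unassigned`
  and excluded from per-region tables.
- N-block bases keep their positional label. Per-Mb denominators use
  genome-wide valid length, not per-region valid lengths, because
  per-region results are reported as counts and percentages.

## Survey statistics

With `L_valid` the assembly length minus N bases: relative abundance =
loci / (L_valid/10⁶); relative density = tract bp / (L_valid/10⁶);
coverage% = 100 × tract bp / L_valid (so coverage% × 10⁴ = density
identically); GC% = 100 × (G+C bases inside tracts) / tract bp, computed
exactly from unit composition × unit count. Valid length is the
denominator because the packaged 14-species survey's printed loci/Mb
values reproduce from valid — not total — lengths (e.g. Olat
145,528/582.14 = 249.99). Lowercase (soft-masked) residues are ordinary
sequence, and ambiguity codes other than N count as valid: only Ns are
subtracted.

Iteration-number bins on the unit count are lower-edge inclusive:
[2,20), [20,50), [50,100), [100,200), [200,300), [300,∞). The printed
interval labels of such surveys are ambiguous at the edges; lower
inclusivity is the documented choice here. "Top motifs" tables rank
classes by descending count (ties alphabetical) and return the shortest
prefix whose cumulative count reaches half the stratum.

Report writers round percentages and per-Mb values to 2 decimals;
internal values keep full precision. No inferential statistics are
computed — the survey is descriptive.

### Packaged reference tables

`ssr_atlas.tables` ships the printed tables of a published 14-species
fish survey (assembly lengths; per-size counts, bp, derived columns;
per-region percent abundance), transcribed with arithmetic
cross-validation (per-size rows must sum to totals, GC% must match GC
bp / total bp, region rows must sum to the "all" row). A few printed
cells are internally inconsistent with their own raw counts (e.g. one
species' total relative density and another's total relative abundance);
they are kept as printed, and recomputation tests use the
self-consistent cells. Because printed inputs are rounded (valid lengths
to 0.01 Mb, outputs to 2 decimals), recomputation tests allow 0.05%
relative error plus half a printed unit-in-the-last-place.

## Synthetic genomes

The generator emulates what the survey consumes, not repeat evolution:

- **Background**: i.i.d. bases from a configurable composition
  (default uniform). Any accidental above-threshold repeat is broken by
  single-base substitution and the chromosome rescanned until the scan
  reports exactly the planted loci — recovery tests are therefore exact,
  not tolerance-based.
- **Gene models**: genes are placed in equal-width slots (default
  25 genes/Mb), each with a fixed number of exons (default 5, 120–320 bp)
  separated by introns ≥400 bp; a configurable fraction of genes gets a
  second isoform that skips one internal exon, exercising the
  exon-union semantics. Defaults give roughly 25% genic sequence, a
  plausible compact-vertebrate-genome figure.
- **Plants**: each planted repeat is a complete-unit tract flanked by
  guard bases chosen so the run cannot extend past its recorded
  coordinates; plants are mutually separated (≥2 background bases) and
  wholly inside one interval of their target region. Exonic plants never
  span a boundary by default. Infeasible demands (planted bp exceeding
  region space) fail before any file is written.
- **N blocks** (default 3%): 500–5000 bp runs of N placed in intronic
  and intergenic space, totalling exactly the configured fraction per
  chromosome.
- `emulate_survey_profile` converts a packaged species row into a plant
  list whose per-size, per-region composition follows the published
  percentages at a chosen scale, for statistical (not exact) end-to-end
  checks.

What the simulator does **not** model: slippage mutation processes,
imperfect/compound repeats, assembly artifacts, soft-masking,
GC-heterogeneous isochores, or realistic gene-length distributions.
Passing recovery tests therefore demonstrates correctness of detection,
classification and accounting — not robustness to sequencing error or
annotation noise in real assemblies.

## Problem sizes in the test suite

Scanner–oracle equivalence runs on 10,000 random 2-kb sequences over
four base compositions (plus N-containing and adversarially duplicated
strings under hypothesis); end-to-end recovery uses five seeds of 1-Mb,
two-chromosome genomes with 500 planted loci each. These sizes give
every code path (all six unit sizes, all three regions, N boundaries,
isoform unions) multiple hits per run while keeping the default suite
around a minute.

## Known limitations

- Exact per-locus agreement with other SSR miners is not guaranteed:
  resume-position and tie-break conventions differ between tools, so
  small count differences on real genomes are expected; the scanning
  semantics here are fully specified above and enforced by the oracle.
- Full-genome replication of the packaged survey (downloading the 14
  assemblies) is a benchmark exercise, not part of the test suite; the
  packaged tables support recomputation of derived columns only.
- The GFF3 reader needs gene/mRNA-or-transcript/exon features with
  `Parent` links; CDS/UTR sub-partitions are out of scope.
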