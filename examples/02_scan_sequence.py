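"""Scan a small sequence for perfect microsatellites.

Builds a toy chromosome with three planted repeats — (A)13, (AC)8 and
(GAT)6 — plus an N gap, scans it with the default minimum tract lengths
(12/14/15/16/20/24 bp for unit sizes 1-6), and prints each detected
locus with its canonical class and 10-bp flanks.
"""

from ssr_atlas import (GenomeSequence, canonical_representative,
                       extract_flanks, scan_sequence)

seq = GenomeSequence("toy", (
    "TGCTGGTCAG" + "A" * 13 + "GTCCTGAGTG" + "AC" * 8 +
    "TGNNNNNNGA" + "GAT" * 6 + "CCTGAGTCGT"
))
for lc in scan_sequence(seq):
    left, right = extract_flanks(lc, seq, flank_bp=10)
    print(f"{lc.chrom}:{lc.start}-{lc.end}  ({lc.motif})x{lc.unit_count} "
          f"class={canonical_representative(lc.motif)} "
          f"tract={lc.tract_length}bp  flanks={left}|{right}")
# Coordinates are 1-based inclusive; the unit count is the number of
# complete motif copies, and tracts never cross the N gap.
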