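"""Perfect microsatellite detection.

A microsatellite (simple sequence repeat, SSR) is a tandem repetition of a
1–6 bp unit. This scanner reports *perfect* tracts only: no mismatches or
indels, with per-unit-size minimum tract lengths (defaults 12, 14, 15, 16,
20 and 24 bp for mono- through hexanucleotide motifs, i.e. at least 12, 7,
5, 4, 4 and 4 complete units).

Reporting rules
---------------
Every reported locus is

* perfect — the spanned subsequence is the motif repeated exactly;
* maximal — it cannot be extended by a unit on either side;
* primitive — the motif is not itself a repetition of a shorter unit
  (an ``ACAC`` tract is always reported under ``AC``);
* complete — a trailing partial unit is excluded, so
  ``tract_length = motif_size * unit_count``.

Loci never contain ``N`` or ambiguity codes; a tract abutting an N block
is maximal at that boundary. Loci are non-overlapping: after a maximal
run is emitted under its smallest-period motif, scanning resumes at the
first base past the run (including any trailing partial unit), so a
poly-A tract is never double-counted inside a dinucleotide candidate.
When several unit sizes qualify at the same position the smallest wins.

The implementation vectorizes run discovery (per-period shifted equality
with numpy) and replays the left-to-right greedy walk over the few
candidate runs, which keeps chromosome-scale scans fast while matching a
straightforward per-base reference walk exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

import numpy as np

from .sequence_io import GenomeCollection, GenomeSequence

DEFAULT_MIN_TRACT = {1: 12, 2: 14, 3: 15, 4: 16, 5: 20, 6: 24}
DEFAULT_FLANK = 200

_ACGT = frozenset(b"ACGT")


def smallest_period(s: str) -> int:
    """Least ``p >= 1`` with ``s[i] == s[i+p]`` for all valid ``i``.

    Note that this string period need not divide ``len(s)`` (e.g. ``ATA``
    has period 2); use :func:`is_primitive` to test whether a motif is a
    repetition of a shorter unit.
    """
    if not s:
        raise ValueError("smallest_period: empty input")
    n = len(s)
    for p in range(1, n + 1):
        if all(s[i] == s[i - p] for i in range(p, n)):
            return p
    return n  # unreachable


def is_primitive(motif: str) -> bool:
    """True if the motif is not an exact repetition of a shorter unit.

    ``AT`` and ``ATA`` are primitive; ``ATAT`` is not (it is ``AT`` twice).
    """
    if not motif:
        raise ValueError("is_primitive: empty input")
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


@dataclass(frozen=True)
class ScanThresholds:
    """Minimum tract lengths (bp) per motif size plus flank length."""

    min_tract_bp: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_TRACT)
    )
    flank_bp: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        for k in range(1, 7):
            if k not in self.min_tract_bp:
                raise ValueError(f"min_tract_bp missing motif size {k}")
            if self.min_tract_bp[k] < 2 * k:
                raise ValueError(
                    f"min_tract_bp[{k}]={self.min_tract_bp[k]} < 2 units"
                )
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")

    def min_units(self, k: int) -> int:
        """Minimum number of complete units for motif size k."""
        return -(-self.min_tract_bp[k] // k)

    @classmethod
    def from_min_lengths(cls, lengths: Iterable[int],
                         flank_bp: int = DEFAULT_FLANK) -> "ScanThresholds":
        vals = list(lengths)
        if len(vals) != 6:
            raise ValueError("expected 6 minimum tract lengths (k=1..6)")
        return cls({k: v for k, v in zip(range(1, 7), vals)}, flank_bp)


@dataclass
class RepeatLocus:
    """One detected perfect microsatellite.

    ``start``/``end`` are 1-based inclusive; ``unit_count`` counts complete
    units (the "iteration number"); ``canonical_class`` and ``region`` are
    filled by the motif and regions stages.
    """

    chrom: str
    start: int
    end: int
    motif: str
    motif_size: int
    unit_count: int
    canonical_class: str | None = None
    region: str = "unassigned"

    @property
    def tract_length(self) -> int:
        return self.motif_size * self.unit_count

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.motif_size * self.unit_count:
            raise ValueError(
                f"inconsistent locus: span {self.end - self.start + 1} != "
                f"{self.motif_size} * {self.unit_count}"
            )


def scan_sequence(seq: Union[GenomeSequence, str],
                  thresholds: ScanThresholds | None = None,
                  chrom: str | None = None) -> list[RepeatLocus]:
    """Detect all perfect microsatellites in one sequence.

    Accepts a :class:`GenomeSequence` or a plain string (``chrom`` names
    the output loci in that case). Returns loci in ascending start order.
    """
    t = thresholds or ScanThresholds()
    if isinstance(seq, GenomeSequence):
        name, s = seq.name, seq.residues
    else:
        name, s = (chrom or ""), seq.upper()
    n = len(s)
    if n == 0:
        return []
    a = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    valid = (a == ord("A")) | (a == ord("C")) | (a == ord("G")) | (a == ord("T"))

    # Per period k, maximal runs where s[j] == s[j+k] over valid bases.
    # A run of L consecutive equalities starting at j spans the sequence
    # interval [j, j+L+k-1] with period k. Runs too short to ever yield a
    # locus, or whose unit is non-primitive (rotation-invariant within a
    # run), are dropped up front.
    run_lists: dict[int, list[tuple[int, int, int]]] = {}
    for k in range(1, 7):
        min_units = t.min_units(k)
        min_full = k * min_units
        runs: list[tuple[int, int, int]] = []
        if n > k:
            eq = (a[k:] == a[:-k]) & valid[k:] & valid[:-k]
            padded = np.empty(eq.size + 2, dtype=bool)
            padded[0] = padded[-1] = False
            padded[1:-1] = eq
            edges = np.flatnonzero(padded[1:] != padded[:-1])
            starts, stops = edges[0::2], edges[1::2]  # eq-index half-open
            full_len = (stops - starts) + k
            keep = full_len >= min_full
            for rs, rstop in zip(starts[keep], stops[keep]):
                if not is_primitive(s[rs:rs + k]):
                    continue
                re_seq = rstop - 1 + k  # inclusive sequence end of the run
                last_ok = re_seq + 1 - min_full  # last qualifying start
                runs.append((rs, re_seq, last_ok))
        run_lists[k] = runs

    loci: list[RepeatLocus] = []
    idx = {k: 0 for k in range(1, 7)}
    pos = 0
    while True:
        # earliest position >= pos where any period qualifies; smallest k wins
        best_pos = None
        best_k = 0
        for k in range(1, 7):
            runs = run_lists[k]
            i = idx[k]
            while i < len(runs) and runs[i][2] < pos:
                i += 1
            idx[k] = i
            if i == len(runs):
                continue
            cand = max(runs[i][0], pos)
            if best_pos is None or cand < best_pos:
                best_pos, best_k = cand, k
        if best_pos is None:
            break
        k = best_k
        rs, re_seq, _ = run_lists[k][idx[k]]
        suffix_full = re_seq - best_pos + 1
        units = suffix_full // k
        tract = units * k
        loci.append(RepeatLocus(
            chrom=name, start=int(best_pos + 1), end=int(best_pos + tract),
            motif=s[best_pos:best_pos + k], motif_size=k,
            unit_count=int(units),
        ))
        pos = re_seq + 1  # resume past the whole run, partial unit included
    return loci


def scan_collection(gc: GenomeCollection,
                    thresholds: ScanThresholds | None = None
                    ) -> list[RepeatLocus]:
    """Scan every sequence of a collection; loci grouped by sequence order."""
    t = thresholds or ScanThresholds()
    loci: list[RepeatLocus] = []
    for seq in gc:
        found = scan_sequence(seq, t)
        loci.extend(found)
    return loci


def extract_flanks(locus: RepeatLocus, seq: GenomeSequence,
                   flank_bp: int = DEFAULT_FLANK) -> tuple[str, str]:
    """Up to ``flank_bp`` bases on each side of a locus.

    Flanks are truncated at sequence ends and returned verbatim (they may
    contain N). Raises if the locus does not lie within the sequence.
    """
    if locus.start < 1 or locus.end > seq.total_length:
        raise ValueError(
            f"locus {locus.chrom}:{locus.start}-{locus.end} outside "
            f"sequence {seq.name} (length {seq.total_length})"
        )
    left = seq.residues[max(0, locus.start - 1 - flank_bp):locus.start - 1]
    right = seq.residues[locus.end:locus.end + flank_bp]
    return left, right
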