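"""Motif canonicalization.

Repeat motifs that are circular permutations and/or reverse complements of
each other describe the same tandem repeat (``AC``, ``CA``, ``GT`` and
``TG`` are one class), so counts are kept per *canonical class*: the
lexicographically smallest string among all rotations of the motif and all
rotations of its reverse complement (alphabet order A < C < G < T). Over
primitive motifs of size 1–6 this yields 2, 4, 10, 33, 102 and 350 classes
respectively — 501 in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .scanner import is_primitive

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string."""
    return s.translate(_COMPLEMENT)[::-1]


def rotations(motif: str) -> list[str]:
    """All circular permutations of a motif, starting with the motif itself."""
    return [motif[i:] + motif[:i] for i in range(len(motif))]


@dataclass(frozen=True, order=True)
class MotifClass:
    """Canonical representative of a rotation/reverse-complement orbit."""

    representative: str

    @property
    def size(self) -> int:
        return len(self.representative)

    def members(self) -> list[str]:
        """All motifs in the orbit, sorted."""
        orbit = set(rotations(self.representative))
        orbit |= set(rotations(revcomp(self.representative)))
        return sorted(orbit)

    def __str__(self) -> str:
        return self.representative


def canonical_class(motif: str) -> MotifClass:
    """Canonical class of a primitive motif.

    Raises on non-ACGT characters or a motif that is a repetition of a
    shorter unit (the scanner never produces those).
    """
    if not motif or any(c not in "ACGT" for c in motif):
        raise ValueError(f"motif must be non-empty over ACGT, got {motif!r}")
    if not (1 <= len(motif) <= 6):
        raise ValueError(f"motif size must be 1..6, got {len(motif)}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is a repetition of a shorter unit")
    rep = min(min(rotations(motif)), min(rotations(revcomp(motif))))
    return MotifClass(rep)


def canonical_representative(motif: str) -> str:
    """Convenience: the representative string of :func:`canonical_class`."""
    return canonical_class(motif).representative


def enumerate_classes(k: int) -> list[MotifClass]:
    """All canonical classes of primitive k-mers, sorted by representative.

    Counts for k = 1..6 are 2, 4, 10, 33, 102 and 350.
    """
    if not (1 <= k <= 6):
        raise ValueError(f"motif size must be 1..6, got {k}")
    reps = set()
    for tup in product("ACGT", repeat=k):
        m = "".join(tup)
        if is_primitive(m):
            reps.add(canonical_class(m))
    return sorted(reps)


def annotate_loci(loci) -> None:
    """Fill ``canonical_class`` on loci in place."""
    cache: dict[str, str] = {}
    for lc in loci:
        rep = cache.get(lc.motif)
        if rep is None:
            rep = canonical_class(lc.motif).representative
            cache[lc.motif] = rep
        lc.canonical_class = rep
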