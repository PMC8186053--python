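"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized/merged code paths:
the scanner oracle is a per-base greedy walk, the orbit oracle builds
motif classes by explicit BFS over rotation/reverse-complement moves,
and the region oracle paints a per-base label array.
"""

from __future__ import annotations

from itertools import product

import numpy as np

DEFAULT_MIN = {1: 12, 2: 14, 3: 15, 4: 16, 5: 20, 6: 24}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def power_free(m: str) -> bool:
    k = len(m)
    for d in range(1, k):
        if k % d == 0 and m == m[:d] * (k // d):
            return False
    return True


def naive_scan(s: str, min_tract: dict[int, int] | None = None):
    """Per-base greedy walk: at each position try unit sizes 1..6 in
    order, extend the perfect run as far as it goes, and emit complete
    units when the tract meets the size's minimum; then resume after the
    whole run. Returns (start_1based, end_1based, motif, units) tuples.
    """
    mins = min_tract or DEFAULT_MIN
    min_units = {k: -(-mins[k] // k) for k in range(1, 7)}
    pf_cache: dict[str, bool] = {}
    acgt = frozenset("ACGT")
    n = len(s)
    out = []
    pos = 0
    while pos < n:
        hit = False
        c0 = s[pos]
        for k in range(1, 7):
            # a qualifying tract needs >= 2 units, hence s[pos+k] == s[pos]
            if pos + k >= n or s[pos + k] != c0:
                continue
            unit = s[pos:pos + k]
            pf = pf_cache.get(unit)
            if pf is None:
                pf = all(c in acgt for c in unit) and power_free(unit)
                pf_cache[unit] = pf
            if not pf:
                continue
            ell = k
            while pos + ell < n and s[pos + ell] == s[pos + ell - k]:
                ell += 1
            units = ell // k
            tract = units * k
            if units >= min_units[k]:
                out.append((pos + 1, pos + tract, unit, units))
                pos += ell
                hit = True
                break
        if not hit:
            pos += 1
    return out


def orbit_classes(k: int) -> list[frozenset]:
    """Partition primitive k-mers into orbits by BFS over rotations and
    reverse complements; returns the set of orbits (each a frozenset)."""
    prim = ["".join(p) for p in product("ACGT", repeat=k)
            if power_free("".join(p))]
    seen: set[str] = set()
    orbits: list[frozenset] = []
    for m in prim:
        if m in seen:
            continue
        frontier = [m]
        orbit = set()
        while frontier:
            x = frontier.pop()
            if x in orbit:
                continue
            orbit.add(x)
            frontier.append(x[1:] + x[0])
            frontier.append(rc(x))
        orbits.append(frozenset(orbit))
        seen |= orbit
    return orbits


def per_base_labels(genes, exons, length: int) -> np.ndarray:
    """0=intergenic, 1=intron, 2=exon painted base by base (1-based
    inputs; index 0 of the result is base 1)."""
    lab = np.zeros(length, dtype=np.int8)
    for g in genes:
        s, e = max(1, g[0]), min(length, g[1])
        if s <= e:
            lab[s - 1:e] = np.maximum(lab[s - 1:e], 1)
    for ex in exons:
        s, e = max(1, ex[0]), min(length, ex[1])
        if s <= e:
            lab[s - 1:e] = 2
    return lab
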