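"""Survey statistics over a set of repeat loci.

All per-megabase quantities are normalized by *valid* length (assembly
length minus Ns):

* relative abundance — loci / Mb;
* relative density — repeat bp / Mb;
* coverage — 100 × repeat bp / valid bp (so coverage% × 10,000 = density);
* GC content — 100 × (G+C bases inside tracts) / repeat bp.

Tables are pandas DataFrames; values are kept at full precision with
rounding applied only by report writers.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .motif import enumerate_classes

MOTIF_SIZE_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra",
                    5: "penta", 6: "hexa"}

ITERATION_BIN_LABELS = ("<20", "20-50", "50-100", "100-200", "200-300", ">300")
_BIN_EDGES = (20, 50, 100, 200, 300)


def loci_to_frame(loci: Iterable) -> pd.DataFrame:
    """Locus list as a DataFrame (one row per locus)."""
    rows = [{
        "chrom": lc.chrom, "start": lc.start, "end": lc.end,
        "motif": lc.motif, "motif_size": lc.motif_size,
        "canonical_class": lc.canonical_class,
        "unit_count": lc.unit_count, "tract_length": lc.tract_length,
        "region": lc.region,
    } for lc in loci]
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "motif", "motif_size", "canonical_class",
        "unit_count", "tract_length", "region",
    ])


def _gc_bp(lc) -> int:
    # tract is the motif repeated exactly, so count per unit and multiply
    return (lc.motif.count("G") + lc.motif.count("C")) * lc.unit_count


def summary_from_counts(n_loci: int, total_bp: int, valid_length: int,
                        gc_bp: int = 0) -> dict:
    """Derived columns from raw counts (also usable on published counts)."""
    if valid_length <= 0:
        raise ValueError("valid_length must be positive")
    mb = valid_length / 1e6
    return {
        "n_loci": n_loci,
        "total_bp": total_bp,
        "rel_abundance": n_loci / mb,
        "rel_density": total_bp / mb,
        "coverage_pct": 100.0 * total_bp / valid_length,
        "gc_bp": gc_bp,
        "gc_pct": (100.0 * gc_bp / total_bp) if total_bp else 0.0,
    }


def summarize(loci: Sequence, valid_length: int) -> pd.DataFrame:
    """Frequency/density/GC summary per motif size plus a total row.

    Indexed by motif size 1..6 plus ``"total"``; motif-size rows sum to
    the total row for counts, bp and GC bp.
    """
    if valid_length <= 0:
        raise ValueError("valid_length must be positive")
    per_size = {k: [0, 0, 0] for k in range(1, 7)}  # n, bp, gc
    for lc in loci:
        acc = per_size[lc.motif_size]
        acc[0] += 1
        acc[1] += lc.tract_length
        acc[2] += _gc_bp(lc)
    rows = {}
    tot = [0, 0, 0]
    for k in range(1, 7):
        n, bp, gc = per_size[k]
        rows[k] = summary_from_counts(n, bp, valid_length, gc)
        tot = [t + v for t, v in zip(tot, per_size[k])]
    rows["total"] = summary_from_counts(tot[0], tot[1], valid_length, tot[2])
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "motif_size"
    return df


def percent_motif_abundance(loci: Sequence) -> pd.DataFrame:
    """Percent of all loci per (region, motif size).

    Rows: ``all``, ``intergenic``, ``intron``, ``exon`` (plus
    ``unassigned`` when present); columns: motif sizes 1..6. Each cell is
    100 × count / total loci, so the ``all`` row equals the sum of the
    region rows and all its cells sum to 100.
    """
    total = len(loci)
    regions = ["intergenic", "intron", "exon"]
    if any(lc.region == "unassigned" for lc in loci):
        regions.append("unassigned")
    counts = {r: {k: 0 for k in range(1, 7)} for r in regions}
    for lc in loci:
        counts.setdefault(lc.region, {k: 0 for k in range(1, 7)})
        counts[lc.region][lc.motif_size] += 1
    rows = {}
    rows["all"] = {
        k: 100.0 * sum(counts[r][k] for r in counts) / total if total else 0.0
        for k in range(1, 7)
    }
    for r in regions:
        rows[r] = {
            k: (100.0 * counts[r][k] / total if total else 0.0)
            for k in range(1, 7)
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "region"
    return df


def motif_count_table(loci: Sequence, region: str | None = None,
                      k: int | None = None) -> pd.DataFrame:
    """Counts per canonical class for a region and motif size.

    Absent classes are reported with 0 so the table always covers the
    full class enumeration for size ``k``. With ``region=None`` counts
    span all regions; with ``k=None`` all sizes are stacked.
    """
    sizes = [k] if k is not None else list(range(1, 7))
    counts: dict[tuple[str, int], int] = {}
    for kk in sizes:
        for cls in enumerate_classes(kk):
            counts[(cls.representative, kk)] = 0
    for lc in loci:
        if region is not None and lc.region != region:
            continue
        if lc.motif_size not in sizes:
            continue
        if lc.canonical_class is None:
            raise ValueError("loci must carry canonical_class; run "
                             "motif.annotate_loci first")
        counts[(lc.canonical_class, lc.motif_size)] += 1
    rows = [
        {"canonical_class": rep, "motif_size": kk,
         "region": region or "all", "count": c}
        for (rep, kk), c in sorted(counts.items(),
                                   key=lambda x: (x[0][1], x[0][0]))
    ]
    return pd.DataFrame(rows, columns=["canonical_class", "motif_size",
                                       "region", "count"])


def top_motifs_half(loci: Sequence, region: str | None = None,
                    k: int | None = None) -> list[tuple[str, int]]:
    """Shortest descending-count prefix of classes covering >= 50% of loci.

    Classes are ranked by count (ties by representative, alphabetical);
    the cumulative threshold is half the loci of the chosen stratum.
    Empty stratum -> empty list.
    """
    table = motif_count_table(loci, region=region, k=k)
    total = int(table["count"].sum())
    if total == 0:
        return []
    ranked = table.sort_values(
        ["count", "canonical_class"], ascending=[False, True]
    )
    out: list[tuple[str, int]] = []
    cum = 0
    for _, row in ranked.iterrows():
        out.append((row["canonical_class"], int(row["count"])))
        cum += int(row["count"])
        if 2 * cum >= total:
            break
    return out


def iteration_bins(loci: Sequence) -> pd.DataFrame:
    """Locus counts per (motif size, iteration-number bin).

    Bins on the unit count, lower edge inclusive: [2,20), [20,50),
    [50,100), [100,200), [200,300), [300,inf). Also reports each bin as
    a percentage of that motif size's loci.
    """
    counts = {k: [0] * len(ITERATION_BIN_LABELS) for k in range(1, 7)}
    for lc in loci:
        u = lc.unit_count
        b = 0
        for edge in _BIN_EDGES:
            if u < edge:
                break
            b += 1
        counts[lc.motif_size][b] += 1
    rows = []
    for k in range(1, 7):
        n_k = sum(counts[k])
        for label, c in zip(ITERATION_BIN_LABELS, counts[k]):
            rows.append({
                "motif_size": k, "bin": label, "count": c,
                "pct_of_size": (100.0 * c / n_k) if n_k else 0.0,
            })
    return pd.DataFrame(rows, columns=["motif_size", "bin", "count",
                                       "pct_of_size"])
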