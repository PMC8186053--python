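"""Survey statistics: summary columns, composition tables, bins."""

import numpy as np
import pandas as pd
import pytest

from ssr_atlas.motif import annotate_loci
from ssr_atlas.scanner import RepeatLocus
from ssr_atlas.stats import (ITERATION_BIN_LABELS, iteration_bins,
                             motif_count_table, percent_motif_abundance,
                             summarize, summary_from_counts,
                             top_motifs_half)


def locus(motif, units, region="unassigned", chrom="c", start=1):
    lc = RepeatLocus(chrom, start, start + len(motif) * units - 1,
                     motif, len(motif), units, region=region)
    annotate_loci([lc])
    return lc


class TestSummarize:
    def test_gc_extremes(self):
        at = summarize([locus("AT", 7)], valid_length=10_000)
        assert at.loc[2, "gc_pct"] == 0.0
        cg = summarize([locus("CG", 7)], valid_length=10_000)
        assert cg.loc[2, "gc_pct"] == 100.0

    def test_per_mb_normalization(self):
        df = summarize([locus("A", 12), locus("AC", 7)],
                       valid_length=2_000_000)
        assert df.loc["total", "n_loci"] == 2
        assert df.loc["total", "rel_abundance"] == pytest.approx(1.0)
        assert df.loc["total", "rel_density"] == pytest.approx(26 / 2)

    def test_coverage_density_identity(self):
        df = summarize([locus("AGG", 10), locus("A", 20)],
                       valid_length=123_456)
        for _, row in df.iterrows():
            assert row["coverage_pct"] * 10_000 == \
                pytest.approx(row["rel_density"])

    def test_size_rows_sum_to_total(self):
        rng = np.random.default_rng(2)
        motifs = {1: "A", 2: "AT", 3: "ACG", 4: "AAGG", 5: "ACGTC",
                  6: "AACGGT"}
        loci = [locus(motifs[int(rng.integers(1, 7))],
                      int(rng.integers(4, 30))) for _ in range(200)]
        df = summarize(loci, valid_length=10**6)
        for col in ("n_loci", "total_bp", "gc_bp"):
            assert df.loc[1:6, col].sum() == df.loc["total", col]

    def test_zero_valid_length_rejected(self):
        with pytest.raises(ValueError):
            summarize([], valid_length=0)

    def test_counts_helper_on_known_numbers(self):
        row = summary_from_counts(100, 5000, 10**7, gc_bp=2500)
        assert row["rel_abundance"] == pytest.approx(10.0)
        assert row["rel_density"] == pytest.approx(500.0)
        assert row["coverage_pct"] == pytest.approx(0.05)
        assert row["gc_pct"] == pytest.approx(50.0)


class TestPercentMotifAbundance:
    def test_single_stratum(self):
        loci = [locus("A", 15, region="exon") for _ in range(5)]
        df = percent_motif_abundance(loci)
        assert df.loc["exon", 1] == 100.0
        assert df.loc["all", 1] == 100.0
        assert df.values.sum() == pytest.approx(200.0)  # all + regions

    def test_all_row_is_sum_of_regions(self):
        rng = np.random.default_rng(4)
        regions = ["exon", "intron", "intergenic"]
        loci = [locus("AC", 8, region=regions[int(rng.integers(0, 3))])
                for _ in range(60)]
        loci += [locus("A", 14, region="intron") for _ in range(20)]
        df = percent_motif_abundance(loci)
        for k in range(1, 7):
            assert df.loc["all", k] == pytest.approx(
                df.loc[regions, k].sum())
        assert df.loc["all"].sum() == pytest.approx(100.0)

    def test_unassigned_counted_in_all(self):
        loci = [locus("A", 12, region="unassigned"),
                locus("A", 12, region="intron")]
        df = percent_motif_abundance(loci)
        assert df.loc["all", 1] == 100.0
        assert df.loc["unassigned", 1] == 50.0


class TestMotifCountTable:
    def test_zero_filled_enumeration(self):
        df = motif_count_table([], region="exon", k=3)
        assert len(df) == 10
        assert (df["count"] == 0).all()

    def test_planted_counts(self):
        loci = [locus("AAT", 5, region="exon") for _ in range(5)]
        loci += [locus("TTA", 5, region="exon")]  # same class as AAT
        loci += [locus("AAT", 5, region="intron")]
        df = motif_count_table(loci, region="exon", k=3)
        assert df.set_index("canonical_class").loc["AAT", "count"] == 6

    def test_matches_bruteforce_groupby(self):
        rng = np.random.default_rng(8)
        from ssr_atlas.motif import enumerate_classes
        choices = [c.representative for c in enumerate_classes(2)]
        regions = ["exon", "intron", "intergenic"]
        loci = [locus(choices[int(rng.integers(0, 4))], 8,
                      region=regions[int(rng.integers(0, 3))])
                for _ in range(300)]
        df = motif_count_table(loci, region="intron", k=2)
        brute = {}
        for lc in loci:
            if lc.region == "intron":
                brute[lc.canonical_class] = \
                    brute.get(lc.canonical_class, 0) + 1
        got = df.set_index("canonical_class")["count"].to_dict()
        for cls in choices:
            assert got[cls] == brute.get(cls, 0)


class TestTopMotifsHalf:
    def test_simple_majority(self):
        loci = [locus("AAT", 5, region="exon")] * 6 + \
               [locus("ACC", 5, region="exon")] * 3 + \
               [locus("AGG", 5, region="exon")] * 1
        assert top_motifs_half(loci, region="exon", k=3) == [("AAT", 6)]

    def test_exact_half_with_tiebreak(self):
        loci = [locus("A", 12)] * 5 + [locus("C", 12)] * 5
        assert top_motifs_half(loci, k=1) == [("A", 5)]

    def test_matches_cumulative_scan(self):
        rng = np.random.default_rng(12)
        from ssr_atlas.motif import enumerate_classes
        reps = [c.representative for c in enumerate_classes(3)]
        weights = rng.dirichlet(np.ones(len(reps)) * 0.3)
        loci = [locus(reps[int(i)], 5)
                for i in rng.choice(len(reps), size=400, p=weights)]
        got = top_motifs_half(loci, k=3)
        counts = {}
        for lc in loci:
            counts[lc.canonical_class] = counts.get(lc.canonical_class, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        cum, expect = 0, []
        for cls, c in ranked:
            expect.append((cls, c))
            cum += c
            if 2 * cum >= len(loci):
                break
        assert got == expect

    def test_empty_stratum(self):
        assert top_motifs_half([], region="exon", k=4) == []


class TestIterationBins:
    @pytest.mark.parametrize("units,label", [
        (2, "<20"), (19, "<20"), (20, "20-50"), (49, "20-50"),
        (50, "50-100"), (100, "100-200"), (200, "200-300"),
        (300, ">300"), (1000, ">300"),
    ])
    def test_edges_lower_inclusive(self, units, label):
        df = iteration_bins([locus("A", units)])
        row = df[(df["motif_size"] == 1) & (df["bin"] == label)]
        assert row["count"].iloc[0] == 1
        assert df["count"].sum() == 1

    def test_matches_direct_histogram(self):
        rng = np.random.default_rng(6)
        units = rng.integers(4, 400, size=500)
        loci = [locus("AC", int(u)) for u in units]
        df = iteration_bins(loci)
        edges = [0, 20, 50, 100, 200, 300, np.inf]
        hist, _ = np.histogram(units, bins=edges)
        di = df[df["motif_size"] == 2].set_index("bin")["count"]
        for label, h in zip(ITERATION_BIN_LABELS, hist):
            assert di[label] == h
        pct = df[df["motif_size"] == 2]["pct_of_size"]
        assert pct.sum() == pytest.approx(100.0)

    def test_counts_sum_to_size_totals(self):
        loci = [locus("A", 25)] * 3 + [locus("AC", 7)] * 4
        df = iteration_bins(loci)
        sums = df.groupby("motif_size")["count"].sum()
        assert sums[1] == 3 and sums[2] == 4
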