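"""FASTA/GFF3 input, length accounting, and locus serialization."""

import numpy as np
import pytest

from ssr_atlas.motif import annotate_loci
from ssr_atlas.scanner import RepeatLocus
from ssr_atlas.sequence_io import (DuplicateSequenceError, FastaFormatError,
                                   GenomeCollection, GenomeSequence,
                                   compute_length_report, read_fasta,
                                   read_gff3, read_loci, write_loci)


def write(path, text):
    path.write_text(text)
    return path


class TestReadFasta:
    def test_single_record(self, tmp_path):
        gc = read_fasta(write(tmp_path / "a.fa", ">chr1\nAAAAAAAAAA\n"))
        assert len(gc) == 1
        assert gc["chr1"].total_length == 10
        assert gc["chr1"].valid_length == 10

    def test_n_subtraction_and_case(self, tmp_path):
        gc = read_fasta(write(tmp_path / "a.fa", ">s\nacgtNNNNac\n"))
        assert gc["s"].residues == "ACGTNNNNAC"
        assert gc["s"].total_length == 10
        assert gc["s"].valid_length == 6

    def test_record_order_preserved(self, tmp_path):
        gc = read_fasta(write(tmp_path / "a.fa",
                              ">b\nACGT\n>a\nACGT\n>c\nAC\n"))
        assert gc.names == ["b", "a", "c"]

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(FastaFormatError, match="line 1"):
            read_fasta(write(tmp_path / "a.fa", ""))

    def test_headerless_file_rejected(self, tmp_path):
        with pytest.raises(FastaFormatError, match="line 1"):
            read_fasta(write(tmp_path / "a.fa", "ACGT\n"))

    def test_duplicate_identifier_rejected(self, tmp_path):
        with pytest.raises(DuplicateSequenceError):
            read_fasta(write(tmp_path / "a.fa", ">x\nAC\n>x\nGT\n"))

    def test_generated_genome_n_fraction(self, sim_bundle):
        """Parsed %N matches an independent single-pass N counter and the
        generator's configured fraction to within 0.01."""
        gc = read_fasta(sim_bundle.paths["fasta"])
        for seq in gc:
            n_count = sum(1 for c in seq.residues if c == "N")
            assert seq.valid_length == seq.total_length - n_count
        assert abs(gc.n_pct - 100 * sim_bundle.config.n_fraction) < 0.01


class TestLengthReport:
    def test_totals_and_pct(self):
        gc = GenomeCollection([GenomeSequence("a", "ACGTACGT"),
                               GenomeSequence("b", "NNNN")])
        rep = compute_length_report(gc)
        assert list(rep["name"]) == ["a", "b", "TOTAL"]
        b = rep.set_index("name").loc["b"]
        assert b["valid_bp"] == 0 and b["n_pct"] == 100.0
        total = rep.set_index("name").loc["TOTAL"]
        assert total["total_bp"] == 12 and total["valid_bp"] == 8
        a = rep.set_index("name").loc["a"]
        assert a["n_pct"] == 0.0

    def test_matches_generator_truth(self, sim_bundle):
        rep = compute_length_report(sim_bundle.genome).set_index("name")
        for row in sim_bundle.truth_genome.itertuples():
            assert rep.loc[row.chrom, "total_bp"] == row.total_bp
            assert rep.loc[row.chrom, "valid_bp"] == row.valid_bp

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            compute_length_report(GenomeCollection())


class TestReadGff3:
    def test_single_gene_single_exon(self, tmp_path):
        gff = write(tmp_path / "a.gff3", "\n".join([
            "##gff-version 3",
            "chr1\t.\tgene\t100\t500\t.\t+\t.\tID=g1",
            "chr1\t.\tmRNA\t100\t500\t.\t+\t.\tID=t1;Parent=g1",
            "chr1\t.\texon\t100\t500\t.\t+\t.\tID=e1;Parent=t1",
        ]) + "\n")
        ann = read_gff3(gff)
        assert len(ann.genes) == 1 and len(ann.exons) == 1
        assert ann.genes[0].start == 100 and ann.genes[0].end == 500
        assert ann.exons[0].gene_id == "g1"

    def test_shared_exon_recorded_per_transcript(self, tmp_path):
        gff = write(tmp_path / "a.gff3", "\n".join([
            "##gff-version 3",
            "chr1\t.\tgene\t1\t900\t.\t+\t.\tID=g1",
            "chr1\t.\tmRNA\t1\t900\t.\t+\t.\tID=t1;Parent=g1",
            "chr1\t.\tmRNA\t1\t900\t.\t+\t.\tID=t2;Parent=g1",
            "chr1\t.\texon\t1\t200\t.\t+\t.\tID=e1;Parent=t1,t2",
        ]) + "\n")
        ann = read_gff3(gff)
        assert len(ann.exons) == 2  # once per transcript; dedup downstream
        assert {e.transcript_id for e in ann.exons} == {"t1", "t2"}

    def test_orphan_exon_warns(self, tmp_path):
        gff = write(tmp_path / "a.gff3", "\n".join([
            "##gff-version 3",
            "chr1\t.\tgene\t1\t500\t.\t+\t.\tID=g1",
            "chr1\t.\texon\t10\t50\t.\t+\t.\tID=e1;Parent=ghost",
        ]) + "\n")
        with pytest.warns(UserWarning, match="unresolvable"):
            ann = read_gff3(gff)
        assert len(ann.orphan_exons) == 1
        assert len(ann.exons) == 0

    def test_simulator_counts_match_truth(self, sim_bundle):
        ann = read_gff3(sim_bundle.paths["gff3"])
        assert len(ann.genes) == len(sim_bundle.annotation.genes)
        assert len(ann.exons) == len(sim_bundle.annotation.exons)
        got = {(e.transcript_id, e.chrom, e.start, e.end)
               for e in ann.exons}
        want = {(e.transcript_id, e.chrom, e.start, e.end)
                for e in sim_bundle.annotation.exons}
        assert got == want


def _random_loci(rng, n):
    loci = []
    for i in range(n):
        k = int(rng.integers(1, 7))
        units = int(rng.integers(max(2, -(-12 // k)), 40))
        start = int(rng.integers(1, 10_000))
        motifs = {1: "A", 2: "AC", 3: "AGG", 4: "ATCC", 5: "AATGC",
                  6: "ACGTAC"}
        lc = RepeatLocus(f"chr{int(rng.integers(1, 4))}", start,
                         start + k * units - 1, motifs[k], k, units)
        loci.append(lc)
    annotate_loci(loci)
    return loci


class TestWriteLoci:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        loci = _random_loci(rng, 1000)
        path = tmp_path / "loci.tsv"
        write_loci(loci, path, "tsv")
        back = read_loci(path)
        assert [(a.chrom, a.start, a.end, a.motif, a.canonical_class,
                 a.unit_count, a.tract_length, a.region) for a in loci] == \
               [(b.chrom, b.start, b.end, b.motif, b.canonical_class,
                 b.unit_count, b.tract_length, b.region) for b in back]

    def test_bed_coordinate_convention(self, tmp_path):
        lc = RepeatLocus("chr1", 11, 22, "AC", 2, 6)
        path = tmp_path / "loci.bed"
        write_loci([lc], path, "bed")
        fields = path.read_text().strip().split("\t")
        assert fields[:3] == ["chr1", "10", "22"]

    def test_gff3_coordinate_convention(self, tmp_path):
        lc = RepeatLocus("chr1", 11, 22, "AC", 2, 6)
        path = tmp_path / "loci.gff3"
        write_loci([lc], path, "gff3")
        line = path.read_text().splitlines()[1].split("\t")
        assert (line[0], line[3], line[4]) == ("chr1", "11", "22")

    def test_bed_and_gff3_describe_same_interval(self, tmp_path):
        rng = np.random.default_rng(3)
        loci = _random_loci(rng, 50)
        write_loci(loci, tmp_path / "x.bed", "bed")
        write_loci(loci, tmp_path / "x.gff3", "gff3")
        bed = [l.split("\t") for l in
               (tmp_path / "x.bed").read_text().splitlines()]
        gff = [l.split("\t") for l in
               (tmp_path / "x.gff3").read_text().splitlines()[1:]]
        for b, g in zip(bed, gff):
            assert int(b[1]) == int(g[3]) - 1
            assert int(b[2]) == int(g[4])

    def test_empty_list_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_loci([], path, "tsv")
        assert path.read_text().strip().startswith("chrom\tstart")
        assert read_loci(path) == []

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_loci([], tmp_path / "x", "vcf")
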