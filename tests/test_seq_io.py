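"""Format readers/writers: validation, coordinate conventions, round-trips."""

import numpy as np
import pytest

from holotools import seq_io
from holotools.seq_io import (
    AlignmentError,
    CoordinateError,
    GeneModel,
    GroupTableError,
    KmerHistogram,
    ProteinAlignment,
    SnpTable,
)


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestAlignment:
    def test_parse_normalises_case_and_dots(self, tmp_path):
        path = write(tmp_path, "a.fasta", ">s1\nmkl.\n>s2\nMKLV\n")
        aln = seq_io.read_alignment(path)
        assert aln.length == 4
        assert aln.rows == ("MKL-", "MKLV")

    def test_ragged_alignment_names_offender(self, tmp_path):
        path = write(tmp_path, "a.fasta", ">s1\nMKLV\n>s2\nMKLVA\n")
        with pytest.raises(AlignmentError, match="s2"):
            seq_io.read_alignment(path)

    def test_illegal_character_reports_position(self, tmp_path):
        path = write(tmp_path, "a.fasta", ">s1\nMKOV\n>s2\nMKLV\n")
        with pytest.raises(AlignmentError, match="column 2"):
            seq_io.read_alignment(path)

    def test_single_record_rejected(self, tmp_path):
        path = write(tmp_path, "a.fasta", ">s1\nMKLV\n")
        with pytest.raises(AlignmentError, match=">=2"):
            seq_io.read_alignment(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(AlignmentError, match="duplicate"):
            ProteinAlignment(ids=("a", "a"), rows=("MK", "ML"))

    def test_round_trip_identity(self, tmp_path):
        aln = ProteinAlignment(ids=("s1", "s2"), rows=("MK-X", "MKLV"))
        seq_io.write_alignment(aln, tmp_path / "out.fasta")
        assert seq_io.read_alignment(tmp_path / "out.fasta") == aln


class TestGroups:
    def test_read_full_table(self, tmp_path):
        path = write(
            tmp_path, "g.tsv",
            "id\tfunctional_group\tanimal_clade\n"
            "p1\tplant_BAS\tnone\np2\tplant_CAS\tnone\na1\tanimal_LAS\tprotostome\n",
        )
        groups = seq_io.read_groups(path)
        assert len(groups.assignment) == 3
        assert groups.animal_clade("a1") == "protostome"

    def test_unknown_vocabulary_rejected(self, tmp_path):
        path = write(tmp_path, "g.tsv", "a1\tLAS_animal\tprotostome\n")
        with pytest.raises(GroupTableError, match="LAS_animal"):
            seq_io.read_groups(path)

    def test_plant_with_clade_rejected(self, tmp_path):
        path = write(tmp_path, "g.tsv", "p1\tplant_BAS\tprotostome\n")
        with pytest.raises(GroupTableError):
            seq_io.read_groups(path)

    def test_conflicting_duplicate_rejected(self, tmp_path):
        path = write(
            tmp_path, "g.tsv",
            "a1\tanimal_LAS\tprotostome\na1\tanimal_LAS\tdeuterostome\n",
        )
        with pytest.raises(GroupTableError, match="conflicting"):
            seq_io.read_groups(path)

    def test_missing_alignment_id_reported(self, tmp_path):
        path = write(tmp_path, "g.tsv", "s1\tanimal_LAS\tprotostome\n")
        groups = seq_io.read_groups(path)
        aln = ProteinAlignment(ids=("s1", "s2"), rows=("MK", "ML"))
        with pytest.raises(GroupTableError, match="s2"):
            groups.require_cover(aln)

    def test_round_trip(self, tmp_path):
        groups = seq_io.read_groups(
            write(tmp_path, "g.tsv", "a1\tanimal_LAS\tdeuterostome\np1\tplant_BAS\tnone\n")
        )
        seq_io.write_groups(groups, tmp_path / "out.tsv")
        assert seq_io.read_groups(tmp_path / "out.tsv") == groups


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chrom1,length=1000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


class TestSnps:
    lengths = {"chrom1": 1000}

    def test_vcf_position_shifts_to_zero_based(self, tmp_path):
        path = write(tmp_path, "v.vcf", VCF_HEADER + "chrom1\t1\t.\tA\tT\t.\t.\t.\n")
        snps = seq_io.read_snps(path, self.lengths)
        assert list(snps.positions["chrom1"]) == [0]

    def test_duplicate_records_collapse(self, tmp_path):
        rows = "chrom1\t5\t.\tA\tT\t.\t.\t.\n" * 2
        snps = seq_io.read_snps(write(tmp_path, "v.vcf", VCF_HEADER + rows), self.lengths)
        assert snps.n_snps == 1

    def test_out_of_range_position_rejected(self, tmp_path):
        path = write(tmp_path, "v.vcf", VCF_HEADER + "chrom1\t1001\t.\tA\tT\t.\t.\t.\n")
        with pytest.raises((CoordinateError, ValueError)):
            seq_io.read_snps(path, self.lengths)

    def test_tsv_is_one_based(self, tmp_path):
        path = write(tmp_path, "s.tsv", "#chrom\tpos (1-based)\nchrom1\t1\nchrom1\t1000\n")
        snps = seq_io.read_snps(path, self.lengths)
        assert list(snps.positions["chrom1"]) == [0, 999]

    def test_tsv_position_zero_rejected(self, tmp_path):
        path = write(tmp_path, "s.tsv", "chrom1\t0\n")
        with pytest.raises(CoordinateError):
            seq_io.read_snps(path, self.lengths)

    def test_unknown_chromosome_rejected(self, tmp_path):
        path = write(tmp_path, "s.tsv", "chrX\t5\n")
        with pytest.raises(CoordinateError, match="chrX"):
            seq_io.read_snps(path, self.lengths)

    def test_tsv_round_trip(self, tmp_path):
        snps = SnpTable.from_records(
            [("chrom1", 0), ("chrom1", 999), ("chrom1", 17)], self.lengths
        )
        seq_io.write_snps_tsv(snps, tmp_path / "out.tsv")
        back = seq_io.read_snps(tmp_path / "out.tsv", self.lengths)
        assert np.array_equal(back.positions["chrom1"], snps.positions["chrom1"])

    def test_vcf_round_trip(self, tmp_path):
        snps = SnpTable.from_records([("chrom1", 3), ("chrom1", 998)], self.lengths)
        seq_io.write_snps_vcf(snps, tmp_path / "out.vcf")
        back = seq_io.read_snps(tmp_path / "out.vcf", self.lengths)
        assert np.array_equal(back.positions["chrom1"], snps.positions["chrom1"])


class TestGeneModels:
    def test_gff3_is_one_based_closed(self, tmp_path):
        gff = 'chr1\tsrc\tCDS\t101\t200\t.\t+\t0\tParent=g1\n'
        genes = seq_io.read_gene_models(write(tmp_path, "g.gff3", gff))
        assert genes[0].cds_intervals == ((100, 200),)
        assert genes[0].cds_length_bp == 100

    def test_overlapping_cds_merged_with_warning(self, tmp_path):
        gff = (
            "chr1\tsrc\tCDS\t1\t50\t.\t+\t0\tParent=g1\n"
            "chr1\tsrc\tCDS\t41\t90\t.\t+\t0\tParent=g1\n"
        )
        with pytest.warns(UserWarning, match="merged"):
            genes = seq_io.read_gene_models(write(tmp_path, "g.gff3", gff))
        assert genes[0].cds_length_bp == 90

    def test_zero_length_gene_skipped_with_warning(self, tmp_path):
        bed = "chr1\t100\t100\tg1\nchr1\t0\t60\tg2\n"
        with pytest.warns(UserWarning, match="g1"):
            genes = seq_io.read_gene_models(write(tmp_path, "g.bed", bed))
        assert [g.gene_id for g in genes] == ["g2"]

    def test_bed12_blocks_expand(self, tmp_path):
        bed = "chr1\t100\t400\tg1\t0\t+\t100\t400\t0\t2\t50,30\t0,270\n"
        genes = seq_io.read_gene_models(write(tmp_path, "g.bed", bed))
        assert genes[0].cds_intervals == ((100, 150), (370, 400))

    def test_bed6_round_trip(self, tmp_path):
        gene = GeneModel("g1", "chr1", ((10, 60), (100, 130)))
        seq_io.write_gene_models_bed([gene], tmp_path / "out.bed")
        back = seq_io.read_gene_models(tmp_path / "out.bed")
        assert back == [gene]


class TestBedExport:
    class Region:
        def __init__(self, chrom, start, end, p):
            self.chrom, self.start, self.end, self.p_value = chrom, start, end, p

    def test_score_is_neg_log10_p(self, tmp_path):
        seq_io.write_bed([self.Region("chrom1", 0, 500_000, 1e-6)], tmp_path / "r.bed")
        lines = (tmp_path / "r.bed").read_text().splitlines()
        assert lines[0].startswith("track")
        fields = lines[1].split("\t")
        assert fields[:3] == ["chrom1", "0", "500000"]
        assert float(fields[4]) == 6.0

    def test_p_zero_capped_at_300(self):
        assert seq_io.bed_score(0.0) == 300.0

    def test_empty_region_list_writes_track_header_only(self, tmp_path):
        seq_io.write_bed([], tmp_path / "r.bed")
        assert (tmp_path / "r.bed").read_text().startswith("track")


class TestKmerHistogram:
    def test_round_trip(self, tmp_path):
        hist = KmerHistogram(
            depths=np.array([1, 5, 30]), counts=np.array([100, 0, 7])
        )
        seq_io.write_kmer_histogram(hist, tmp_path / "h.txt")
        back = seq_io.read_kmer_histogram(tmp_path / "h.txt")
        assert np.array_equal(back.depths, hist.depths)
        assert np.array_equal(back.counts, hist.counts)

    def test_total_mass(self):
        hist = KmerHistogram(depths=np.array([2, 3]), counts=np.array([5, 4]))
        assert hist.total_mass() == 22
        assert hist.total_mass(min_depth=3) == 12

    def test_non_increasing_depths_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            KmerHistogram(depths=np.array([3, 2]), counts=np.array([1, 1]))


def test_chrom_lengths_round_trip(tmp_path):
    lengths = {"chr1": 123, "chr2": 456}
    seq_io.write_chrom_lengths(lengths, tmp_path / "l.tsv")
    assert seq_io.read_chrom_lengths(tmp_path / "l.tsv") == lengths
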