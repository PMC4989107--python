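import numpy as np
import pytest

from delscan import codons
from delscan.formats_io import (
    CodonAlignment,
    GenomicVariant,
    Phylogeny,
    read_alignment,
    read_gene_models,
    read_genetic_map,
    read_tree,
    read_variants,
    write_variants,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
)


def write_vcf(tmp_path, body, name="test.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return str(path)


class TestReadVariants:
    def test_single_record(self, tmp_path):
        path = write_vcf(tmp_path, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t1/1\n")
        table = read_variants(path)
        assert len(table) == 1
        v = table.records[0]
        assert (v.chrom, v.pos, v.ref, v.alt) == ("chr1", 100, "A", "G")
        assert v.genotypes == ((0, 0), (1, 1))
        assert table.sample_ids == ["s1", "s2"]

    def test_multiallelic_dropped(self, tmp_path):
        path = write_vcf(tmp_path, "chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t1/2\n")
        table = read_variants(path)
        assert len(table) == 0 and table.n_dropped == 1

    def test_indel_dropped(self, tmp_path):
        path = write_vcf(tmp_path, "chr1\t100\t.\tA\tGA\t.\tPASS\t.\tGT\t0/1\t0/0\n")
        table = read_variants(path)
        assert len(table) == 0 and table.n_dropped == 1

    def test_half_call_is_missing(self, tmp_path):
        path = write_vcf(tmp_path, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t./1\t./.\n")
        table = read_variants(path)
        assert table.records[0].genotypes == ((None, None), (None, None))

    def test_unsorted_error(self, tmp_path):
        body = (
            "chr1\t200\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\n"
            "chr1\t100\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/0\n"
        )
        with pytest.raises(ValueError, match="sorted"):
            read_variants(write_vcf(tmp_path, body))

    def test_round_trip(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t1/1\n"
            "chr1\t250\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.\n"
        )
        table = read_variants(write_vcf(tmp_path, body))
        out = tmp_path / "out.vcf"
        write_variants(table, str(out))
        again = read_variants(str(out))
        assert again.sample_ids == table.sample_ids
        assert again.records == table.records


class TestGeneModels:
    def _write(self, tmp_path, fasta, gff):
        fa = tmp_path / "g.fasta"
        fa.write_text(fasta)
        gf = tmp_path / "g.gff3"
        gf.write_text(gff)
        return str(gf), str(fa)

    def test_plus_strand_single_exon(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr1\tx\tmRNA\t1\t6\t.\t+\t.\tID=t1\n"
            "chr1\tx\tCDS\t1\t6\t.\t+\t0\tID=c1;Parent=t1\n"
        )
        genes = read_gene_models(*self._write(tmp_path, ">chr1\nATGGGTAAA\n", gff))
        assert genes.models["t1"].cds_seq == "ATGGGT"

    def test_minus_strand_reverse_complement(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr1\tx\tmRNA\t1\t6\t.\t-\t.\tID=t1\n"
            "chr1\tx\tCDS\t1\t6\t.\t-\t0\tID=c1;Parent=t1\n"
        )
        genes = read_gene_models(*self._write(tmp_path, ">chr1\nACCCATAAA\n", gff))
        assert genes.models["t1"].cds_seq == "ATGGGT"

    def test_shared_exon_two_transcripts(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr1\tx\tmRNA\t1\t6\t.\t+\t.\tID=t1\n"
            "chr1\tx\tmRNA\t1\t12\t.\t+\t.\tID=t2\n"
            "chr1\tx\tCDS\t1\t6\t.\t+\t0\tID=c1;Parent=t1,t2\n"
            "chr1\tx\tCDS\t7\t12\t.\t+\t0\tID=c2;Parent=t2\n"
        )
        genes = read_gene_models(
            *self._write(tmp_path, ">chr1\nATGGGTCATTGTAAA\n", gff)
        )
        assert set(genes.models) == {"t1", "t2"}
        assert genes.models["t1"].cds_seq == "ATGGGT"
        assert genes.models["t2"].cds_seq == "ATGGGTCATTGT"

    def test_phase_trims_partial_first_codon(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr1\tx\tCDS\t1\t7\t.\t+\t1\tID=c1;Parent=t1\n"
        )
        genes = read_gene_models(*self._write(tmp_path, ">chr1\nGATGGGTAA\n", gff))
        model = genes.models["t1"]
        assert model.cds_seq == "ATGGGT"
        assert not model.flagged

    def test_bad_length_flagged(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr1\tx\tCDS\t1\t7\t.\t+\t0\tID=c1;Parent=t1\n"
        )
        genes = read_gene_models(*self._write(tmp_path, ">chr1\nATGGGTAAA\n", gff))
        assert genes.models["t1"].flagged
        assert genes.models["t1"].flag_reason == "cds_length_not_multiple_of_3"

    def test_internal_stop_flagged(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr1\tx\tCDS\t1\t9\t.\t+\t0\tID=c1;Parent=t1\n"
        )
        genes = read_gene_models(*self._write(tmp_path, ">chr1\nATGTAAGGT\n", gff))
        assert genes.models["t1"].flagged
        assert genes.models["t1"].flag_reason == "internal_stop"

    def test_genome_to_cds_minus_strand(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr1\tx\tCDS\t1\t6\t.\t-\t0\tID=c1;Parent=t1\n"
        )
        genes = read_gene_models(*self._write(tmp_path, ">chr1\nACCCATAAA\n", gff))
        model = genes.models["t1"]
        # genomic position 6 is the first CDS base on the minus strand
        assert model.genome_to_cds(6) == 0
        assert model.genome_to_cds(1) == 5


class TestCodonAlignment:
    def test_codon_columns(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">q\nATGGGT\n>a\nATGGGC\n>b\nATAGGT\n")
        aln = read_alignment(str(path), "q")
        assert aln.n_codons == 2
        assert aln.matrix.shape == (3, 2)
        assert aln.matrix[0, 0] == codons.CODON_STATE["ATG"]

    def test_gap_codon_missing(self):
        aln = CodonAlignment(["q", "a"], ["ATGGGT", "AT-GGT"], "q")
        assert aln.matrix[1, 0] == codons.MISSING
        assert aln.matrix[1, 1] == codons.CODON_STATE["GGT"]

    def test_stop_codon_missing(self):
        aln = CodonAlignment(["q", "a"], ["ATGGGT", "TAAGGT"], "q")
        assert aln.matrix[1, 0] == codons.MISSING

    def test_bad_length_rejected(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">q\nATGGGTA\n>a\nATGGGTA\n")
        with pytest.raises(ValueError, match="divisible by 3"):
            read_alignment(str(path), "q")

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            CodonAlignment(["q", "a"], ["ATGGGT", "ATG"], "q")

    def test_query_absent_rejected(self):
        with pytest.raises(ValueError, match="query"):
            CodonAlignment(["a", "b"], ["ATGGGT", "ATGGGT"], "q")

    def test_query_maps_skip_gaps(self):
        aln = CodonAlignment(["q", "a"], ["---ATGGGT", "CCCATAGGC"], "q")
        # query's first ungapped codon is alignment codon column 1
        assert aln.query_codon_column == {0: 1, 1: 2}
        assert aln.query_nuc_to_column(0) == 3


class TestTree:
    def test_two_tips(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("(A:0.1,B:0.2);\n")
        phylo = read_tree(str(path))
        assert sorted(phylo.tip_labels) == ["A", "B"]
        assert phylo.total_length == pytest.approx(0.3)

    def test_internal_edge(self):
        phylo = Phylogeny.from_newick("((A:0.1,B:0.1):0.05,C:0.2);")
        assert len(phylo.tip_labels) == 3
        assert phylo.total_length == pytest.approx(0.45)

    def test_missing_length_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            Phylogeny.from_newick("(A:0.1,B);")


class TestGeneticMap:
    def _write(self, tmp_path, rows):
        path = tmp_path / "map.tsv"
        path.write_text("marker\tchrom\tbp\tcM\n" + "".join(rows))
        return str(path)

    def test_sorted_output(self, tmp_path):
        rows = [
            "m2\tchr1\t2000000\t3.0\n",
            "m1\tchr1\t1000000\t1.0\n",
            "m3\tchr1\t3000000\t4.5\n",
        ]
        gmap = read_genetic_map(self._write(tmp_path, rows))
        assert list(gmap.table["bp"]) == [1000000, 2000000, 3000000]

    def test_duplicate_bp_collapsed(self, tmp_path):
        rows = [
            "m1\tchr1\t1000000\t1.0\n",
            "m2\tchr1\t1000000\t1.2\n",
            "m3\tchr1\t2000000\t2.0\n",
        ]
        gmap = read_genetic_map(self._write(tmp_path, rows))
        assert len(gmap.table) == 2
        assert gmap.n_duplicates_dropped == 1
        assert gmap.table.iloc[0]["marker"] == "m1"

    def test_non_numeric_rejected_with_line(self, tmp_path):
        rows = ["m1\tchr1\t1000000\t1.0\n", "m2\tchr1\toops\t2.0\n"]
        with pytest.raises(ValueError, match="line 3"):
            read_genetic_map(self._write(tmp_path, rows))
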